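"""Pipeline orchestration: simulate (optional) -> mine -> annotate -> stats.

A :class:`PipelineConfig` carries all input paths, thresholds and output
paths; :func:`run_pipeline` executes the stages, writes a VCF, a variant
table, a per-variant Hardy-Weinberg report and a JSON run manifest, and is
idempotent given identical inputs and configuration.  Any stage failure
raises a stage-named error and removes partial outputs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as ovio
from .consequence import annotate_deletion, annotate_snp
from .genemodel import CdsLocation, GeneModel, coding_sequence, genomic_to_cds
from .mining import mine_variants
from .popgen import GenotypeCounts, hwe_test

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("ovmx")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and outputs of a full pipeline run."""

    pileup_path: str
    out_vcf: str
    out_table: str
    out_stats: str
    out_manifest: str
    reference_fasta: str | None = None  # needed for deletion anchoring on partial refs
    gene_model_path: str | None = None  # enables consequence annotation
    hom_max_minor: float = 0.10
    het_min_minor: float = 0.25
    coverage_min: int = 10
    region_sum_min: int = 99
    minor_fraction_crit: float = 0.45
    seed: int | None = None
    verbosity: str = "INFO"

    def validate(self) -> None:
        if not 0 <= self.hom_max_minor < self.het_min_minor <= 0.5:
            raise ValueError(
                "thresholds must satisfy 0 <= hom_max_minor < het_min_minor <= 0.5"
            )
        if self.coverage_min < 1 or self.region_sum_min < 0:
            raise ValueError("coverage thresholds out of range")
        if not 0 < self.minor_fraction_crit < 0.5:
            raise ValueError("minor_fraction_crit must be in (0, 0.5)")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute mine -> annotate -> stats and write all artifacts.

    Returns a summary dict (counts per stage).  Partial outputs are removed
    on failure.
    """
    cfg.validate()
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, cfg.verbosity.upper(), logging.INFO)
    )
    written: list[Path] = []
    try:
        return _run(cfg, written)
    except Exception as exc:
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"pipeline failed: {exc}") from exc


def _run(cfg: PipelineConfig, written: list[Path]) -> dict:
    # stage: load
    try:
        pileup = ovio.read_pileup_tsv(cfg.pileup_path)
    except Exception as exc:
        raise PipelineError(f"[load] cannot read pileup {cfg.pileup_path}: {exc}") from exc
    logger.info(
        "loaded pileup: %d individuals x %d positions",
        pileup.n_individuals,
        pileup.n_positions,
    )

    # stage: mine
    try:
        records = mine_variants(
            pileup,
            hom_max_minor=cfg.hom_max_minor,
            het_min_minor=cfg.het_min_minor,
            min_depth=cfg.coverage_min,
            region_sum_min=cfg.region_sum_min,
        )
    except Exception as exc:
        raise PipelineError(f"[mine] variant mining failed: {exc}") from exc
    accepted = [r for r in records if r.accepted]
    logger.info("mined %d candidate variants, %d accepted", len(records), len(accepted))

    # stage: annotate (optional, requires a gene model)
    annotations: dict[int, dict[str, str]] = {}
    codon_of: dict[int, int] = {}
    if cfg.gene_model_path:
        try:
            models = ovio.read_gene_model_tsv(cfg.gene_model_path)
            genome = pileup.reference  # pileup covers the modelled locus
            if int(pileup.positions[0]) != 1:
                raise ValueError("gene-model annotation requires a pileup starting at position 1")
            for model in models:
                cds = coding_sequence(model, genome)
                for rec in accepted:
                    loc = genomic_to_cds(model, rec.position)
                    if not isinstance(loc, CdsLocation):
                        continue
                    if rec.alt == "-":
                        csq = annotate_deletion(cds, loc.cds_pos)
                    else:
                        csq = annotate_snp(cds, loc.cds_pos, rec.alt)
                    annotations[rec.position] = {
                        "CSQ_CLASS": csq.consequence_class,
                        "HGVS_C": csq.hgvs_c,
                        "HGVS_P": csq.hgvs_p(),
                    }
                    codon_of[rec.position] = csq.codon_number
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"[annotate] consequence annotation failed: {exc}") from exc
        logger.info("annotated %d coding variants", len(annotations))

    # stage: stats (per accepted variant: genotype tallies + HWE)
    try:
        stat_rows = []
        for rec in accepted:
            states = [c.state for c in rec.genotypes.values()]
            counts = GenotypeCounts(
                n_ref_hom=states.count("hom_ref"),
                n_het=states.count("het"),
                n_alt_hom=states.count("hom_alt"),
            )
            hwe = hwe_test(counts)
            stat_rows.append(
                {
                    "position": rec.position,
                    "n_ref_hom": counts.n_ref_hom,
                    "n_het": counts.n_het,
                    "n_alt_hom": counts.n_alt_hom,
                    "n_ambiguous": states.count("ambiguous"),
                    "n_missing": states.count("missing"),
                    "hwe_chi2": "" if hwe.undefined else f"{hwe.statistic:.4f}",
                    "hwe_p": "" if hwe.undefined else f"{hwe.p_value:.4g}",
                }
            )
    except Exception as exc:
        raise PipelineError(f"[stats] per-variant statistics failed: {exc}") from exc

    # stage: write
    config = {k: v for k, v in asdict(cfg).items()}
    digest = ovio.config_hash(config)
    try:
        out_vcf, out_table, out_stats, out_manifest = (
            Path(cfg.out_vcf),
            Path(cfg.out_table),
            Path(cfg.out_stats),
            Path(cfg.out_manifest),
        )
        written.extend([out_vcf, out_table, out_stats, out_manifest])
        ovio.write_vcf(
            accepted,
            pileup.reference,
            out_vcf,
            ref_start=int(pileup.positions[0]),
            annotations=annotations,
            config_digest=digest,
        )
        ovio.write_variant_table(accepted, out_table, codon_of=codon_of)
        pd.DataFrame(stat_rows).to_csv(out_stats, sep="\t", index=False)
        ovio.write_manifest(
            out_manifest,
            config,
            inputs={"pileup": cfg.pileup_path},
            outputs={"vcf": out_vcf, "table": out_table, "stats": out_stats},
            extra={"n_candidates": len(records), "n_accepted": len(accepted)},
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[write] writing outputs failed: {exc}") from exc
    return {
        "n_candidates": len(records),
        "n_accepted": len(accepted),
        "n_annotated": len(annotations),
        "config_hash": digest,
    }
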