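"""Readers and writers for every external format the pipeline touches.

Formats: FASTA (sequences), a versioned pileup TSV dialect, VCFv4.2
(accepted variants; 1-based POS, deletions left-anchored on the preceding
reference base), a published-table-style variant TSV, gene models (BED12-
like TSV in, GFF3 out), genotype/pedigree/Ct TSVs, and a JSON run manifest.

Every variant output file declares the tool version and a config hash in
its header so runs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genemodel import GeneModel
from .mining import ALLELES, CohortPileup, CriteriaFlags, GenotypeCall, VariantRecord
from .popgen import CtTable, PedigreeTrio

__version__ = "0.1.0"

PILEUP_HEADER = "#ovmx-pileup\tv1"
_PILEUP_COLUMNS = [
    "individual_id",
    "position",
    "ref",
    "countA",
    "countC",
    "countG",
    "countT",
    "countGap",
]

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pileup_tsv",
    "write_pileup_tsv",
    "write_vcf",
    "read_vcf",
    "write_variant_table",
    "read_gene_model_tsv",
    "write_gene_model_gff3",
    "read_genotype_tsv",
    "read_pedigree_tsv",
    "read_ct_tsv",
    "write_manifest",
    "config_hash",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Pileup TSV


def write_pileup_tsv(pileup: CohortPileup, path: str | Path) -> None:
    """Write the versioned pileup dialect: one row per (individual, position)."""
    rows = []
    for i, ind in enumerate(pileup.individuals):
        for j, pos in enumerate(pileup.positions):
            c = pileup.counts[i, j]
            rows.append((ind, int(pos), pileup.reference[j], *(int(x) for x in c)))
    frame = pd.DataFrame(rows, columns=_PILEUP_COLUMNS)
    with open(path, "w") as fh:
        fh.write(PILEUP_HEADER + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_pileup_tsv(path: str | Path) -> CohortPileup:
    """Read the pileup dialect back into a :class:`CohortPileup`.

    Missing (individual, position) pairs are taken as zero depth.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != PILEUP_HEADER:
            raise ValueError(
                f"not an ovmx pileup file (header {first!r}, expected {PILEUP_HEADER!r})"
            )
        frame = pd.read_csv(fh, sep="\t", dtype={"ref": str, "individual_id": str})
    missing = set(_PILEUP_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"pileup file lacks columns: {sorted(missing)}")
    individuals = sorted(frame["individual_id"].unique())
    positions = np.sort(frame["position"].unique())
    pos_index = {int(p): j for j, p in enumerate(positions)}
    ind_index = {s: i for i, s in enumerate(individuals)}
    reference = [""] * len(positions)
    counts = np.zeros((len(individuals), len(positions), len(ALLELES)), dtype=np.int64)
    count_cols = ["countA", "countC", "countG", "countT", "countGap"]
    for row in frame.itertuples(index=False):
        j = pos_index[int(row.position)]
        i = ind_index[row.individual_id]
        ref = row.ref.upper()
        if reference[j] and reference[j] != ref:
            raise ValueError(f"conflicting reference base at position {row.position}")
        reference[j] = ref
        counts[i, j] = [getattr(row, c) for c in count_cols]
    if any(r == "" for r in reference):
        raise ValueError("some positions lack a reference base")
    return CohortPileup(
        individuals=individuals,
        positions=positions,
        reference="".join(reference),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# VCF


def _vcf_ref_alt(
    rec: VariantRecord, reference: str, ref_start: int
) -> tuple[int, str, str]:
    """POS/REF/ALT with 1-bp deletions left-anchored on the preceding base."""
    if rec.alt == "-":
        if rec.position <= ref_start:
            raise ValueError("cannot anchor a deletion at the first reference base")
        prev = reference[rec.position - 1 - ref_start - 1]
        return rec.position - 1, prev + rec.ref, prev
    return rec.position, rec.ref, rec.alt


def write_vcf(
    records: Sequence[VariantRecord],
    reference: str,
    path: str | Path,
    contig: str = "ref",
    ref_start: int = 1,
    annotations: Mapping[int, Mapping[str, str]] | None = None,
    config_digest: str | None = None,
) -> None:
    """Write accepted variants as VCFv4.2.

    ``annotations`` optionally maps a record's position to extra INFO keys
    (e.g. CSQ_CLASS / HGVS_C / HGVS_P from consequence annotation).
    """
    annotations = annotations or {}
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=ovmx {__version__}",
    ]
    if config_digest:
        lines.append(f"##ovmx_config_hash={config_digest}")
    lines += [
        f"##contig=<ID={contig},length={ref_start + len(reference) - 1}>",
        '##INFO=<ID=FALT,Number=1,Type=Float,Description="Pooled alternative-allele read frequency">',
        '##INFO=<ID=READS,Number=2,Type=Integer,Description="Variant and total pooled reads">',
        '##INFO=<ID=ANIMALS,Number=2,Type=Integer,Description="Carrier and genotyped animal counts">',
        '##INFO=<ID=VCLASS,Number=1,Type=String,Description="SNP_Ts, SNP_Tv or INDEL">',
        '##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Coding consequence class">',
        '##INFO=<ID=HGVS_C,Number=1,Type=String,Description="Coding-level label">',
        '##INFO=<ID=HGVS_P,Number=1,Type=String,Description="Protein-level label">',
        '##FILTER=<ID=cohort_criteria,Description="Failed one or more cohort filter criteria">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for rec in sorted(records, key=lambda r: r.position):
        pos, ref, alt = _vcf_ref_alt(rec, reference, ref_start)
        info = {
            "FALT": f"{rec.f_alt_reported:.2f}",
            "READS": f"{rec.pooled_variant_reads},{rec.pooled_total_reads}",
            "ANIMALS": f"{rec.n_carriers},{rec.n_genotyped}",
            "VCLASS": rec.variant_class,
        }
        info.update(annotations.get(rec.position, {}))
        info_str = ";".join(f"{k}={v}" for k, v in info.items())
        filt = "PASS" if rec.accepted else "cohort_criteria"
        lines.append(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t{info_str}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[dict]:
    """Re-parse an ovmx VCF (via pysam) into plain record dicts.

    Returns position/ref/alt in the pileup convention (deletions restored
    to the gap allele at the deleted base) plus the INFO payload, which is
    the round-trip complement of :func:`write_vcf`.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref, alt = rec.ref, rec.alts[0]
            pos = rec.pos
            if len(ref) == 2 and len(alt) == 1 and ref[0] == alt:
                # left-anchored 1-bp deletion
                pos, ref, alt = pos + 1, ref[1], "-"
            reads = rec.info["READS"]
            animals = rec.info["ANIMALS"]
            out.append(
                {
                    "position": pos,
                    "ref": ref,
                    "alt": alt,
                    "variant_class": rec.info["VCLASS"],
                    "f_alt": float(rec.info["FALT"]),
                    "pooled_variant_reads": int(reads[0]),
                    "pooled_total_reads": int(reads[1]),
                    "n_carriers": int(animals[0]),
                    "n_genotyped": int(animals[1]),
                    "filter": list(rec.filter.keys()),
                    "info": {
                        k: rec.info[k]
                        for k in ("CSQ_CLASS", "HGVS_C", "HGVS_P")
                        if k in rec.info
                    },
                }
            )
    return out


def write_variant_table(
    records: Sequence[VariantRecord],
    path: str | Path,
    codon_of: Mapping[int, int] | None = None,
) -> None:
    """Published-table-style TSV: position, change, type, pooled reads,
    f(alt), carrier/genotyped animals (and codon number when known)."""
    rows = []
    for rec in sorted(records, key=lambda r: r.position):
        change = f"{rec.ref} > {rec.alt}" if rec.alt != "-" else f"{rec.ref}del"
        rows.append(
            {
                "position": rec.position,
                "codon": codon_of.get(rec.position, "") if codon_of else "",
                "change": change,
                "type": rec.variant_class,
                "reads_variant_total": f"{rec.pooled_variant_reads}/{rec.pooled_total_reads}",
                "f_alt": f"{rec.f_alt_reported:.2f}",
                "animals_variant_total": f"{rec.n_carriers}/{rec.n_genotyped}",
                "accepted": rec.accepted,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models


def read_gene_model_tsv(path: str | Path) -> list[GeneModel]:
    """Read gene models from a minimal BED12-like TSV.

    Columns: gene_id, strand, exon_starts, exon_ends (comma-separated,
    1-based inclusive, transcript order), cds_start, cds_end.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    models = []
    for row in frame.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",") if x]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x]
        if len(starts) != len(ends):
            raise ValueError(f"gene {row.gene_id}: exon start/end count mismatch")
        models.append(
            GeneModel(
                gene_id=str(row.gene_id),
                strand=str(row.strand),
                exons=tuple(zip(starts, ends)),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
        )
    return models


def write_gene_model_gff3(
    models: Sequence[GeneModel], path: str | Path, contig: str = "ref"
) -> None:
    """Write gene models as GFF3 (gene / exon / CDS features)."""
    lines = ["##gff-version 3", f"##source ovmx {__version__}"]
    for m in models:
        lo = min(a for a, _ in m.exons)
        hi = max(b for _, b in m.exons)
        lines.append(
            f"{contig}\tovmx\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\tID={m.gene_id}"
        )
        for k, (a, b) in enumerate(m.exons, 1):
            lines.append(
                f"{contig}\tovmx\texon\t{min(a, b)}\t{max(a, b)}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.exon{k};Parent={m.gene_id}"
            )
        c1, c2 = sorted((m.cds_start, m.cds_end))
        lines.append(
            f"{contig}\tovmx\tCDS\t{c1}\t{c2}\t.\t{m.strand}\t0\t"
            f"ID={m.gene_id}.cds;Parent={m.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Genotype / pedigree / Ct tables


def read_genotype_tsv(path: str | Path) -> pd.DataFrame:
    """Genotype table: animal_id plus one column per locus with values
    hom_ref/het/hom_alt/unknown."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "animal_id" not in frame.columns:
        raise ValueError("genotype table requires an animal_id column")
    return frame


def read_pedigree_tsv(path: str | Path, locus: str | None = None) -> list[PedigreeTrio]:
    """Pedigree TSV: animal_id, sire_id, dam_id and per-locus genotype
    columns (``<locus>`` for the offspring, ``dam_<locus>`` optionally)."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("unknown")
    required = {"animal_id", "sire_id", "dam_id"}
    if not required <= set(frame.columns):
        raise ValueError(f"pedigree table requires columns {sorted(required)}")
    trios = []
    for row in frame.itertuples(index=False):
        geno = getattr(row, locus) if locus and hasattr(row, locus) else "unknown"
        dam_col = f"dam_{locus}" if locus else None
        dam_geno = (
            getattr(row, dam_col) if dam_col and hasattr(row, dam_col) else "unknown"
        )
        trios.append(
            PedigreeTrio(
                offspring_id=row.animal_id,
                sire_id=row.sire_id,
                dam_id=row.dam_id,
                offspring_genotype=geno,
                dam_genotype=dam_geno,
            )
        )
    return trios


def read_ct_tsv(path: str | Path) -> CtTable:
    """Ct table TSV with columns: role (target|reference),
    condition (treated|control), ct."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    def pick(role: str, condition: str) -> tuple[float, ...]:
        sel = frame[(frame["role"] == role) & (frame["condition"] == condition)]
        return tuple(float(x) for x in sel["ct"])

    return CtTable(
        target_treated=pick("target", "treated"),
        reference_treated=pick("reference", "treated"),
        target_control=pick("target", "control"),
        reference_control=pick("reference", "control"),
    )


# ---------------------------------------------------------------------------
# Manifest


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(
    path: str | Path,
    config: Mapping,
    inputs: Mapping[str, str | Path] | None = None,
    outputs: Mapping[str, str | Path] | None = None,
    extra: Mapping | None = None,
) -> None:
    """Machine-readable JSON run manifest (version, config hash, checksums)."""
    manifest = {
        "tool": "ovmx",
        "version": __version__,
        "config": dict(config),
        "config_hash": config_hash(config),
        "inputs": {
            k: {"path": str(v), "sha256_16": file_checksum(v)}
            for k, v in (inputs or {}).items()
        },
        "outputs": {k: str(v) for k, v in (outputs or {}).items()},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
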