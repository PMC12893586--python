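"""Seedable simulators for diploid cohorts, pedigrees and closed flocks.

The cohort generator emulates the statistical structure of a whole-genome
resequencing panel: each individual carries a diploid genotype at every
planted variant site (two Bernoulli draws from the population allele
frequency), per-site read depth is Poisson, and each read suffers an
independent per-base error that substitutes uniformly among the other
nucleotides.  Heterozygous sites therefore show minor-allele read fractions
near 0.5, homozygous sites near 0.  Defaults (mean depth 20, error rate
0.5%) sit inside the 10-30x coverage band typical of such panels.

Randomness: one seed drives everything; sub-generators draw from
independent substreams keyed by (module, individual), so adding individuals
never perturbs the reads of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mining import ALLELES, CohortPileup

__all__ = [
    "PlantedVariant",
    "PedigreeSpec",
    "SimConfig",
    "TruthSet",
    "simulate_cohort",
    "simulate_pedigree",
    "simulate_closed_flock",
]

_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}

# substream domains
_STREAM_COHORT = 0
_STREAM_PEDIGREE = 1
_STREAM_FLOCK = 2


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class PlantedVariant:
    """A variant segregating in the simulated population."""

    position: int  # 1-based position on the reference
    ref: str
    alt: str  # "-" for a single-base deletion allele
    frequency: float  # population alternative-allele frequency
    kind: str = "SNP"  # SNP | deletion

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")
        if self.kind not in ("SNP", "deletion"):
            raise ValueError(f"kind must be SNP or deletion, got {self.kind!r}")
        if self.kind == "deletion" and self.alt != "-":
            raise ValueError("deletion variants must use the gap allele '-'")
        if self.ref not in "ACGT" or self.alt not in ALLELES:
            raise ValueError("malformed alleles")


@dataclass(frozen=True)
class PedigreeSpec:
    n_sires: int
    progeny_per_sire: int

    def __post_init__(self) -> None:
        if self.n_sires < 1 or self.progeny_per_sire < 1:
            raise ValueError("pedigree spec requires >= 1 sire and >= 1 progeny")


@dataclass(frozen=True)
class SimConfig:
    """Specification of a synthetic cohort; the seed is mandatory."""

    n_individuals: int
    planted_variants: tuple[PlantedVariant, ...]
    seed: int
    mean_depth: float = 20.0
    error_rate: float = 0.005
    pedigree: PedigreeSpec | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        object.__setattr__(self, "planted_variants", tuple(self.planted_variants))


@dataclass(frozen=True)
class TruthSet:
    """Ground truth behind a simulated pileup.

    ``genotypes`` holds the number of alternative-allele copies (0/1/2) per
    (individual, planted variant); ``true_f_alt`` the realised cohort
    alternative-allele fraction per planted variant.
    """

    individuals: tuple[str, ...]
    variants: tuple[PlantedVariant, ...]
    genotypes: np.ndarray  # (n_individuals, n_variants) int
    true_f_alt: tuple[float, ...]

    def genotype_state(self, individual: int, variant: int) -> str:
        return ("hom_ref", "het", "hom_alt")[int(self.genotypes[individual, variant])]


def _error_targets(source_idx: int) -> list[int]:
    """Alleles an erroneous read of a given true allele can turn into.

    Errors always produce nucleotides: a nucleotide read miscalls as one of
    the other three bases; a gap read miscalls as any of the four bases.
    """
    if ALLELES[source_idx] == "-":
        return [0, 1, 2, 3]
    return [i for i in range(4) if i != source_idx]


def simulate_cohort(
    cfg: SimConfig, reference: str
) -> tuple[CohortPileup, TruthSet]:
    """Simulate a cohort read pileup over a reference sequence.

    Returns the pileup (all positions of the reference) and the truth set.
    Fully reproducible from ``cfg.seed``.
    """
    reference = reference.upper()
    n_pos = len(reference)
    variants = cfg.planted_variants
    for v in variants:
        if not 1 <= v.position <= n_pos:
            raise ValueError(f"planted variant position {v.position} outside reference")
        if reference[v.position - 1] != v.ref:
            raise ValueError(
                f"planted variant at {v.position} declares ref {v.ref} but the "
                f"reference has {reference[v.position - 1]}"
            )
    positions = sorted({v.position for v in variants})
    if len(positions) != len(variants):
        raise ValueError("planted variants must have distinct positions")

    ref_idx = np.array([_ALLELE_INDEX[b] for b in reference])
    var_cols = {v.position - 1 for v in variants}
    individuals = tuple(f"ind{i:03d}" for i in range(cfg.n_individuals))

    counts = np.zeros((cfg.n_individuals, n_pos, len(ALLELES)), dtype=np.int64)
    genotypes = np.zeros((cfg.n_individuals, len(variants)), dtype=np.int64)

    # group non-variant positions by reference base for vectorised error draws
    by_base: dict[int, np.ndarray] = {}
    nonvar_mask = np.ones(n_pos, dtype=bool)
    for j in var_cols:
        nonvar_mask[j] = False
    for b in range(4):
        by_base[b] = np.nonzero(nonvar_mask & (ref_idx == b))[0]

    for i in range(cfg.n_individuals):
        rng = _rng(cfg.seed, _STREAM_COHORT, i)
        genotypes[i] = rng.binomial(2, [v.frequency for v in variants])
        depth = rng.poisson(cfg.mean_depth, size=n_pos)
        # non-variant sites: all reads drawn from the reference base, then errors
        for b in range(4):
            cols = by_base[b]
            if cols.size == 0:
                continue
            d = depth[cols]
            counts[i, cols, b] = d
            if cfg.error_rate > 0:
                n_err = rng.binomial(d, cfg.error_rate)
                counts[i, cols, b] -= n_err
                targets = _error_targets(b)
                spread = rng.multinomial(n_err, [1 / 3] * 3)
                for k, t in enumerate(targets):
                    counts[i, cols, t] += spread[:, k]
        # variant sites: reads split between the two true alleles by genotype
        for k, v in enumerate(variants):
            j = v.position - 1
            d = int(depth[j])
            alt_frac = genotypes[i, k] / 2.0
            a_ref = _ALLELE_INDEX[v.ref]
            a_alt = _ALLELE_INDEX[v.alt]
            n_alt = int(rng.binomial(d, alt_frac)) if 0 < alt_frac < 1 else int(d * alt_frac)
            true_reads = {a_ref: d - n_alt, a_alt: n_alt}
            for src, n_src in true_reads.items():
                if n_src == 0:
                    continue
                n_err = int(rng.binomial(n_src, cfg.error_rate)) if cfg.error_rate else 0
                counts[i, j, src] += n_src - n_err
                if n_err:
                    targets = _error_targets(src)
                    spread = rng.multinomial(n_err, [1 / len(targets)] * len(targets))
                    for t, c in zip(targets, spread):
                        counts[i, j, t] += int(c)

    pileup = CohortPileup(
        individuals=list(individuals),
        positions=np.arange(1, n_pos + 1),
        reference=reference,
        counts=counts,
    )
    truth = TruthSet(
        individuals=individuals,
        variants=variants,
        genotypes=genotypes,
        true_f_alt=tuple(
            float(genotypes[:, k].sum() / (2 * cfg.n_individuals))
            for k in range(len(variants))
        ),
    )
    return pileup, truth


# ---------------------------------------------------------------------------
# Pedigrees


@dataclass(frozen=True)
class SimulatedTrio:
    offspring_id: str
    sire_id: str
    dam_id: str
    sire_genotype: str
    dam_genotype: str
    offspring_genotype: str


def _state(n_alt: int) -> str:
    return ("hom_ref", "het", "hom_alt")[n_alt]


def simulate_pedigree(
    cfg: SimConfig, variant_index: int = 0
) -> list[SimulatedTrio]:
    """Simulate single-sire families at one planted variant.

    Sires and (distinct) dams draw their genotypes from the variant's
    population allele frequency; offspring genotypes follow Mendelian
    transmission.  Reproducible from the config seed.
    """
    if cfg.pedigree is None:
        raise ValueError("SimConfig has no pedigree spec")
    freq = cfg.planted_variants[variant_index].frequency
    spec = cfg.pedigree
    trios: list[SimulatedTrio] = []
    for s in range(spec.n_sires):
        rng = _rng(cfg.seed, _STREAM_PEDIGREE, s)
        sire_n = int(rng.binomial(2, freq))
        for k in range(spec.progeny_per_sire):
            dam_n = int(rng.binomial(2, freq))
            from_sire = int(rng.random() < sire_n / 2.0)
            from_dam = int(rng.random() < dam_n / 2.0)
            trios.append(
                SimulatedTrio(
                    offspring_id=f"s{s:02d}o{k:03d}",
                    sire_id=f"sire{s:02d}",
                    dam_id=f"s{s:02d}d{k:03d}",
                    sire_genotype=_state(sire_n),
                    dam_genotype=_state(dam_n),
                    offspring_genotype=_state(from_sire + from_dam),
                )
            )
    return trios


# ---------------------------------------------------------------------------
# Closed-flock allele trajectories


def simulate_closed_flock(
    n_breeding: int,
    generations: int,
    f0: float,
    s: float,
    seed: int | None = None,
    deterministic: bool = False,
    replicate: int = 0,
) -> np.ndarray:
    """Wright-Fisher allele-frequency trajectory with viability selection.

    Fitnesses are 1, 1, 1-s for reference homozygotes, heterozygotes and
    alternative homozygotes (selection against a recessive deleterious
    allele).  Each generation applies selection to Hardy-Weinberg genotype
    proportions and then binomially resamples 2*``n_breeding`` allele
    copies; ``deterministic=True`` skips the resampling (infinite
    population), in which case the recessive-lethal case s = 1 follows the
    closed form f' = f / (1 + f).

    Returns the trajectory of length ``generations`` + 1 starting at f0.
    """
    if n_breeding < 2:
        raise ValueError("n_breeding must be >= 2")
    if not 0.0 <= s <= 1.0:
        raise ValueError("selection coefficient must be in [0, 1]")
    if not 0.0 <= f0 <= 1.0:
        raise ValueError("f0 must be in [0, 1]")
    if not deterministic and seed is None:
        raise ValueError("stochastic mode requires a seed")
    rng = _rng(seed, _STREAM_FLOCK, replicate) if not deterministic else None
    traj = np.empty(generations + 1, dtype=float)
    f = float(f0)
    traj[0] = f
    two_n = 2 * n_breeding
    for t in range(1, generations + 1):
        w_bar = 1.0 - s * f * f
        if w_bar <= 0.0:
            f = 0.0
        else:
            f = (f * (1.0 - f) + (1.0 - s) * f * f) / w_bar
        if not deterministic:
            f = rng.binomial(two_n, f) / two_n
        traj[t] = f
    return traj
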