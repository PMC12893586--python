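"""Population-genetic statistics for biallelic loci.

Covers allele/genotype frequency estimation, Hardy-Weinberg conformance and
between-flock allele-frequency chi-square tests, maximum-likelihood sire
genotype inference from progeny under Mendelian transmission, haplotype
enumeration over linked sites, and qPCR relative expression by the
2^-ddCt method.

All chi-square p-values come from the chi-square distribution (df = 1 for a
biallelic locus: three genotype classes, one estimated allele frequency).
No multiple-testing correction is applied; callers compare p against their
chosen significance level (default 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "ChiSquareResult",
    "PedigreeTrio",
    "SireInference",
    "CtTable",
    "PedigreeInconsistencyError",
    "allele_frequency",
    "carriers",
    "hwe_test",
    "flock_compare",
    "allele_counts_from_frequency",
    "infer_sire_genotype",
    "enumerate_haplotypes",
    "ddct",
]

GENOTYPES = ("hom_ref", "het", "hom_alt")


@dataclass(frozen=True)
class GenotypeCounts:
    """Hom-ref / het / hom-alt tallies at one biallelic locus."""

    n_ref_hom: int
    n_het: int
    n_alt_hom: int

    def __post_init__(self) -> None:
        if min(self.n_ref_hom, self.n_het, self.n_alt_hom) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_alt_hom

    @property
    def allele_counts(self) -> tuple[int, int]:
        """(reference, alternative) allele counts; sums to 2n."""
        return (
            2 * self.n_ref_hom + self.n_het,
            2 * self.n_alt_hom + self.n_het,
        )


def allele_frequency(counts: GenotypeCounts) -> tuple[float, float]:
    """(f_ref, f_alt) from genotype counts; f_ref + f_alt = 1."""
    if counts.n < 1:
        raise ValueError("empty genotype counts")
    ref, alt = counts.allele_counts
    total = 2 * counts.n
    return ref / total, alt / total


def carriers(counts: GenotypeCounts) -> int:
    """Animals carrying at least one alternative allele."""
    return counts.n_het + counts.n_alt_hom


def allele_counts_from_frequency(
    f_ref: float, f_alt: float, n_animals: int
) -> tuple[int, int]:
    """Convert published allele frequencies + sample size to allele counts.

    Frequencies are rounded to the nearest whole allele; the two counts
    must conserve 2n alleles.
    """
    total = 2 * n_animals
    ref = round(f_ref * total)
    alt = round(f_alt * total)
    if ref + alt != total:
        raise ValueError(
            f"frequencies {f_ref}/{f_alt} do not conserve {total} alleles "
            f"(got {ref}+{alt})"
        )
    return ref, alt


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square test result with its expected-count table."""

    statistic: float
    df: int
    p_value: float
    expected: tuple[float, ...]
    undefined: bool = False
    note: str | None = None


def _undefined_result(note: str) -> ChiSquareResult:
    return ChiSquareResult(
        statistic=math.nan,
        df=1,
        p_value=math.nan,
        expected=(),
        undefined=True,
        note=note,
    )


def hwe_test(counts: GenotypeCounts) -> ChiSquareResult:
    """Pearson chi-square test of Hardy-Weinberg genotype proportions.

    Expected counts are (p^2, 2pq, q^2) * n with p estimated from the
    observed allele counts; df = 1.  A monomorphic sample yields an
    explicit undefined result rather than a silent p = 1.
    """
    if counts.n < 1:
        raise ValueError("empty genotype counts")
    ref, alt = counts.allele_counts
    if ref == 0 or alt == 0:
        return _undefined_result("monomorphic sample: HWE test undefined")
    p = ref / (2 * counts.n)
    q = 1.0 - p
    expected = (p * p * counts.n, 2 * p * q * counts.n, q * q * counts.n)
    observed = (counts.n_ref_hom, counts.n_het, counts.n_alt_hom)
    statistic = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(statistic=statistic, df=1, p_value=p_value, expected=expected)


def flock_compare(
    a: GenotypeCounts | tuple[int, int],
    b: GenotypeCounts | tuple[int, int],
    yates: bool = False,
) -> ChiSquareResult:
    """2x2 chi-square on allele counts (ref/alt x flock), df = 1.

    Flocks may be given as :class:`GenotypeCounts` or directly as
    (ref, alt) allele counts (the published-table format).  Yates
    continuity correction is off by default.
    """
    row_a = a.allele_counts if isinstance(a, GenotypeCounts) else tuple(a)
    row_b = b.allele_counts if isinstance(b, GenotypeCounts) else tuple(b)
    if sum(row_a) == 0 or sum(row_b) == 0:
        return _undefined_result("empty flock: test undefined")
    table = np.array([row_a, row_b], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        return _undefined_result("an allele absent from both flocks: test undefined")
    res = stats.chi2_contingency(table, correction=yates)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        expected=tuple(res.expected_freq.ravel()),
    )


# ---------------------------------------------------------------------------
# Sire genotype inference


@dataclass(frozen=True)
class PedigreeTrio:
    """One offspring with its recorded sire and dam."""

    offspring_id: str
    sire_id: str
    dam_id: str
    offspring_genotype: str = "unknown"  # hom_ref | het | hom_alt | unknown
    dam_genotype: str = "unknown"

    def __post_init__(self) -> None:
        ids = {self.offspring_id, self.sire_id, self.dam_id}
        if len(ids) != 3:
            raise ValueError("offspring, sire and dam ids must be distinct")
        for g in (self.offspring_genotype, self.dam_genotype):
            if g not in GENOTYPES + ("unknown",):
                raise ValueError(f"unknown genotype label {g!r}")


class PedigreeInconsistencyError(ValueError):
    """No candidate sire genotype can explain the progeny."""


@dataclass(frozen=True)
class SireInference:
    """Per-genotype likelihoods and the maximum-likelihood verdict."""

    likelihoods: Mapping[str, float]
    verdict: str
    label: str  # "likely" | "ambiguous"
    likelihood_ratio: float  # ML vs runner-up; inf if runner-up is 0


def _transmit_alt_prob(genotype: str) -> float:
    return {"hom_ref": 0.0, "het": 0.5, "hom_alt": 1.0}[genotype]


def _offspring_probs(p_sire_alt: float, p_dam_alt: float) -> dict[str, float]:
    return {
        "hom_ref": (1 - p_sire_alt) * (1 - p_dam_alt),
        "het": p_sire_alt * (1 - p_dam_alt) + (1 - p_sire_alt) * p_dam_alt,
        "hom_alt": p_sire_alt * p_dam_alt,
    }


def infer_sire_genotype(
    progeny: Sequence[PedigreeTrio],
    dam_f_alt: float | None = None,
    likely_ratio: float = 20.0,
) -> SireInference:
    """Maximum-likelihood sire genotype from progeny genotypes.

    For each candidate sire genotype the likelihood is the product over
    progeny of P(offspring genotype | sire, dam) under Mendelian
    transmission.  A dam with a recorded genotype transmits accordingly;
    otherwise her transmitted allele is drawn from the population
    alternative-allele frequency ``dam_f_alt``.  The verdict is "likely"
    when the best genotype beats the runner-up by at least ``likely_ratio``
    to one, else "ambiguous".
    """
    informative = [t for t in progeny if t.offspring_genotype != "unknown"]
    if not informative:
        raise ValueError("need at least one progeny with a known genotype")
    likelihoods: dict[str, float] = {}
    for sire_g in GENOTYPES:
        ps = _transmit_alt_prob(sire_g)
        lik = 1.0
        for trio in informative:
            if trio.dam_genotype != "unknown":
                pd = _transmit_alt_prob(trio.dam_genotype)
            elif dam_f_alt is not None:
                pd = dam_f_alt
            else:
                raise ValueError(
                    "dam genotype unknown and no population dam_f_alt given "
                    f"for trio {trio.offspring_id}"
                )
            lik *= _offspring_probs(ps, pd)[trio.offspring_genotype]
        likelihoods[sire_g] = lik
    ranked = sorted(GENOTYPES, key=lambda g: -likelihoods[g])
    best, runner = ranked[0], ranked[1]
    if likelihoods[best] == 0.0:
        bad = _first_inconsistent_trio(informative, dam_f_alt)
        raise PedigreeInconsistencyError(
            f"no sire genotype explains the progeny (e.g. trio "
            f"{bad.offspring_id if bad else '?'})"
        )
    ratio = (
        math.inf
        if likelihoods[runner] == 0.0
        else likelihoods[best] / likelihoods[runner]
    )
    label = "likely" if ratio >= likely_ratio else "ambiguous"
    return SireInference(
        likelihoods=likelihoods, verdict=best, label=label, likelihood_ratio=ratio
    )


def _first_inconsistent_trio(
    progeny: Sequence[PedigreeTrio], dam_f_alt: float | None
) -> PedigreeTrio | None:
    for trio in progeny:
        possible = False
        for sire_g in GENOTYPES:
            ps = _transmit_alt_prob(sire_g)
            pd = (
                _transmit_alt_prob(trio.dam_genotype)
                if trio.dam_genotype != "unknown"
                else (dam_f_alt if dam_f_alt is not None else 0.5)
            )
            if _offspring_probs(ps, pd)[trio.offspring_genotype] > 0:
                possible = True
                break
        if not possible:
            return trio
    return None


# ---------------------------------------------------------------------------
# Haplotypes


def enumerate_haplotypes(
    genotype: Sequence[tuple[str, str]],
) -> tuple[set[tuple[str, str]], bool]:
    """All haplotype pairs consistent with an unphased multi-site genotype.

    ``genotype`` is an ordered list of allele pairs at linked sites.  With
    h heterozygous sites there are 2^(h-1) distinct phase configurations
    (one when h <= 1); each configuration is returned as a
    lexicographically ordered pair of haplotype strings.  The genotype is
    unambiguous iff h <= 1.
    """
    het_sites = [i for i, (x, y) in enumerate(genotype) if x != y]
    h = len(het_sites)
    configs: set[tuple[str, str]] = set()
    n_free = max(0, h - 1)  # first het site anchors the labelling
    for mask in range(2 ** n_free):
        hap1 = []
        hap2 = []
        free_idx = 0
        for i, (x, y) in enumerate(genotype):
            if x == y:
                hap1.append(x)
                hap2.append(y)
            elif i == (het_sites[0] if het_sites else -1):
                hap1.append(x)
                hap2.append(y)
            else:
                flip = (mask >> free_idx) & 1
                free_idx += 1
                hap1.append(y if flip else x)
                hap2.append(x if flip else y)
        pair = tuple(sorted(("".join(hap1), "".join(hap2))))
        configs.add(pair)  # type: ignore[arg-type]
    return configs, h <= 1


# ---------------------------------------------------------------------------
# qPCR relative expression


@dataclass(frozen=True)
class CtTable:
    """qPCR cycle thresholds for one target/reference/treatment comparison.

    Each field holds one or more technical-replicate Ct values; replicates
    are averaged before differencing.
    """

    target_treated: tuple[float, ...]
    reference_treated: tuple[float, ...]
    target_control: tuple[float, ...]
    reference_control: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in (
            "target_treated",
            "reference_treated",
            "target_control",
            "reference_control",
        ):
            values = getattr(self, name)
            if not values:
                raise ValueError(f"missing Ct values for {name}")
            if any(not math.isfinite(v) or v <= 0 for v in values):
                raise ValueError(f"Ct values for {name} must be finite and positive")


def ddct(ct: CtTable) -> float:
    """Relative expression fold change by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) under treatment minus the same
    difference under control; the fold change is 2 to the power -ddCt.
    """
    d_treated = float(np.mean(ct.target_treated)) - float(np.mean(ct.reference_treated))
    d_control = float(np.mean(ct.target_control)) - float(np.mean(ct.reference_control))
    return 2.0 ** -(d_treated - d_control)
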