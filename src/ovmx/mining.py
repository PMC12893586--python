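"""Per-individual genotype calling and cohort-level variant acceptance.

The substrate is a cohort pileup: per-individual, per-position read counts
over the alleles A, C, G, T and "-" (a single-base deletion observed as a
gap in the reads).  An individual's genotype at a site is called from the
minor-allele read fraction over the two most frequent alleles; a site
becomes an accepted variant when the cohort satisfies all of:

(i)   the variation is seen in an individual with >= 10-fold coverage;
(ii)  some individual has a minor-allele read fraction > 0.45;
(iii) every homozygote carries one of the two alleles seen in the
      heterozygotes, or all homozygotes are homozygous non-reference;
(iv)  at least two heterozygotes exist and all heterozygotes show the
      same substitution;

and the site lies in a "suitable coverage region": a position where the
summed depth of individuals with >= 10-fold coverage exceeds 99 reads.

Genotype-calling thresholds: hom if the minor fraction is <= 0.10, het if
>= 0.25, ambiguous in between — an explicit uncertain band separating
sequencing error from true heterozygosity at 10-fold depth or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .consequence import classify_substitution

__all__ = [
    "ALLELES",
    "SiteCounts",
    "CohortPileup",
    "GenotypeCall",
    "CriteriaFlags",
    "VariantRecord",
    "call_genotype",
    "suitable_coverage_regions",
    "apply_cohort_criteria",
    "mine_variants",
    "MIN_DEPTH",
    "REGION_SUM_MIN",
    "MINOR_FRACTION_CRIT",
]

ALLELES: tuple[str, ...] = ("A", "C", "G", "T", "-")
_ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}

MIN_DEPTH = 10  # criterion (i): per-individual qualifying coverage
REGION_SUM_MIN = 99  # suitable coverage region: pooled qualified depth must exceed this
MINOR_FRACTION_CRIT = 0.45  # criterion (ii): strict lower bound
HOM_MAX_MINOR = 0.10
HET_MIN_MINOR = 0.25
THIRD_ALLELE_MAX = 0.10  # a third allele above this fraction marks the call ambiguous


@dataclass(frozen=True)
class SiteCounts:
    """Read counts of one individual at one position."""

    individual_id: str
    position: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for a, c in self.counts.items():
            if a not in _ALLELE_INDEX:
                raise ValueError(f"unknown allele {a!r}")
            if c < 0:
                raise ValueError(f"negative read count for {a}")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class GenotypeCall:
    """Diploid genotype call with its supporting minor-allele fraction."""

    state: str  # hom_ref | het | hom_alt | ambiguous | missing
    alleles: tuple[str, ...]  # one or two alleles; empty when missing
    minor_fraction: float  # in [0, 0.5]; 0 when missing

    @property
    def is_het(self) -> bool:
        return self.state == "het"

    @property
    def is_hom(self) -> bool:
        return self.state in ("hom_ref", "hom_alt")


def call_genotype(
    site: SiteCounts,
    hom_max_minor: float = HOM_MAX_MINOR,
    het_min_minor: float = HET_MIN_MINOR,
    reference: str | None = None,
    min_depth: int = MIN_DEPTH,
) -> GenotypeCall:
    """Call one individual's genotype from allele read counts.

    Missing below ``min_depth``; otherwise the two most frequent alleles
    define the call via their minor fraction m: hom if m <= hom_max_minor,
    het if m >= het_min_minor, ambiguous in between.  A third allele above
    10% of depth also yields ambiguous.  Ties between equally supported
    alleles are broken in the fixed order A, C, G, T, "-".
    """
    if not 0 <= hom_max_minor < het_min_minor <= 0.5:
        raise ValueError("need 0 <= hom_max_minor < het_min_minor <= 0.5")
    depth = site.depth
    if depth < min_depth:
        return GenotypeCall(state="missing", alleles=(), minor_fraction=0.0)
    ranked = sorted(
        ALLELES, key=lambda a: (-site.counts.get(a, 0), _ALLELE_INDEX[a])
    )
    major, minor = ranked[0], ranked[1]
    c_major = site.counts.get(major, 0)
    c_minor = site.counts.get(minor, 0)
    c_third = site.counts.get(ranked[2], 0)
    m = c_minor / (c_major + c_minor) if c_major + c_minor else 0.0
    if c_third > THIRD_ALLELE_MAX * depth:
        return GenotypeCall(state="ambiguous", alleles=(major, minor), minor_fraction=m)
    if m >= het_min_minor:
        return GenotypeCall(state="het", alleles=(major, minor), minor_fraction=m)
    if m <= hom_max_minor:
        state = "hom_alt" if reference is not None and major != reference else "hom_ref"
        return GenotypeCall(state=state, alleles=(major,), minor_fraction=m)
    return GenotypeCall(state="ambiguous", alleles=(major, minor), minor_fraction=m)


class CohortPileup:
    """Per-individual, per-position allele read counts for a cohort.

    Counts live in an integer array of shape (individuals, positions,
    alleles) with the allele axis ordered A, C, G, T, "-"; ``positions``
    is a sorted 1-based coordinate array and ``reference`` the reference
    base at each of those positions.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        positions: Sequence[int] | np.ndarray,
        reference: str,
        counts: np.ndarray,
    ) -> None:
        self.individuals = list(individuals)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.reference = reference.upper()
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.shape != (len(self.individuals), len(self.positions), len(ALLELES)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.positions)} positions"
            )
        if len(self.reference) != len(self.positions):
            raise ValueError("reference length must match number of positions")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("negative read counts")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def depth(self) -> np.ndarray:
        """(individuals, positions) summed read depth."""
        return self.counts.sum(axis=2)

    def site(self, individual: int | str, position: int) -> SiteCounts:
        """SiteCounts for one (individual, 1-based genomic position) pair."""
        i = (
            individual
            if isinstance(individual, int)
            else self.individuals.index(individual)
        )
        j = int(np.searchsorted(self.positions, position))
        if j >= len(self.positions) or self.positions[j] != position:
            raise KeyError(f"position {position} not in pileup")
        row = self.counts[i, j]
        return SiteCounts(
            individual_id=self.individuals[i],
            position=position,
            counts={a: int(row[k]) for k, a in enumerate(ALLELES) if row[k] > 0},
        )

    def ref_base(self, position: int) -> str:
        j = int(np.searchsorted(self.positions, position))
        if j >= len(self.positions) or self.positions[j] != position:
            raise KeyError(f"position {position} not in pileup")
        return self.reference[j]


def suitable_coverage_regions(
    pileup: CohortPileup,
    min_depth: int = MIN_DEPTH,
    region_sum_min: int = REGION_SUM_MIN,
) -> list[tuple[int, int]]:
    """Maximal intervals where pooled qualified depth exceeds the threshold.

    At each position, individuals with depth >= ``min_depth`` contribute
    their full depth and all others contribute nothing; the position
    qualifies when the sum strictly exceeds ``region_sum_min``.  Adjacent
    qualifying positions merge into 1-based inclusive intervals.
    """
    if pileup.n_positions == 0:
        return []
    depth = pileup.depth()
    qualified = np.where(depth >= min_depth, depth, 0).sum(axis=0)
    ok = qualified > region_sum_min
    regions: list[tuple[int, int]] = []
    start = None
    prev = None
    for pos, flag in zip(pileup.positions, ok):
        pos = int(pos)
        if flag and start is None:
            start = prev = pos
        elif flag and pos == prev + 1:
            prev = pos
        elif flag:  # qualifying but not adjacent: close and reopen
            regions.append((start, prev))
            start = prev = pos
        elif start is not None:
            regions.append((start, prev))
            start = None
    if start is not None:
        regions.append((start, prev))
    return regions


@dataclass(frozen=True)
class CriteriaFlags:
    """Pass/fail of the four cohort filter criteria plus region membership."""

    depth_support: bool  # (i)
    minor_fraction: bool  # (ii)
    hom_consistency: bool  # (iii)
    het_agreement: bool  # (iv)
    in_coverage_region: bool

    @property
    def all_pass(self) -> bool:
        return (
            self.depth_support
            and self.minor_fraction
            and self.hom_consistency
            and self.het_agreement
            and self.in_coverage_region
        )


def apply_cohort_criteria(
    calls: Mapping[str, GenotypeCall],
    reference: str,
    alt: str,
    in_coverage_region: bool = True,
) -> CriteriaFlags:
    """Evaluate the four cohort filter criteria for one candidate variant.

    ``calls`` maps individual id to its genotype call at the site;
    ambiguous calls are excluded from (iii) and (iv), missing calls from
    everything.
    """
    informative = {k: c for k, c in calls.items() if c.state != "missing"}
    hets = [c for c in informative.values() if c.is_het]
    homs = [c for c in informative.values() if c.is_hom]

    # (i): the variation is observed in a genotype call at qualifying depth
    flag_i = any(alt in c.alleles for c in informative.values())

    # (ii): some individual's top-two alleles are {reference, alt} with a
    # strictly > 0.45 minor fraction
    flag_ii = any(
        set(c.alleles) == {reference, alt} and c.minor_fraction > MINOR_FRACTION_CRIT
        for c in informative.values()
        if len(c.alleles) == 2
    )

    # (iii): homozygote alleles drawn from the heterozygote pair, or all
    # homozygotes non-reference
    het_alleles: set[str] = set()
    for c in hets:
        het_alleles.update(c.alleles)
    all_homs_nonref = bool(homs) and all(c.alleles[0] != reference for c in homs)
    homs_in_het_pair = bool(hets) and all(c.alleles[0] in het_alleles for c in homs)
    flag_iii = homs_in_het_pair or all_homs_nonref or not homs

    # (iv): >= 2 heterozygotes, all showing the same substitution
    pairs = {frozenset(c.alleles) for c in hets}
    flag_iv = len(hets) >= 2 and len(pairs) == 1

    return CriteriaFlags(
        depth_support=flag_i,
        minor_fraction=flag_ii,
        hom_consistency=flag_iii,
        het_agreement=flag_iv,
        in_coverage_region=in_coverage_region,
    )


@dataclass(frozen=True)
class VariantRecord:
    """An observed cohort variant with pooled read statistics and genotypes."""

    position: int
    ref: str
    alt: str
    variant_class: str  # SNP_Ts | SNP_Tv | INDEL
    pooled_variant_reads: int
    pooled_total_reads: int
    n_carriers: int
    n_genotyped: int
    genotypes: Mapping[str, GenotypeCall]
    criteria: CriteriaFlags

    def __post_init__(self) -> None:
        if not 0 <= self.pooled_variant_reads <= self.pooled_total_reads:
            raise ValueError("pooled read counts inconsistent")
        if self.n_carriers > self.n_genotyped:
            raise ValueError("more carriers than genotyped animals")

    @property
    def f_alt(self) -> float:
        """Pooled alternative-allele read frequency (full precision)."""
        if self.pooled_total_reads == 0:
            return 0.0
        return self.pooled_variant_reads / self.pooled_total_reads

    @property
    def f_alt_reported(self) -> float:
        """f(alt) rounded to two decimals, the table-reporting convention."""
        return round(self.f_alt, 2)

    @property
    def accepted(self) -> bool:
        return self.criteria.all_pass


def _variant_class(ref: str, alt: str) -> str:
    if ref == "-" or alt == "-":
        return "INDEL"
    return f"SNP_{classify_substitution(ref, alt)}"


def mine_variants(
    pileup: CohortPileup,
    hom_max_minor: float = HOM_MAX_MINOR,
    het_min_minor: float = HET_MIN_MINOR,
    min_depth: int = MIN_DEPTH,
    region_sum_min: int = REGION_SUM_MIN,
    accepted_only: bool = False,
) -> list[VariantRecord]:
    """Mine cohort variants from a pileup.

    Emits a :class:`VariantRecord` for every position inside a suitable
    coverage region where any individual's genotype call contains a
    non-reference allele; pooled read counts are taken over individuals
    with qualifying depth at the site.  Records are sorted by position.
    """
    regions = suitable_coverage_regions(pileup, min_depth, region_sum_min)
    in_region = np.zeros(pileup.n_positions, dtype=bool)
    for a, b in regions:
        lo = np.searchsorted(pileup.positions, a)
        hi = np.searchsorted(pileup.positions, b, side="right")
        in_region[lo:hi] = True

    depth = pileup.depth()  # (I, P)
    qualified = depth >= min_depth
    ref_idx = np.array([_ALLELE_INDEX[b] for b in pileup.reference])
    nonref_counts = pileup.counts.copy()
    nonref_counts[:, np.arange(pileup.n_positions), ref_idx] = 0
    # candidate screen: any qualified individual whose non-reference reads
    # could enter its called alleles (top-two), i.e. >= het band or a hom
    # majority that is non-reference
    nonref_any = (nonref_counts.sum(axis=2) > 0) & qualified
    candidate_cols = np.nonzero(in_region & nonref_any.any(axis=0))[0]

    records: list[VariantRecord] = []
    for j in candidate_cols:
        position = int(pileup.positions[j])
        ref = pileup.reference[j]
        calls: dict[str, GenotypeCall] = {}
        any_nonref_call = False
        for i, ind in enumerate(pileup.individuals):
            row = pileup.counts[i, j]
            site = SiteCounts(
                individual_id=ind,
                position=position,
                counts={a: int(row[k]) for k, a in enumerate(ALLELES) if row[k] > 0},
            )
            call = call_genotype(
                site, hom_max_minor, het_min_minor, reference=ref, min_depth=min_depth
            )
            calls[ind] = call
            if call.state != "missing" and any(a != ref for a in call.alleles):
                any_nonref_call = True
        if not any_nonref_call:
            continue
        # the alternative allele: the non-reference allele with the highest
        # pooled read support over qualified individuals
        pooled = pileup.counts[:, j][qualified[:, j]].sum(axis=0)
        nonref_order = sorted(
            (a for a in ALLELES if a != ref),
            key=lambda a: (-pooled[_ALLELE_INDEX[a]], _ALLELE_INDEX[a]),
        )
        alt = nonref_order[0]
        flags = apply_cohort_criteria(calls, ref, alt, in_coverage_region=True)
        n_genotyped = sum(1 for c in calls.values() if c.state != "missing")
        n_carriers = sum(
            1
            for c in calls.values()
            if c.state in ("het", "hom_alt") and alt in c.alleles
        )
        rec = VariantRecord(
            position=position,
            ref=ref,
            alt=alt,
            variant_class=_variant_class(ref, alt),
            pooled_variant_reads=int(pooled[_ALLELE_INDEX[alt]]),
            pooled_total_reads=int(pooled.sum()),
            n_carriers=n_carriers,
            n_genotyped=n_genotyped,
            genotypes=calls,
            criteria=flags,
        )
        if not accepted_only or rec.accepted:
            records.append(rec)
    return records
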