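"""Genotype calling, coverage regions and the cohort filter criteria."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovmx.mining import (
    ALLELES,
    CohortPileup,
    GenotypeCall,
    SiteCounts,
    apply_cohort_criteria,
    call_genotype,
    mine_variants,
    suitable_coverage_regions,
)
from conftest import make_pileup
from oracles import oracle_criteria


def _site(counts: dict, ind: str = "x", pos: int = 1) -> SiteCounts:
    return SiteCounts(individual_id=ind, position=pos, counts=counts)


class TestCallGenotype:
    def test_balanced_het(self):
        call = call_genotype(_site({"A": 10, "G": 10}), reference="A")
        assert call.state == "het"
        assert set(call.alleles) == {"A", "G"}
        assert call.minor_fraction == 0.5

    def test_pure_hom_ref(self):
        call = call_genotype(_site({"A": 20}), reference="A")
        assert call.state == "hom_ref" and call.alleles == ("A",)

    def test_pure_hom_alt(self):
        call = call_genotype(_site({"G": 20}), reference="A")
        assert call.state == "hom_alt" and call.alleles == ("G",)

    def test_depth_below_ten_is_missing(self):
        call = call_genotype(_site({"A": 5, "G": 4}), reference="A")
        assert call.state == "missing"

    def test_het_boundary_inclusive(self):
        # 6/24 = 0.25 sits exactly on the het threshold and is called het
        call = call_genotype(_site({"A": 18, "G": 6}), reference="A")
        assert call.state == "het"
        assert call.minor_fraction == pytest.approx(0.25)

    def test_ambiguous_band(self):
        call = call_genotype(_site({"A": 17, "G": 3}), reference="A")  # m = 0.15
        assert call.state == "ambiguous"

    def test_gap_allele_forms_het(self):
        call = call_genotype(_site({"C": 11, "-": 9}), reference="C")
        assert call.state == "het" and "-" in call.alleles

    def test_third_allele_marks_ambiguous(self):
        call = call_genotype(_site({"A": 12, "G": 10, "T": 4}), reference="A")
        assert call.state == "ambiguous"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _site({"A": -1})

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            call_genotype(_site({"A": 20}), hom_max_minor=0.3, het_min_minor=0.2)


class TestSuitableCoverageRegions:
    def test_sum_rule(self):
        # 5 individuals at depth 20 -> 100 > 99 qualifies; depth 10 each -> 50 fails
        ref = "AAAA"
        sites = {
            f"i{k}": {1: {"A": 20}, 2: {"A": 10}, 3: {"A": 20}, 4: {"A": 20}}
            for k in range(5)
        }
        pileup = make_pileup(sites, ref)
        assert suitable_coverage_regions(pileup) == [(1, 1), (3, 4)]

    def test_subthreshold_individual_contributes_nothing(self):
        # ten at depth 10 sum to 100; an eleventh at depth 9 is dropped
        sites = {f"i{k}": {1: {"A": 10}} for k in range(10)}
        sites["low"] = {1: {"A": 9}}
        pileup = make_pileup(sites, "A")
        assert suitable_coverage_regions(pileup) == [(1, 1)]

    def test_empty_pileup(self):
        pileup = make_pileup({"i0": {}}, "ACGT")
        assert suitable_coverage_regions(pileup) == []


def _call(state, alleles, mf):
    return GenotypeCall(state=state, alleles=alleles, minor_fraction=mf)


class TestCohortCriteria:
    def test_two_hets_and_consistent_hom_pass_all(self):
        calls = {
            "a": _call("het", ("A", "G"), 0.5),
            "b": _call("het", ("A", "G"), 0.5),
            "c": _call("hom_ref", ("A",), 0.0),
        }
        flags = apply_cohort_criteria(calls, reference="A", alt="G")
        assert flags.all_pass

    def test_single_het_fails_het_agreement(self):
        calls = {
            "a": _call("het", ("A", "G"), 0.5),
            "b": _call("hom_ref", ("A",), 0.0),
            "c": _call("hom_ref", ("A",), 0.0),
        }
        flags = apply_cohort_criteria(calls, reference="A", alt="G")
        assert not flags.het_agreement
        assert flags.depth_support and flags.minor_fraction

    def test_discordant_het_types_fail(self):
        calls = {
            "a": _call("het", ("A", "G"), 0.5),
            "b": _call("het", ("A", "C"), 0.5),
        }
        flags = apply_cohort_criteria(calls, reference="A", alt="G")
        assert not flags.het_agreement

    def test_hom_outside_het_pair_fails_consistency(self):
        # a reference homozygote when the het pair lacks the reference:
        # neither "in the het pair" nor "all homozygotes non-reference"
        calls = {
            "a": _call("het", ("G", "T"), 0.5),
            "b": _call("het", ("G", "T"), 0.5),
            "c": _call("hom_ref", ("A",), 0.0),
        }
        flags = apply_cohort_criteria(calls, reference="A", alt="G")
        assert not flags.hom_consistency

    def test_third_allele_homozygote_allowed_by_nonref_clause(self):
        # the rule admits homozygotes for *any* non-reference allele when
        # all homozygotes are non-reference
        calls = {
            "a": _call("het", ("A", "G"), 0.5),
            "b": _call("het", ("A", "G"), 0.5),
            "c": _call("hom_alt", ("T",), 0.0),
        }
        flags = apply_cohort_criteria(calls, reference="A", alt="G")
        assert flags.hom_consistency

    def test_all_hom_nonref_satisfies_consistency(self):
        calls = {
            "a": _call("hom_alt", ("G",), 0.0),
            "b": _call("hom_alt", ("G",), 0.0),
        }
        flags = apply_cohort_criteria(calls, reference="A", alt="G")
        assert flags.hom_consistency

    def test_ambiguous_calls_excluded_from_iii_iv(self):
        calls = {
            "a": _call("het", ("A", "G"), 0.5),
            "b": _call("het", ("A", "G"), 0.46),
            "c": _call("ambiguous", ("A", "T"), 0.15),
        }
        flags = apply_cohort_criteria(calls, reference="A", alt="G")
        assert flags.het_agreement and flags.hom_consistency


# --- randomized agreement with the brute-force rule-text oracle ------------

_counts_strategy = st.dictionaries(
    st.sampled_from(ALLELES),
    st.integers(0, 30),
    min_size=0,
    max_size=3,
)


@given(st.data())
@settings(derandomize=True, max_examples=500, deadline=None)
def test_criteria_agree_with_bruteforce_oracle(data):
    """Randomised cohorts (<=5 x <=20): every flag matches the oracle."""
    n_ind = data.draw(st.integers(1, 5))
    n_pos = data.draw(st.integers(1, 20))
    ref = data.draw(
        st.text(alphabet="ACGT", min_size=n_pos, max_size=n_pos)
    )
    for j in range(n_pos):
        calls = {}
        for i in range(n_ind):
            counts = data.draw(_counts_strategy)
            site = SiteCounts(individual_id=f"i{i}", position=j + 1, counts=counts)
            calls[f"i{i}"] = call_genotype(site, reference=ref[j])
        alt = data.draw(st.sampled_from([a for a in ALLELES if a != ref[j]]))
        flags = apply_cohort_criteria(calls, reference=ref[j], alt=alt)
        expected = oracle_criteria(calls, ref[j], alt)
        assert flags.depth_support == expected["i"]
        assert flags.minor_fraction == expected["ii"]
        assert flags.hom_consistency == expected["iii"]
        assert flags.het_agreement == expected["iv"]


# --- mining ----------------------------------------------------------------


def _cohort_with_variant(n_hom_ref=3, n_het=2, n_hom_alt=0, depth=30):
    ref = "ACGTA"
    sites = {}
    k = 0
    for _ in range(n_hom_ref):
        sites[f"r{k}"] = {3: {"G": depth}}
        k += 1
    for _ in range(n_het):
        sites[f"h{k}"] = {3: {"G": depth // 2, "T": depth - depth // 2}}
        k += 1
    for _ in range(n_hom_alt):
        sites[f"a{k}"] = {3: {"T": depth}}
        k += 1
    for ind in sites:
        for p in (1, 2, 4, 5):
            sites[ind][p] = {ref[p - 1]: depth}
    return make_pileup(sites, ref)


def test_mine_accepts_planted_variant():
    pileup = _cohort_with_variant(n_hom_ref=3, n_het=2, depth=30)
    records = mine_variants(pileup)
    assert len(records) == 1
    rec = records[0]
    assert (rec.position, rec.ref, rec.alt) == (3, "G", "T")
    assert rec.variant_class == "SNP_Tv"
    assert rec.accepted
    assert rec.n_carriers == 2 and rec.n_genotyped == 5
    assert rec.pooled_variant_reads == 30 and rec.pooled_total_reads == 150


def test_mine_reports_conservation_of_genotype_states():
    pileup = _cohort_with_variant(n_hom_ref=2, n_het=3, n_hom_alt=1)
    rec = mine_variants(pileup)[0]
    states = [c.state for c in rec.genotypes.values()]
    assert len(states) == pileup.n_individuals


def test_mine_no_variants_on_clean_cohort():
    ref = "ACGT"
    sites = {f"i{k}": {p: {ref[p - 1]: 25} for p in range(1, 5)} for k in range(5)}
    assert mine_variants(make_pileup(sites, ref)) == []


def test_mine_outside_coverage_region_suppressed():
    # only 2 individuals: pooled qualified depth 60 <= 99 -> no suitable region
    pileup = _cohort_with_variant(n_hom_ref=0, n_het=2, depth=30)
    assert mine_variants(pileup) == []


def test_f_alt_monotone_in_alt_reads():
    base = _cohort_with_variant(n_hom_ref=3, n_het=2, depth=30)
    rec0 = mine_variants(base)[0]
    boosted = CohortPileup(
        individuals=base.individuals,
        positions=base.positions,
        reference=base.reference,
        counts=base.counts.copy(),
    )
    t_idx = ALLELES.index("T")
    boosted.counts[0, 2, t_idx] += 15  # more alt-supporting reads
    rec1 = mine_variants(boosted)[0]
    assert rec1.f_alt >= rec0.f_alt


def test_deletion_variant_classified_indel():
    ref = "ACGTA"
    depth = 30
    sites = {}
    for k in range(3):
        sites[f"r{k}"] = {p: {ref[p - 1]: depth} for p in range(1, 6)}
    for k in range(2):
        s = {p: {ref[p - 1]: depth} for p in range(1, 6)}
        s[4] = {"T": 15, "-": 15}
        sites[f"h{k}"] = s
    rec = mine_variants(make_pileup(sites, ref))[0]
    assert rec.alt == "-" and rec.variant_class == "INDEL"
    assert rec.accepted
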