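"""Shared fixtures: small deterministic references, pileup builders."""

from __future__ import annotations

import numpy as np
import pytest

from ovmx.mining import ALLELES, CohortPileup


def make_pileup(site_counts: dict, reference: str, start: int = 1) -> CohortPileup:
    """Build a CohortPileup from {individual: {position: {allele: count}}}.

    Positions not mentioned for an individual get zero depth; ``reference``
    covers positions start .. start+len-1.
    """
    individuals = sorted(site_counts)
    positions = np.arange(start, start + len(reference))
    idx = {a: i for i, a in enumerate(ALLELES)}
    counts = np.zeros((len(individuals), len(reference), len(ALLELES)), dtype=np.int64)
    for i, ind in enumerate(individuals):
        for pos, alleles in site_counts[ind].items():
            j = pos - start
            for a, c in alleles.items():
                counts[i, j, idx[a]] = c
    return CohortPileup(
        individuals=individuals, positions=positions, reference=reference, counts=counts
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_reference(rng):
    return "".join(rng.choice(list("ACGT"), size=400))
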