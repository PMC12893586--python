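"""Simulate a 68-animal resequencing cohort over a toy Mx-like locus.

Plants three variants whose population frequencies mirror the three
headline coding variants of the real cohort: the start-codon SNP
(f_alt = 50/136), the stop-gain SNP (16/136 allele copies: ten het and
three hom carriers among 68), and the rare frameshift deletion (3/136,
three het carriers).  Read depth is Poisson(20) with a 0.5% per-base error
rate.  Writes the pileup, truth genotypes and a run manifest under
results/sim/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from ovmx import io as ovio
from ovmx.simulate import PlantedVariant, SimConfig, simulate_cohort

HERE = Path(__file__).resolve().parent.parent
OUT = HERE / "results" / "sim"


def main(seed: int = 2026) -> None:
    rng = np.random.default_rng(seed)
    reference = "".join(rng.choice(list("ACGT"), size=900))

    def planted(pos, freq, kind="SNP"):
        base = reference[pos - 1]
        alt = "-" if kind == "deletion" else next(a for a in "ACGT" if a != base)
        return PlantedVariant(position=pos, ref=base, alt=alt, frequency=freq, kind=kind)

    variants = (
        planted(3, 50 / 136),     # start-codon-like common SNP
        planted(497, 16 / 136),   # stop-gain-like SNP
        planted(700, 3 / 136, kind="deletion"),  # rare frameshift deletion
    )
    cfg = SimConfig(
        n_individuals=68,
        planted_variants=variants,
        seed=seed,
        mean_depth=20.0,
        error_rate=0.005,
    )
    pileup, truth = simulate_cohort(cfg, reference)

    OUT.mkdir(parents=True, exist_ok=True)
    ovio.write_pileup_tsv(pileup, OUT / "pileup.tsv")
    ovio.write_fasta({"toy_locus": reference}, OUT / "reference.fasta")
    lines = ["individual_id\tposition\ttrue_genotype"]
    for i, ind in enumerate(truth.individuals):
        for k, v in enumerate(truth.variants):
            lines.append(f"{ind}\t{v.position}\t{truth.genotype_state(i, k)}")
    (OUT / "truth_genotypes.tsv").write_text("\n".join(lines) + "\n")
    ovio.write_manifest(
        OUT / "manifest.json",
        config={
            "seed": seed, "n_individuals": 68, "mean_depth": 20.0,
            "error_rate": 0.005,
            "planted": [(v.position, v.ref, v.alt, round(v.frequency, 4)) for v in variants],
        },
        outputs={"pileup": OUT / "pileup.tsv", "truth": OUT / "truth_genotypes.tsv"},
    )
    print(f"simulated 68 animals x 900 bp; realised allele fractions: "
          f"{[round(f, 3) for f in truth.true_f_alt]}")
    print(f"wrote {OUT / 'pileup.tsv'}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=2026)
    main(parser.parse_args().seed)
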