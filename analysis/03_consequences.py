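"""Annotate the published coding variants of both Mx genes.

Builds fixture coding sequences consistent with every published variant row
(codon number, nucleotide change, amino-acid consequence), annotates each
row, and reports the two null alleles — the stop gain at codon 166 and the
frameshift deletion in codon 329 — together with per-gene protein-altering
counts (expected: 3 for MX1, 6 for MX2).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ovmx.consequence import count_protein_altering
from ovmx.mx_tables import (
    MX1_CODING_VARIANTS,
    MX2_CODING_VARIANTS,
    annotate_rows,
    mx1_fixture_cds,
    mx2_fixture_cds,
)

HERE = Path(__file__).resolve().parent.parent
OUT = HERE / "results" / "consequences"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frames = []
    for gene, rows, cds in (
        ("MX1", MX1_CODING_VARIANTS, mx1_fixture_cds()),
        ("MX2", MX2_CODING_VARIANTS, mx2_fixture_cds()),
    ):
        annotated = annotate_rows(rows, cds)
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "codon": [c.codon_number for c in annotated],
                    "hgvs_c": [c.hgvs_c for c in annotated],
                    "hgvs_p": [c.hgvs_p() for c in annotated],
                    "class": [c.consequence_class for c in annotated],
                    "type": [
                        "INDEL" if r.is_deletion else "SNP" for r in rows
                    ],
                    "f_alt": [r.f_alt_reported for r in rows],
                }
            )
        )
        n_alter = count_protein_altering(annotated)
        print(f"{gene}: {len(rows)} coding variants, {n_alter} protein-altering")
        for c in annotated:
            if c.consequence_class in ("nonsense", "frameshift"):
                extra = f" novel peptide {c.fs_peptide} (stop {c.stop_offset}th codon)" \
                    if c.fs_peptide else ""
                print(f"  null allele: {c.hgvs_c} -> {c.hgvs_p()}{extra}")
    pd.concat(frames).to_csv(OUT / "consequence_table.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'consequence_table.tsv'}")


if __name__ == "__main__":
    main()
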