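"""Published coding-variant tables for the ovine Mx genes, and fixture CDSs.

The coding variants reported for ovine *MX1* and *MX2* are given as codon
number, nucleotide change, pooled read counts and the reference/alternative
amino acids.  The underlying nucleotide sequences are not printed, so for
desk-scale analysis we build *fixture* coding sequences that are consistent
with every printed row: each substitution is placed at the unique
intra-codon offset (and reference codon) for which the reference amino acid
and the printed consequence both hold, found by exhaustive search over the
synonymous codons of the reference residue and the three offsets.

The frameshift region around codon 329 of *MX2* is pinned explicitly:
codons 329-336 read CAG CAG GAT ATC ACC AAC AAG CTG and codon 337 begins
with A, so that deleting c.985 shifts the frame to
Ser.Arg.Ile.Ser.Pro.Thr.Ser followed by a stop (p.Q329Sfs7*).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "CodingVariantRow",
    "MX1_CODING_VARIANTS",
    "MX2_CODING_VARIANTS",
    "FLOCK_ALLELE_TABLE",
    "build_fixture_cds",
    "mx1_fixture_cds",
    "mx2_fixture_cds",
]

_AA1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "STOP": "*",
}


@dataclass(frozen=True)
class CodingVariantRow:
    """One published coding-variant row: codon, change, pooled read support."""

    codon: int
    ref_nt: str  # reference nucleotide; for the deletion row, the deleted base
    alt_nt: str | None  # None marks the single-nucleotide deletion
    variant_reads: int
    total_reads: int
    carriers: int
    genotyped: int
    ref_aa: str  # one-letter reference residue
    alt_aa: str | None  # None = synonymous ("no" change); '*' = stop; 'fs' n/a

    @property
    def is_deletion(self) -> bool:
        return self.alt_nt is None

    @property
    def f_alt_reported(self) -> float:
        return round(self.variant_reads / self.total_reads, 2)


def _row(codon, change, reads, animals, ref_aa, alt_aa):
    ref_nt, alt_nt = change
    v, t = reads
    c, g = animals
    return CodingVariantRow(
        codon=codon,
        ref_nt=ref_nt,
        alt_nt=alt_nt,
        variant_reads=v,
        total_reads=t,
        carriers=c,
        genotyped=g,
        ref_aa=_AA1[ref_aa],
        alt_aa=None if alt_aa == "no" else _AA1[alt_aa],
    )


#: 11 coding SNPs in MX1 (codon, ref>alt, reads variant/total, animals, aa change)
MX1_CODING_VARIANTS: tuple[CodingVariantRow, ...] = (
    _row(16, ("C", "T"), (166, 878), (18, 57), "Ser", "no"),
    _row(17, ("G", "A"), (136, 876), (12, 57), "Gly", "Ser"),
    _row(30, ("T", "C"), (796, 801), (52, 52), "Met", "Thr"),
    _row(80, ("T", "C"), (200, 569), (24, 40), "Ser", "no"),
    _row(125, ("G", "A"), (281, 741), (30, 51), "Glu", "no"),
    _row(288, ("C", "T"), (142, 692), (18, 46), "Asp", "no"),
    _row(323, ("C", "G"), (104, 681), (14, 47), "Thr", "no"),
    _row(390, ("C", "T"), (25, 629), (4, 44), "Leu", "no"),
    _row(452, ("A", "G"), (7, 700), (2, 51), "Ile", "Val"),
    _row(575, ("G", "A"), (26, 735), (3, 49), "Ala", "no"),
    _row(579, ("A", "G"), (74, 411), (8, 32), "Glu", "no"),
)

#: 17 coding variants in MX2, including the stop-gain at codon 166 and the
#: 1-bp deletion (frameshift) in codon 329.
MX2_CODING_VARIANTS: tuple[CodingVariantRow, ...] = (
    _row(1, ("A", "G"), (254, 551), (27, 39), "Met", "Val"),
    _row(28, ("T", "C"), (557, 585), (40, 40), "Phe", "no"),
    _row(64, ("A", "C"), (42, 612), (4, 43), "Asn", "His"),
    _row(85, ("C", "T"), (318, 674), (28, 43), "Pro", "Ser"),
    _row(166, ("G", "A"), (79, 627), (9, 44), "Trp", "STOP"),
    _row(175, ("G", "A"), (282, 619), (32, 46), "Val", "no"),
    _row(329, ("C", None), (14, 689), (3, 49), "Gln", "no"),  # frameshift
    _row(376, ("G", "A"), (54, 641), (7, 44), "Glu", "no"),
    _row(378, ("T", "C"), (58, 672), (8, 47), "Ile", "no"),
    _row(422, ("T", "C"), (140, 527), (19, 38), "Ile", "no"),
    _row(561, ("G", "A"), (582, 735), (48, 50), "Ala", "no"),
    _row(584, ("C", "T"), (56, 760), (7, 51), "Tyr", "no"),
    _row(598, ("C", "T"), (108, 743), (15, 51), "Ser", "no"),
    _row(608, ("A", "G"), (580, 688), (44, 46), "Ser", "no"),
    _row(616, ("G", "A"), (192, 728), (21, 49), "Gln", "no"),
    _row(697, ("C", "A"), (621, 781), (50, 53), "Arg", "no"),
    _row(713, ("G", "A"), (32, 727), (4, 49), "Gly", "Ser"),
)

#: Published exon-5 allele frequencies in the four closed Merino flocks:
#: flock -> locus -> (reference-allele frequency, alternative, n animals).
#: Loci: the stop-gain W166*, the missense T167A and the synonymous V175V.
#: (The V175V row for TSFS prints n = 2 in the source table, read as 20.)
FLOCK_ALLELE_TABLE: dict[str, dict[str, tuple[float, float, int]]] = {
    "HSFR": {"W166*": (0.5, 0.5, 33), "T167A": (0.1, 0.9, 20), "V175V": (0.625, 0.375, 20)},
    "HSFS": {"W166*": (0.75, 0.25, 20), "T167A": (0.05, 0.95, 20), "V175V": (0.4, 0.6, 20)},
    "TSFR": {"W166*": (1.0, 0.0, 20), "T167A": (0.1, 0.9, 20), "V175V": (0.075, 0.925, 20)},
    "TSFS": {"W166*": (1.0, 0.0, 20), "T167A": (0.05, 0.95, 20), "V175V": (0.05, 0.95, 20)},
}

#: Codons 329-336 of the MX2 fixture, chosen so that deleting the first base
#: of codon 329 reads Ser.Arg.Ile.Ser.Pro.Thr.Ser.STOP in the shifted frame
#: (the stop uses the first base of codon 337, which must be A).
_MX2_FRAMESHIFT_CODONS = {
    329: "CAG", 330: "CAG", 331: "GAT", 332: "ATC",
    333: "ACC", 334: "AAC", 335: "AAG", 336: "CTG",
    337: "ATT",  # first base A completes the TGA stop in the shifted frame
}

_FILLER = "GCT"  # alanine filler for unconstrained codons


def _codons_for(aa: str, table_id: int = 1) -> list[str]:
    table = unambiguous_dna_by_id[table_id]
    if aa == "*":
        return sorted(table.stop_codons)
    return sorted(c for c, a in table.forward_table.items() if a == aa)


def _pick_codon(row: CodingVariantRow, table_id: int = 1) -> str:
    """Reference codon + offset consistent with a printed substitution row.

    Searches the synonymous codons of the reference residue and the three
    intra-codon offsets for a placement whose substituted codon encodes the
    printed alternative residue (or the same residue for synonymous rows).
    Deterministic: candidate codons and offsets are scanned in sorted order.
    """
    table = unambiguous_dna_by_id[table_id]

    def aa_of(codon: str) -> str:
        return "*" if codon in table.stop_codons else table.forward_table[codon]

    want_alt = row.ref_aa if row.alt_aa is None else row.alt_aa
    for codon in _codons_for(row.ref_aa, table_id):
        for off in (1, 2, 3):
            if codon[off - 1] != row.ref_nt:
                continue
            alt_codon = codon[: off - 1] + row.alt_nt + codon[off:]
            if alt_codon == codon:
                continue
            if aa_of(alt_codon) == want_alt:
                return codon
    raise ValueError(f"no codon placement consistent with row at codon {row.codon}")


def build_fixture_cds(
    rows: tuple[CodingVariantRow, ...],
    n_codons: int,
    pinned: dict[int, str] | None = None,
) -> str:
    """Fixture CDS consistent with every printed variant row.

    Unconstrained codons are alanine filler; ``pinned`` codons (e.g. the
    frameshift region) override both filler and search.  A stop codon is
    appended after ``n_codons`` sense codons.
    """
    pinned = dict(pinned or {})
    codons = {n: _FILLER for n in range(1, n_codons + 1)}
    codons.update(pinned)
    for row in rows:
        if row.codon in pinned:
            continue
        if row.is_deletion:
            raise ValueError(f"deletion row at codon {row.codon} must be pinned")
        codons[row.codon] = _pick_codon(row)
    return "".join(codons[n] for n in range(1, n_codons + 1)) + "TAA"


def mx1_fixture_cds() -> str:
    """Fixture CDS for the 11 MX1 coding SNPs (654 sense codons)."""
    return build_fixture_cds(MX1_CODING_VARIANTS, n_codons=654)


def mx2_fixture_cds() -> str:
    """Fixture CDS for the 17 MX2 coding variants (714 sense codons), with
    the codon 329-337 frameshift region pinned."""
    return build_fixture_cds(
        MX2_CODING_VARIANTS, n_codons=714, pinned=_MX2_FRAMESHIFT_CODONS
    )


def annotate_rows(rows: tuple[CodingVariantRow, ...], cds: str):
    """Annotate every row of a printed table against a fixture CDS.

    Substitution rows are placed at the intra-codon offset where the fixture
    base equals the printed reference nucleotide; the deletion row is
    annotated at the first base of its codon.
    """
    from .consequence import annotate_deletion, annotate_snp

    out = []
    for row in rows:
        base = 3 * (row.codon - 1)
        if row.is_deletion:
            out.append(annotate_deletion(cds, base + 1))
            continue
        offsets = [i for i in (1, 2, 3) if cds[base + i - 1] == row.ref_nt]
        for off in offsets:
            ann = annotate_snp(cds, base + off, row.alt_nt)
            want = row.ref_aa if row.alt_aa is None else row.alt_aa
            if (ann.alt_aa == want) and ann.ref_aa == row.ref_aa:
                out.append(ann)
                break
        else:
            raise ValueError(f"fixture inconsistent with row at codon {row.codon}")
    return out
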