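"""Codon-level consequence annotation of coding SNPs and 1-bp deletions.

Substitutions are classified as synonymous / missense / nonsense (and
transition vs transversion); single-nucleotide deletions are translated in
the shifted frame to the next stop codon, yielding the novel peptide, its
length and the ordinal position of the premature stop.

Two frameshift label conventions are supported: the compact convention in
which ``fsN*`` counts the N novel residues translated before the stop
(``p.Q329Sfs7*`` = 7 novel residues, stop as the 8th altered codon), and
standard HGVS ``fsTer`` notation which counts the stop position itself
(``p.Gln329SerfsTer8``).  Both numbers are stored; the compact form is the
default output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

__all__ = [
    "Consequence",
    "classify_substitution",
    "annotate_snp",
    "annotate_deletion",
    "count_protein_altering",
    "parse_hgvs_c",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


def classify_substitution(ref: str, alt: str) -> str:
    """Transition ("Ts": purine↔purine or pyrimidine↔pyrimidine) vs
    transversion ("Tv")."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"nucleotides must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    pair = {ref, alt}
    return "Ts" if pair <= _PURINES or pair <= _PYRIMIDINES else "Tv"


@dataclass(frozen=True)
class Consequence:
    """Annotated coding consequence of a SNP or 1-bp deletion."""

    cds_pos: int
    codon_number: int
    ref_codon: str
    alt_codon: str | None  # None for frameshifts
    ref_aa: str  # one-letter, '*' for stop
    alt_aa: str | None
    consequence_class: str  # synonymous|missense|nonsense|frameshift|stop_lost
    fs_peptide: str | None = None  # novel residues before the stop (frameshift)
    fs_len: int | None = None
    stop_offset: int | None = None  # stop position, first altered codon = 1
    note: str | None = None
    ref_nt: str | None = None
    alt_nt: str | None = None

    @property
    def hgvs_c(self) -> str:
        if self.alt_nt is None:  # deletion
            return f"c.{self.cds_pos}del"
        return f"c.{self.cds_pos}{self.ref_nt}>{self.alt_nt}"

    def hgvs_p(self, style: str = "compact") -> str:
        """Protein-level label.

        ``style="compact"`` uses one-letter residues and the compact fsN*
        convention; ``style="hgvs"`` uses three-letter residues and
        fsTer notation.
        """
        if self.consequence_class == "frameshift":
            first_new = self.fs_peptide[0] if self.fs_peptide else "*"
            if style == "compact":
                return f"p.{self.ref_aa}{self.codon_number}{first_new}fs{self.fs_len}*"
            return (
                f"p.{AA3[self.ref_aa]}{self.codon_number}{AA3[first_new]}"
                f"fsTer{self.stop_offset}"
            )
        assert self.alt_aa is not None
        ref, alt = self.ref_aa, self.alt_aa
        if style == "compact":
            alt_sym = "*" if alt == "*" else alt
            if self.consequence_class == "synonymous":
                return f"p.{ref}{self.codon_number}{ref}"
            return f"p.{ref}{self.codon_number}{alt_sym}"
        return f"p.{AA3[ref]}{self.codon_number}{AA3[alt]}"


def _translate_codon(codon: str, table_id: int = 1) -> str:
    table = unambiguous_dna_by_id[table_id]
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def annotate_snp(cds: str, cds_pos: int, alt: str, table_id: int = 1) -> Consequence:
    """Annotate a coding substitution at a 1-based CDS position.

    The genetic code table is injectable (NCBI table id; default standard).
    """
    cds = cds.upper()
    alt = alt.upper()
    if len(cds) % 3 != 0 or not cds:
        raise ValueError("CDS length must be a positive multiple of 3")
    if not 1 <= cds_pos <= len(cds):
        raise ValueError(f"cds_pos {cds_pos} outside 1..{len(cds)}")
    ref = cds[cds_pos - 1]
    if alt == ref:
        raise ValueError(f"alt equals reference base {ref} at c.{cds_pos}")
    if alt not in "ACGT":
        raise ValueError(f"alt must be A/C/G/T, got {alt!r}")
    codon_number = (cds_pos + 2) // 3
    offset = cds_pos - 3 * (codon_number - 1)
    ref_codon = cds[3 * (codon_number - 1) : 3 * codon_number]
    alt_codon = ref_codon[: offset - 1] + alt + ref_codon[offset:]
    ref_aa = _translate_codon(ref_codon, table_id)
    alt_aa = _translate_codon(alt_codon, table_id)
    note = None
    if ref_aa == alt_aa:
        cls = "synonymous"
    elif alt_aa == "*":
        cls = "nonsense"
    elif ref_aa == "*":
        cls = "stop_lost"
    else:
        cls = "missense"
        if codon_number == 1 and ref_aa == "M":
            # the functional start may move; flagged, not reclassified
            note = "start_lost_candidate"
    return Consequence(
        cds_pos=cds_pos,
        codon_number=codon_number,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence_class=cls,
        note=note,
        ref_nt=ref,
        alt_nt=alt,
    )


def annotate_deletion(cds: str, cds_pos: int, table_id: int = 1) -> Consequence:
    """Annotate a single-nucleotide coding deletion.

    The edited sequence is translated from the first affected codon in the
    shifted frame until a stop codon; ``fs_peptide`` holds the novel
    residues up to but excluding the stop, and ``stop_offset`` the ordinal
    position of the stop counting the first altered codon as 1.  If no stop
    is reached before the sequence ends the class is ``stop_lost``.
    """
    cds = cds.upper()
    if not 1 <= cds_pos <= len(cds):
        raise ValueError(f"cds_pos {cds_pos} outside 1..{len(cds)}")
    codon_number = (cds_pos + 2) // 3
    ref_codon = cds[3 * (codon_number - 1) : 3 * codon_number]
    ref_aa = _translate_codon(ref_codon, table_id)
    edited = cds[: cds_pos - 1] + cds[cds_pos:]
    tail = edited[3 * (codon_number - 1) :]
    peptide = []
    stop_offset = None
    for i in range(0, len(tail) - len(tail) % 3, 3):
        aa = _translate_codon(tail[i : i + 3], table_id)
        if aa == "*":
            stop_offset = i // 3 + 1
            break
        peptide.append(aa)
    fs_peptide = "".join(peptide)
    if stop_offset is None:
        return Consequence(
            cds_pos=cds_pos,
            codon_number=codon_number,
            ref_codon=ref_codon,
            alt_codon=None,
            ref_aa=ref_aa,
            alt_aa=None,
            consequence_class="stop_lost",
            fs_peptide=fs_peptide,
            fs_len=len(fs_peptide),
            stop_offset=None,
            note="no stop found before end of sequence",
            ref_nt=cds[cds_pos - 1],
            alt_nt=None,
        )
    return Consequence(
        cds_pos=cds_pos,
        codon_number=codon_number,
        ref_codon=ref_codon,
        alt_codon=None,
        ref_aa=ref_aa,
        alt_aa=None,
        consequence_class="frameshift",
        fs_peptide=fs_peptide,
        fs_len=len(fs_peptide),
        stop_offset=stop_offset,
        ref_nt=cds[cds_pos - 1],
        alt_nt=None,
    )


def count_protein_altering(records: Iterable[Consequence]) -> int:
    """Number of consequences that change the protein (class != synonymous)."""
    return sum(1 for r in records if r.consequence_class != "synonymous")


_HGVS_C_RE = re.compile(r"^c\.(\d+)(?:([ACGT])>([ACGT])|del)$")


def parse_hgvs_c(label: str) -> tuple[int, str | None, str | None]:
    """Parse ``c.497G>A`` / ``c.985del`` back to (cds_pos, ref, alt).

    Deletions return (pos, None, None).
    """
    m = _HGVS_C_RE.match(label)
    if not m:
        raise ValueError(f"unparsable c. label: {label!r}")
    pos = int(m.group(1))
    if m.group(2) is None:
        return pos, None, None
    return pos, m.group(2), m.group(3)
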