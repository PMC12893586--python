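"""Gene structure and coordinate arithmetic.

A :class:`GeneModel` anchors all conversions between genomic coordinates,
coding-sequence (c.) coordinates and codon space for a spliced gene.
Coordinates are 1-based and inclusive throughout; conversion to 0-based
half-open intervals happens only inside file writers.

Minus-strand genes are handled by reverse-complementing at splice time, so
all downstream CDS math is strand-agnostic and c.1 is always the A of the
start ATG in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "CdsLocation",
    "ExonMapping",
    "MappingFailure",
    "cds_to_codon",
    "codon_to_cds",
    "genomic_to_cds",
    "cds_to_genomic",
    "spliced_transcript",
    "coding_sequence",
    "map_transcript_to_genome",
]


@dataclass(frozen=True)
class CdsLocation:
    """Position within a coding sequence (c. coordinate, c.1 = A of ATG)."""

    cds_pos: int
    codon_number: int
    codon_offset: int  # 1..3

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise ValueError(f"cds_pos must be >= 1, got {self.cds_pos}")
        expected_codon = (self.cds_pos + 2) // 3
        expected_offset = self.cds_pos - 3 * (expected_codon - 1)
        if (self.codon_number, self.codon_offset) != (expected_codon, expected_offset):
            raise ValueError("inconsistent CdsLocation fields")


def cds_to_codon(cds_pos: int) -> CdsLocation:
    """Convert a 1-based CDS position to (codon number, intra-codon offset).

    >>> cds_to_codon(497)
    CdsLocation(cds_pos=497, codon_number=166, codon_offset=2)
    """
    if not isinstance(cds_pos, (int,)) or isinstance(cds_pos, bool):
        raise TypeError("cds_pos must be an integer")
    if cds_pos < 1:
        raise ValueError(f"cds_pos must be >= 1, got {cds_pos}")
    codon = (cds_pos + 2) // 3
    offset = cds_pos - 3 * (codon - 1)
    return CdsLocation(cds_pos=cds_pos, codon_number=codon, codon_offset=offset)


def codon_to_cds(codon_number: int, codon_offset: int = 1) -> int:
    """Inverse of :func:`cds_to_codon`."""
    if codon_number < 1 or codon_offset not in (1, 2, 3):
        raise ValueError("codon_number >= 1 and codon_offset in 1..3 required")
    return 3 * (codon_number - 1) + codon_offset


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of a gene on a single reference sequence.

    ``exons`` are genomic (start, end) intervals, 1-based inclusive,
    non-overlapping, ordered 5'→3' in *transcript* orientation (genomically
    decreasing for strand "-").  ``cds_start``/``cds_end`` are the genomic
    positions of the first and last coding nucleotide in transcript
    orientation.
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError("at least one exon required")
        for a, b in exons:
            if a < 1 or b < a:
                raise ValueError(f"malformed exon interval ({a}, {b})")
        # non-overlap and transcript-orientation order
        key = [e[0] for e in exons]
        if self.strand == "+":
            if any(exons[i][1] >= exons[i + 1][0] for i in range(len(exons) - 1)):
                raise ValueError("exons must be sorted and non-overlapping (+)")
        else:
            if any(exons[i + 1][1] >= exons[i][0] for i in range(len(exons) - 1)):
                raise ValueError("exons must be sorted and non-overlapping (-)")
        for pos, name in ((self.cds_start, "cds_start"), (self.cds_end, "cds_end")):
            if not any(a <= pos <= b for a, b in exons):
                raise ValueError(f"{name}={pos} falls outside all exons")
        n = self.cds_length
        if n <= 0 or n % 3 != 0:
            raise ValueError(f"CDS length must be a positive multiple of 3, got {n}")

    # -- transcript-space helpers ------------------------------------------

    def _tpos(self, genomic_pos: int) -> int | None:
        """1-based transcript coordinate of a genomic position, or None."""
        offset = 0
        for a, b in self.exons:
            if a <= genomic_pos <= b:
                if self.strand == "+":
                    return offset + (genomic_pos - a + 1)
                return offset + (b - genomic_pos + 1)
            offset += b - a + 1
        return None

    def _gpos(self, tpos: int) -> int:
        offset = 0
        for a, b in self.exons:
            length = b - a + 1
            if tpos <= offset + length:
                within = tpos - offset
                return a + within - 1 if self.strand == "+" else b - within + 1
            offset += length
        raise ValueError(f"transcript position {tpos} beyond transcript")

    @property
    def transcript_length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def cds_length(self) -> int:
        t_start = self._tpos(self.cds_start)
        t_end = self._tpos(self.cds_end)
        if t_start is None or t_end is None:
            return 0
        return t_end - t_start + 1


def genomic_to_cds(model: GeneModel, genomic_pos: int) -> CdsLocation | str:
    """Map a genomic position into CDS space, or label it.

    Returns a :class:`CdsLocation` for coding positions, otherwise one of
    the labels ``"5'UTR"``, ``"intron"``, ``"3'UTR"``, ``"upstream"``,
    ``"downstream"``.  Every position of the reference gets exactly one
    label.
    """
    lo = min(a for a, _ in model.exons)
    hi = max(b for _, b in model.exons)
    if genomic_pos < lo:
        return "upstream" if model.strand == "+" else "downstream"
    if genomic_pos > hi:
        return "downstream" if model.strand == "+" else "upstream"
    tpos = model._tpos(genomic_pos)
    if tpos is None:
        return "intron"
    t_cds_start = model._tpos(model.cds_start)
    t_cds_end = model._tpos(model.cds_end)
    assert t_cds_start is not None and t_cds_end is not None
    if tpos < t_cds_start:
        return "5'UTR"
    if tpos > t_cds_end:
        return "3'UTR"
    return cds_to_codon(tpos - t_cds_start + 1)


def cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """Genomic position of a 1-based CDS coordinate (inverse of genomic_to_cds)."""
    if cds_pos < 1 or cds_pos > model.cds_length:
        raise ValueError(f"cds_pos {cds_pos} outside 1..{model.cds_length}")
    t_cds_start = model._tpos(model.cds_start)
    assert t_cds_start is not None
    return model._gpos(t_cds_start + cds_pos - 1)


def spliced_transcript(model: GeneModel, genome_seq: str) -> str:
    """Concatenate exon subsequences in transcript orientation.

    ``genome_seq`` is the reference starting at genomic coordinate 1.
    Strand "-" exons are reverse-complemented.
    """
    genome_seq = genome_seq.upper()
    parts = []
    for a, b in model.exons:
        if b > len(genome_seq):
            raise ValueError(f"exon ({a},{b}) exceeds sequence bounds ({len(genome_seq)})")
        sub = genome_seq[a - 1 : b]
        if model.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        parts.append(sub)
    return "".join(parts)


def coding_sequence(model: GeneModel, genome_seq: str) -> str:
    """The concatenated CDS (c.1 .. c.n) of the model on genome_seq."""
    transcript = spliced_transcript(model, genome_seq)
    t_start = model._tpos(model.cds_start)
    t_end = model._tpos(model.cds_end)
    assert t_start is not None and t_end is not None
    return transcript[t_start - 1 : t_end]


@dataclass(frozen=True)
class ExonMapping:
    """Exact-identity tiling of a transcript onto a genome.

    ``blocks`` pair 1-based inclusive transcript intervals with genomic
    intervals of equal length; transcript intervals tile the transcript
    without gaps, and genomic intervals strictly increase.
    """

    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]

    def __post_init__(self) -> None:
        prev_t_end = 0
        prev_g_end = 0
        for (t1, t2), (g1, g2) in self.blocks:
            if t1 != prev_t_end + 1:
                raise ValueError("transcript intervals must tile without gaps")
            if t2 - t1 != g2 - g1:
                raise ValueError("paired intervals must have equal length")
            if g1 <= prev_g_end:
                raise ValueError("genomic intervals must strictly increase")
            prev_t_end, prev_g_end = t2, g2


@dataclass(frozen=True)
class MappingFailure:
    """Explicit no-mapping result naming the transcript interval left unmapped."""

    unmapped: tuple[int, int]
    reason: str = "no exact match of sufficient length"


def _longest_match_at(transcript: str, genome: str, t0: int, g_min: int) -> tuple[int, int]:
    """(best genomic start 0-based, length) of the maximal exact match of
    transcript[t0:] among genome positions >= g_min; ties by smallest start."""
    best_len = 0
    best_g = -1
    tlen = len(transcript)
    for g in range(g_min, len(genome)):
        k = 0
        while t0 + k < tlen and g + k < len(genome) and transcript[t0 + k] == genome[g + k]:
            k += 1
        if k > best_len:
            best_len, best_g = k, g
    return best_g, best_len


def map_transcript_to_genome(
    transcript: str, genome: str, min_block: int = 15
) -> ExonMapping | MappingFailure:
    """Tile a transcript onto a genome by greedy leftmost maximal exact matching.

    From the current transcript offset, the longest exact match in the
    genome downstream of the previous block is taken (ties broken by
    smallest genomic start); matching fails explicitly if no block of at
    least ``min_block`` nucleotides exists.
    """
    if not transcript or not genome:
        raise ValueError("sequences must be non-empty")
    if min_block < 8:
        raise ValueError("min_block must be >= 8")
    transcript = transcript.upper()
    genome = genome.upper()
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = []
    t0 = 0  # 0-based transcript offset
    g_min = 0  # 0-based minimal genomic start for the next block
    while t0 < len(transcript):
        remaining = len(transcript) - t0
        g, k = _longest_match_at(transcript, genome, t0, g_min)
        if k < min(min_block, remaining) or k == 0:
            return MappingFailure(unmapped=(t0 + 1, len(transcript)))
        blocks.append(((t0 + 1, t0 + k), (g + 1, g + k)))
        t0 += k
        g_min = g + k
    return ExonMapping(blocks=tuple(blocks))
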