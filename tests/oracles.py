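"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the rule statements, with no code
shared with the package: a plain-loop re-implementation of the cohort
filter criteria, an alternative maximal-exact-match tiler, and a
whole-sequence re-translation oracle for frameshifts.
"""

from __future__ import annotations

from Bio.Seq import Seq

ALLELE_ORDER = "ACGT-"


def oracle_criteria(calls: dict, reference: str, alt: str) -> dict:
    """Re-derive the four cohort criteria flags by plain enumeration.

    ``calls`` maps individual -> GenotypeCall-like object with .state,
    .alleles, .minor_fraction.  Missing calls are ignored; ambiguous calls
    are excluded from (iii) and (iv).
    """
    present = [c for c in calls.values() if c.state != "missing"]

    # (i) the variation is observed at qualifying depth
    i_flag = False
    for c in present:
        if alt in c.alleles:
            i_flag = True

    # (ii) minor allele read frequency > 0.45 for at least one individual,
    # the individual's two alleles being the reference and the variant
    ii_flag = False
    for c in present:
        if len(c.alleles) == 2 and sorted(c.alleles) == sorted((reference, alt)):
            if c.minor_fraction > 0.45:
                ii_flag = True

    # (iii) homozygotes all had one of the two nucleotides (or gaps) seen in
    # the heterozygotes, or were all homozygous for the non-reference allele
    het_alleles = set()
    n_het = 0
    het_pairs = set()
    for c in present:
        if c.state == "het":
            n_het += 1
            het_alleles |= set(c.alleles)
            het_pairs.add(tuple(sorted(c.alleles)))
    hom_alleles = [c.alleles[0] for c in present if c.state in ("hom_ref", "hom_alt")]
    if not hom_alleles:
        iii_flag = True
    else:
        in_het_pair = n_het > 0 and all(a in het_alleles for a in hom_alleles)
        all_nonref = all(a != reference for a in hom_alleles)
        iii_flag = in_het_pair or all_nonref

    # (iv) same variation type in >= 2 heterozygotes and identical in all
    iv_flag = n_het >= 2 and len(het_pairs) == 1

    return {"i": i_flag, "ii": ii_flag, "iii": iii_flag, "iv": iv_flag}


def oracle_greedy_blocks(transcript: str, genome: str, min_block: int):
    """Alternative implementation of greedy leftmost maximal exact tiling.

    Returns the block list or None when the transcript cannot be tiled.
    Scans every genomic offset with zip-based prefix comparison (no code
    shared with the package implementation).
    """
    transcript, genome = transcript.upper(), genome.upper()
    blocks = []
    t = 0
    g_floor = 0
    while t < len(transcript):
        best = (0, None)
        for g in range(g_floor, len(genome)):
            length = 0
            for a, b in zip(transcript[t:], genome[g:]):
                if a != b:
                    break
                length += 1
            if length > best[0]:
                best = (length, g)
        length, g = best
        needed = min(min_block, len(transcript) - t)
        if g is None or length < needed or length == 0:
            return None
        blocks.append(((t + 1, t + length), (g + 1, g + length)))
        t += length
        g_floor = g + length
    return blocks


def oracle_frameshift_peptide(cds: str, del_pos: int) -> tuple[str, int | None]:
    """Frameshift peptide by deleting the base and re-translating everything.

    Returns (novel residues from the first altered codon up to the stop,
    ordinal stop position counting that codon as 1, or None if no stop).
    """
    edited = cds[: del_pos - 1] + cds[del_pos:]
    first_codon = (del_pos - 1) // 3  # 0-based codon index of the deletion
    usable = len(edited) - len(edited) % 3
    protein = str(Seq(edited[:usable]).translate())
    tail = protein[first_codon:]
    if "*" in tail:
        stop_at = tail.index("*")
        return tail[:stop_at], stop_at + 1
    return tail, None
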