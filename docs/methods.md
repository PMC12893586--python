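# Methods

`ovmx` re-implements, as a tested desk-scale pipeline, the computational
workflow behind a resequencing survey of the ovine *MX1*/*MX2* locus: mining
single-nucleotide variants and 1-bp deletions from cohort read pileups,
annotating their coding consequences (including premature stop codons and
frameshift peptides), and analysing their population genetics in closed
Merino flocks.  This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic data do and do not show.

## Gene model and coordinates

A gene is a set of 1-based, inclusive, non-overlapping exon intervals
ordered 5'→3' in transcript orientation, plus the genomic positions of the
first and last coding nucleotide.  All coding arithmetic is done in c.
coordinates (c.1 = A of the start ATG): codon number `⌈c/3⌉`, intra-codon
offset `c − 3(codon − 1)`.  Minus-strand genes are reverse-complemented at
splice time so everything downstream is strand-agnostic, matching the
transcript-oriented c. notation.  Conversion to 0-based half-open
coordinates happens only inside file writers (VCF anchoring, GFF3).

`map_transcript_to_genome` tiles a transcript onto a genome by greedy
leftmost **maximal exact matching** (ties broken by smallest genomic
start), the procedure used manually to localise a three-exon 5' UTR by
perfect 32-nt and 202-nt matches.  The minimum block length defaults to
15 nt — conservative relative to the ≥ 32-nt matches that motivated it.
Exactness is deliberate: there is no mismatch or gap scoring (a non-goal),
so the mapper fails *explicitly*, reporting the unmapped transcript
interval.  Note the round-trip guarantee (splice → map recovers the exon
structure) holds only when maximal matches stop at exon junctions; on
random sequence a match can extend past a junction by chance, which is why
the property tests validate against an independent brute-force
re-implementation rather than asserting exon recovery on arbitrary input.

## Genotype calling and the cohort filter

The substrate is a per-individual, per-position table of read counts over
the alleles A, C, G, T and "−" (a single-base deletion seen as a gap).
A genotype call uses the two most frequent alleles and their minor-read
fraction *m*:

* depth < 10 → **missing** (10-fold coverage is the qualifying depth
  throughout);
* *m* ≤ 0.10 → homozygous; *m* ≥ 0.25 → heterozygous; in between →
  **ambiguous**, an explicit abstention.  The band separates sequencing
  error (≲ 2 % expected per base) from true heterozygosity (≈ 0.5) at
  10-fold depth while refusing to guess in the middle — mirroring the
  "ambiguous genotype" sires encountered in practice.  A third allele
  above 10 % of depth also marks the call ambiguous (fail-safe for
  multi-allelic artefacts).
* Ties between equally supported alleles break in the fixed order
  A, C, G, T, −, so calls are deterministic.

A site becomes an accepted cohort variant only if all of the following
hold (ambiguous calls are excluded from (iii) and (iv)):

1. *(i)* the variation appears in a genotype call at qualifying depth;
2. *(ii)* at least one individual whose top-two alleles are
   {reference, variant} has a minor-allele read fraction **strictly**
   greater than 0.45;
3. *(iii)* every homozygote carries one of the two alleles seen in the
   heterozygotes, or all homozygotes are homozygous non-reference;
4. *(iv)* at least two heterozygotes exist and all show the same
   substitution;

and the site lies in a **suitable coverage region** — a position where the
summed depth of individuals with ≥ 10-fold coverage strictly exceeds
99 reads (individuals below 10-fold contribute nothing).  Pooled
alternative-read frequency f(alt) is likewise computed over qualifying
individuals only, kept at full precision internally and rounded to two
decimals for reporting.

Two consequences of taking the rules verbatim are worth noting.  A site
where every carrier is a homozygote fails (ii) and (iv) — the criteria are
built around observing heterozygotes.  And clause (iii)'s "all homozygous
for the non-reference allele" admits a homozygote for a third allele; the
multi-allelic guard in the caller is what keeps such sites out in
practice.

## Consequence annotation

Substitutions are classified through the standard genetic code (the code
table is injectable): synonymous, missense, nonsense (creates TAA/TAG/TGA),
stop-lost; transitions (purine↔purine, pyrimidine↔pyrimidine) are
distinguished from transversions.  A substitution in codon 1 that removes
the reference methionine is classified missense with a
`start_lost_candidate` note, because the functional start codon of the
locus is itself ambiguous (three candidate in-frame ATGs).

A single-base deletion is annotated by deleting the base and translating
from the first affected codon in the shifted frame until a stop codon:
`fs_peptide` is the novel residue string before the stop, `fs_len` its
length, and `stop_offset` the ordinal position of the stop counting the
first altered codon as 1 (so `stop_offset = fs_len + 1`).  Two label
conventions are emitted: the compact `p.Q329Sfs7*` form, which counts the
**novel residues** before the stop, and standard HGVS `p.Gln329SerfsTer8`,
which counts the stop position.  If no stop is reached the class is
stop-lost with an explicit marker.

### Fixture coding sequences

The survey's variant table prints, per variant, the codon number, the
nucleotide change and the amino-acid consequence — but not the underlying
sequence.  `mx_tables` therefore builds *fixture* CDSs consistent with
every printed row: for each substitution row it searches the synonymous
codons of the printed reference residue and the three intra-codon offsets
for the unique placement that reproduces the printed consequence
(deterministic scan order; alanine filler elsewhere).  The frameshift
region is pinned explicitly — codons 329–336 read
`CAG CAG GAT ATC ACC AAC AAG CTG` with codon 337 beginning `A` — so that
deleting c.985 yields Ser·Arg·Ile·Ser·Pro·Thr·Ser followed by a stop.
These fixtures are synthetic sequences constrained by published data, not
the real *MX1*/*MX2* transcripts.

## Population genetics

* **Allele frequencies** from genotype counts: f(alt) = (2·hom + het)/2n.
  Published tables give frequency + n instead; these convert to allele
  counts by rounding with an explicit 2n-conservation check.
* **Hardy–Weinberg**: Pearson chi-square of observed genotype counts
  against (p², 2pq, q²)·n with p estimated from the data; df = 1 (three
  classes, one estimated parameter).  Monomorphic samples return an
  explicit "undefined" result, never a silent p = 1.
* **Flock comparison**: 2×2 chi-square on allele counts (ref/alt × flock),
  df = 1, Yates continuity correction off by default and available by
  flag.  No multiple-testing correction is applied (deliberately, for
  small single-locus datasets); the default significance level is 0.05.
* **Sire inference**: for each candidate sire genotype the likelihood is
  the product over progeny of P(offspring genotype | sire, dam) under
  Mendelian transmission; dams contribute either their recorded genotype
  or a random allele at the population frequency.  The maximum-likelihood
  genotype is labelled "likely" when it beats the runner-up by ≥ 20:1
  (configurable), else "ambiguous"; if no genotype explains the progeny a
  pedigree-inconsistency error names an offending trio.
* **Haplotypes**: an unphased genotype over linked sites with h
  heterozygous positions admits 2^(h−1) phase configurations (one when
  h ≤ 1, which is also the "unambiguous" condition).
* **Relative expression**: 2^−ΔΔCt with technical replicates averaged
  before differencing; ΔΔCt = (Ct_target − Ct_ref)_treated −
  (Ct_target − Ct_ref)_control.

## Synthetic cohorts

The generator emulates the statistical structure of a 68-animal
whole-genome panel at desk scale: diploid genotypes at planted sites are
two Bernoulli(f) draws; per-(individual, site) depth is Poisson with mean
20 by default (inside the 10–30× band typical of such panels); reads are
drawn from the genotype's allele mix (alt fraction 0, ½ or 1) and each
read suffers an independent error at rate 0.5 % by default, substituting
uniformly among the other three nucleotides (a gap read miscalls as any of
the four).  Deletion alleles appear as gap reads at the deleted position,
matching the pileup dialect.

One seed drives everything; sub-generators use independent substreams
keyed by (module, individual), so enlarging a cohort never perturbs the
reads of existing individuals.  Depth is i.i.d. per site — there is no
coverage autocorrelation, no mapping error, no FASTQ-level simulation —
which is adequate because every filter criterion is per-site.  Passing
tests on these cohorts therefore demonstrate the *logic* of the caller and
filters, not robustness to alignment artefacts or context-dependent error,
which real data have and this generator does not.

A subtlety the simulations expose: with error-free reads a true
heterozygote can still draw a minor fraction inside the (0.10, 0.25)
ambiguous band by binomial chance, so "exact recovery" is asserted as
*no wrong assignment* — ambiguous abstentions are allowed, wrong hom/het
calls are not.  Similarly, rare alleles with a couple of carriers can
legitimately fail criteria (ii)/(iv); the mining driver reports such
misses rather than hiding them.

Closed-flock trajectories use Wright–Fisher binomial resampling of
2N allele copies per generation with viability selection (fitnesses 1, 1,
1−s against alternative homozygotes).  A deterministic (infinite
population) mode skips the resampling; for a recessive lethal (s = 1) it
follows the closed form f' = f/(1+f), which the tests check to 1e-12.
Defaults in the analysis driver — 90 breeding animals, 25 generations —
match a research flock of 80–100 ewes kept closed for several decades.

## Problem sizes and numerical choices

Test and driver scales were chosen so the whole suite runs in minutes on
one CPU: cohorts of up to 68 individuals over 0.3–50 kb references, 500
randomized oracle comparisons, 200 pedigree replicates, 500 flock
replicates.  Chi-square p-values come from `scipy.stats`; the VCF writer
is plain text VCFv4.2 with 1-bp deletions left-anchored on the preceding
reference base, and round-trip fidelity is checked by re-parsing with
`pysam`.  Every variant output file carries the tool version and a
configuration hash in its header; re-running on identical inputs produces
byte-identical outputs.

## Known limitations

* Starts from allele counts: no alignment, base-quality or BAM handling.
* Exact-match transcript mapping only; no spliced alignment with
  mismatches.
* Single-nucleotide deletions only; no multi-base indels.
* Pearson chi-square for HWE (no exact test), no linkage-disequilibrium
  estimation, no impact prediction for missense changes.
* The fixture CDSs are constrained reconstructions, not the true ovine
  transcripts; analyses that depend on sequence context outside the
  constrained codons (e.g. the filler regions) are synthetic by
  construction.
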