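# ovmx

Cohort variant mining, coding-consequence annotation and population
genetics for the ovine Mx genes (*MX1*, *MX2*), with a seedable
synthetic-cohort generator so every stage is testable at desk scale.

Sheep carry two interferon-induced antiviral GTPase genes, *MX1* and
*MX2*, adjacent on chromosome 1.  Resequencing surveys of such loci mine
variants from per-animal read pileups, annotate which changes disrupt the
protein — premature stop codons (p.W166\*) and frameshifting deletions
(p.Q329Sfs7\*) create *null alleles* — and then ask population-genetic
questions: allele frequencies per flock, Hardy–Weinberg conformance,
between-flock contrasts, sire genotypes inferred from progeny, and whether
a null allele can persist in a closed flock under selection.  `ovmx`
implements that entire workflow as a reusable library, a CLI, and a set of
narrative analysis drivers.

## What's in the box

| module | purpose |
| --- | --- |
| `ovmx.genemodel` | exon/CDS gene models; genomic ↔ c. ↔ codon coordinate math; exact-match transcript-to-genome tiling |
| `ovmx.mining` | genotype calling from allele read counts; suitable-coverage regions; the four cohort acceptance criteria; `mine_variants` |
| `ovmx.consequence` | Ts/Tv classification; synonymous/missense/nonsense calls; frameshift translation to the next stop; c./p. labels |
| `ovmx.popgen` | allele/genotype frequencies, HWE and 2×2 flock chi-squares, ML sire inference, haplotype enumeration, 2^−ΔΔCt |
| `ovmx.simulate` | seedable diploid cohort/pedigree/closed-flock generators |
| `ovmx.mx_tables` | the published coding-variant rows for both genes and fixture CDSs consistent with them |
| `ovmx.io`, `ovmx.pipeline`, `ovmx.cli` | FASTA/pileup-TSV/VCF/GFF3/manifest I/O, the `run` orchestration, the `ovmx` command |

The statistical core: a site is an accepted variant when it lies where
pooled qualified depth exceeds 99 reads and (i) the variation is seen at
≥ 10-fold coverage, (ii) some individual shows a minor-allele read
fraction > 0.45, (iii) homozygotes are consistent with the heterozygote
allele pair (or all non-reference), and (iv) at least two heterozygotes
show the identical substitution.  Genotypes come from the minor-read
fraction *m* of the top two alleles: hom if *m* ≤ 0.10, het if *m* ≥ 0.25,
ambiguous between, missing below 10 reads.  See `docs/methods.md` for the
full model description.

## Worked example

Annotate the two null alleles on the *MX2* fixture CDS and run a
Hardy–Weinberg test on a genotyped lamb cohort (7 wild-type, 14
heterozygous, 10 null-homozygous):

```python
>>> from ovmx.mx_tables import mx2_fixture_cds
>>> from ovmx.consequence import annotate_snp, annotate_deletion
>>> cds = mx2_fixture_cds()
>>> stop = annotate_snp(cds, 497, "A")
>>> stop.consequence_class, stop.hgvs_p()
('nonsense', 'p.W166*')
>>> fs = annotate_deletion(cds, 985)
>>> fs.fs_peptide, fs.fs_len, fs.stop_offset, fs.hgvs_p()
('SRISPTS', 7, 8, 'p.Q329Sfs7*')

>>> from ovmx.popgen import GenotypeCounts, hwe_test, carriers
>>> lambs = GenotypeCounts(n_ref_hom=7, n_het=14, n_alt_hom=10)
>>> res = hwe_test(lambs)
>>> round(res.statistic, 3), round(res.p_value, 3)
(0.241, 0.623)
>>> carriers(GenotypeCounts(31, 24, 13))
37
```

The G→A transition at c.497 turns the tryptophan codon TGG into the amber
stop TAG at codon 166; the single-base deletion at c.985 shifts the frame
so seven novel residues (Ser·Arg·Ile·Ser·Pro·Thr·Ser) are translated
before a stop as the eighth altered codon.  The lamb cohort's genotype
tallies sit comfortably on Hardy–Weinberg proportions (χ² = 0.24,
p = 0.62), and 24 + 13 = 37 of 68 animals carry at least one copy of a
start-codon variant.

## Analysis drivers

`analysis/` holds numbered, re-runnable drivers that write their tables
under `results/`:

1. `01_simulate_cohort.py` — 68-animal synthetic cohort over a 900-bp toy
   locus (Poisson-20 depth, 0.5 % error, planted common/uncommon/rare
   variants);
2. `02_mine_variants.py` — mines that pileup, writes VCF + variant table,
   scores recovery against the planted truth;
3. `03_consequences.py` — annotates all published coding-variant rows of
   both genes; reports the two null alleles and the protein-altering
   counts (3 for *MX1*, 6 for *MX2*);
4. `04_flock_popgen.py` — flock allele-frequency contrasts, lamb-cohort
   HWE, carrier tabulation, 17-progeny sire inference, haplotype
   enumeration over the codon 166/167/175 SNP trio;
5. `05_closed_flock_selection.py` — Wright–Fisher persistence of a null
   allele in a ~90-ewe closed flock over 25 generations across selection
   strengths;
6. `06_expression_ddct.py` — 2^−ΔΔCt fold changes on a synthetic qPCR
   table emulating interferon induction.

Run them in order: `python analysis/01_simulate_cohort.py` etc.

There is also a CLI:

```bash
ovmx mine --pileup results/sim/pileup.tsv --out-vcf out.vcf --out-table out.tsv
ovmx stats hwe --counts 7 14 10
ovmx annotate --cds-fasta cds.fasta --change c.497G>A --change c.985del
```

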