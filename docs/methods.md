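# Methods

## Scope and model

`gojivar` analyses called variants (VCF) from a two-cohort resequencing
design — cultivated versus wild *Lycium barbarum* genotypes — against a
reference genome (FASTA) and a CDS annotation (GFF3 subset). It does not
align reads or call variants; its inputs are the caller's output, and its
own contribution is everything downstream: filtering, summary statistics,
codon-level consequence annotation and the cohort discrimination rule.
Coordinates are 1-based inclusive throughout; CDS positions count spliced
coding bases 5′→3′ of the mRNA, so on the minus strand position 1 is the
highest genomic coordinate and alleles are complemented during projection.

## Post-call filtering

A variant record is kept when its record-level read support is strictly
greater than 4 and its RMS mapping quality strictly greater than 20 (the
wording "over four" / "exceeding 20" makes both bounds exclusive; 4 reads or
MQ 20.0 exactly are dropped). The support threshold is applied to the
record-level DP as emitted by mpileup-style callers, not per sample, because
that is the granularity the caller reports. InDels are defined as length
≤ 50 bp — longer events are rejected with a reason — and pass through the
same evidence filters. Multiallelic records are split per alternate allele
(a genotype carrying a different alternate becomes missing on that split),
and equal-length multi-base substitutions are decomposed into per-base SNPs
at the offsets that actually change, which is what lets two adjacent
substitutions be re-grouped into a single codon later. InDels are not
re-normalized beyond VCF conventions; positions are taken as given.

## Spectrum, heterozygosity, density

Every single-base substitution maps to one of six strand-collapsed classes
(a T>C on one strand is an A>G on the other, so the two are one class).
Transitions are T:A>C:G and C:G>T:A. Per sample, a site contributes to the
spectrum when the sample carries the alternate (het or hom-alt); the
heterozygosity rate is 1000 × het calls / callable bases, with the
N-excluded reference length as the default denominator (a flag selects the
total length including Ns, since both denominators are in circulation).
When a sample has no transversions the ratio is reported as absent rather
than raising a division error. Density tracks tile each chromosome with
half-open windows (default 1 Mb — the figure bin width behind published
density plots is never stated, so it is exposed as a parameter), counting
variants by start position; the BED-like export is the only 0-based surface.

## Consequence annotation

Codon index and offset follow directly from CDS-position arithmetic
(codon = ⌈p/3⌉). SNPs sharing a codon form one group; the alternate codon is
built by substituting the group's alleles into the reference codon. Because
phase is unknown, multi-SNP codons enumerate the allele combinations
actually attested by per-sample genotypes rather than the full Cartesian
product (a flag forces full enumeration); independent alternates at
different offsets therefore yield separate alternate codons (e.g. TCT →
GCT, TCA, TCG = Ser → Ala, Ser, Ser). Translation uses the standard genetic
code; a stop-gaining change is nonsense, never synonymous, and codons
containing N classify as "unknown" and are excluded from counts. Property
flags use the partition nonpolar {Gly Ala Val Leu Ile Pro Phe Met Trp},
polar {Ser Thr Cys Tyr Asn Gln}, basic {Lys Arg His}, acidic {Asp Glu}:
polarity change = polar↔nonpolar crossing, charge change = basic↔acidic or
charged↔uncharged crossing. Synonymous changes carry false flags by
construction.

## The packaged gene tables and their corrections

The three *BDG* coding-SNP tables ship as TSVs with cells exactly as
published; the loader applies an explicit corrections file (ship the raw
table plus auditable edits, never silent fixes). Corrections: chromosome 4
position 1439 reference amino acid Gly→Lys and 1761 Tyr→Thr (the codons
AAA/ACG dictate Lys/Thr), chromosome 8 position 824 reference Pro→Ser,
chromosome 9 position 982 printed alternate "Ser"→Cys (codon TGT) and
position 1285 "h775"→"h75" (a read percentage cannot exceed 100). Cell
token grammar: `hNN` = heterozygous with NN% alternate reads; any other
token names an amino acid (optionally with codon) and resolves against the
reference/alternate codons, ties (silent rows where both spell the same
amino acid) resolving to hom-ref; multi-position rows accept `/`-separated
per-position sub-tokens (`h14/Lys`). A printed position range anchors the
codon's first base at the range start; the substituted positions are then
derived from the codon offsets at which the alternates differ, and every
disagreement between printed positions and codon-grid arithmetic (the
tables' printed CDS positions are systematically off the ⌈p/3⌉ grid implied
by their own codons) is logged as a row note rather than patched.

## Discrimination rule and the two granularities

A site discriminates when each cohort is internally uniform in three-way
state class (hom-ref / hom-alt / het) and the two classes differ; the
heterozygous read split is ignored. This rule was chosen over the weaker
"cohort state sets disjoint" alternative because the published
non-discriminating assignments (e.g. chromosome 4 position 590, cultivated
uniformly hom-alt against a mixed wild cohort) require it. Reports carry
counts at two granularities: per codon-change row (a sample is het for the
row if het anywhere in the codon) and per substituted position. They
coincide for single-SNP rows — all 22 on chromosome 4 — but differ for
multi-SNP codons: on chromosome 8, 15 of 26 rows but 17 of 28 positions
discriminate (the 392–394 codon contributes two discriminating positions,
287–288 only its second), and on chromosome 9, 15 of 28 rows versus 17 of
30 positions. The published per-gene claims correspond to different
granularities (positions for chromosome 8, rows elsewhere), and the
published percentages are internally inconsistent with their own fractions;
the reports therefore print exact fractions at both granularities and keep
counts authoritative. One published discriminating call (chromosome 8
position 799, wild cohort {het, het, hom-alt}) is not reproducible under
any uniformity-based rule and is reported as non-discriminating.
Percentages round half-up (14/22 → 64%). A site with any unassessable
(missing) sample in either cohort is excluded from the denominator and
listed separately, so partial data can remove a site but never flip a
verdict.

## The simulator

The generator emulates the *statistical* structure of the study data, not
its sequence content: uniform-random chromosomes (no Ns, no repeats, no GC
structure), single-exon non-overlapping CDS genes, and variants with

* a six-class spectrum; defaults put the transition share at 1.72/2.72 with
  within-share splits 52/48 (transitions) and 29/29/26/16 (transversions),
  matching the observed ordering — C:G>T:A most frequent, C:G>G:C least —
  while fixing ts/tv at exactly 1.72. Class counts are drawn multinomially
  and positions are then sampled within the compatible reference-base
  stratum, so the realized spectrum is exact rather than biased by base
  composition;
* a per-sample heterozygous-call probability derived from the per-mille
  target (default 5.037 ‰, the highest observed genotype) divided by the
  SNP site rate (default 0.0084/bp, the observed ~14 M SNPs per 1.67 Gb
  genome) and by the filter pass rate, because the published rate is
  measured after filtering; hom-alt probability defaults to 0.25;
* an InDel length law with 49.4% 1 bp, 13% 2 bp, 7% 3 bp, a declining
  explicit sequence to 12 bp and a geometric tail carrying 1% beyond 12 bp
  and <0.1% beyond 32 bp, matching the reported envelope; deletions
  slightly outnumber insertions (0.538) and the InDel rate defaults to one
  tenth of the SNP rate (the observed SNP:InDel ratio ≈ 10);
* terminal density enrichment: the outer 10% of each chromosome end has its
  variant intensity multiplied by `end_density_gradient` (default 3) — the
  two-valued weight lets the draw split into a binomial between regions
  followed by uniform sampling without replacement, which keeps it exact
  and fast;
* planted discriminating coding sites: a configured fraction of coding SNPs
  is forced into (cultivated het, wild hom-ref) or (cultivated hom-alt,
  wild het) with equal probability — the two patterns dominant in the gene
  tables; and
* DP/MQ evidence above both filter thresholds with a configured pass rate
  (default 0.95), failures split evenly between low support and low MQ.

Determinism: all draws come from numpy Generators keyed on
`(seed, stream-id[, sample-index, chromosome])`, so a fixed seed gives
byte-identical FASTA/GFF3/VCF output and adding samples does not perturb
genome or site draws. Because the simulator has none of real data's
alignment artifacts, linkage, repeat-driven error modes or coverage
heterogeneity, passing recovery tests demonstrates the *estimators* are
correct, not that the filters would behave identically on real reads.

## Problem sizes and numerical choices

Parameter-recovery checks run at 10⁵ SNPs / 10⁵ InDels on ~12 Mb genomes
and 84,000 sites on a 10 Mb genome for the heterozygosity rate — sizes at
which three Monte-Carlo standard errors bound ts/tv within about ±0.04,
the 1-bp share within ±0.5 points and the rate within ±0.07 ‰, and a full
run stays in the tens of seconds on one CPU. The shared test simulation
uses two 150 kb chromosomes. Standard errors use the delta method for the
ratio (r·√(1/nts + 1/ntv)) and binomial forms elsewhere. Percentages round
half-up; degenerate cases (no transversions, empty genes, empty variant
streams) return absent values or header-only tables rather than errors.

## Known limitations

No phasing, no linkage or demographic structure, no read-level simulation
(FASTQ/BAM), no genotype-likelihood recomputation, no left-normalization of
InDels, no statistical association tests (the discrimination rule is a
deterministic classification, not a test), and no splice/UTR/regulatory
consequence prediction. The genome-wide totals reported for the original
cohort depend on unreleased raw data and are treated as narrative context,
not reproduction targets.
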