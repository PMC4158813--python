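# Methods

## The statistic

For a sequence over {A,C,G,T}, let f_X be the frequency of nucleotide X
and f*_XY the frequency of the overlapping dinucleotide XY (windows at
positions 1..L−1, linear, no circular wrap-around).  The dinucleotide
relative abundance is

    ρ*_XY = f*_XY / (f_X · f_Y),

the observed dinucleotide frequency relative to the expectation under
independence of the component bases; ρ* − 1 is the dinucleotide bias.
The transcript signature normalises a transcript's ρ* to a pooled
whole-genome profile:

    TS_XY = ρ*_XY(transcript) / ρ*_XY(genome),

so TS = 1 is genome-like.  The CG component is the discriminating
feature: vertebrate genomes are strongly CG-suppressed (methylation–
deamination converts CG to TG/CA), while coding transcripts overlap
CpG-island-rich promoter-proximal sequence and retain much more CG.
mRNAs therefore sit near TS_CG ≈ 2.3, long non-coding RNAs near ≈ 2.0,
and pseudogene transcripts — non-coding but sequence-similar to their
parent genes — in between.  Enrichment is reported as
(TS − 1) × 100 percent, so 0% means genome-like; the TA dinucleotide is
uniformly under-represented (≈ −20%) in transcripts of every class and
serves as a negative control.

## Conventions and numerical choices

- Residues are uppercased and U→T at ingest; RNA and DNA are treated
  identically afterwards.
- Frequencies are computed on the given strand only.  No
  reverse-complement symmetrisation is applied: transcripts are
  directional, and for the self-complementary dinucleotides CG and TA
  (the two that carry signal) ρ* is strand-symmetric anyway, so the
  choice does not affect the headline statistic.
- Any window containing a non-ACGT symbol (genome builds contain long N
  runs) is dropped from both the numerator and the denominator.
- The genome baseline pools raw counts over all chromosomes and computes
  frequencies once — it is not a mean of per-chromosome ρ*, so long
  chromosomes weigh more, matching a "whole genome" reading.
- Zero-denominator ρ* or TS values are *undefined*: `None` in maps, NaN
  in matrices, `NA` on disk — never silently 0, so degenerate short
  sequences cannot drag dataset means.
- Dataset summaries exclude undefined entries per dinucleotide (pairwise
  deletion), preserving sample size for the common dinucleotides;
  sem = sd/√n requires n > 1 and is `NA` for singletons.

## Curation filters

The mRNA dataset keeps RefSeq `NM_` records without "partial",
"predicted"/"PREDICTED:" or "RIKEN" in the header and with either no
"transcript variant n" annotation or n = 1 (one reference isoform per
gene).  Drop accounting attributes each record to the first matching
rule in the fixed order prefix → partial → predicted → RIKEN → variant,
which makes reports deterministic and exactly decomposes the input
count.  The lncRNA dataset is the `NR_` accession class.  The bona-fide
prefilter additionally removes infrastructural RNA (tRNA, rRNA, snoRNA,
snRNA), small RNAs (miRNA, piRNA), pseudogene and antisense records by
case-insensitive substring match; the keyword list is a reconstruction
and is configurable.  Literature confirmation cannot be automated; it is
represented by a whitelist table.  The packaged 52-row table is a
**synthetic stand-in** that follows the published schema (name, RefSeq
accession, chromosome, exon count, length, longest ORF, disease link) —
only its WBSCR26/NR_026690 row (471 nt, 240 nt ORF) reflects a real
transcript.  Replace it with a genuine curated table for production use.

## Dataset cross-validation

Transcripts are partitioned at random (seeded) into datasets of 50.
Every dataset pair is compared with a two-sided Student's t-test on the
per-transcript ρ* of each of the 16 dinucleotides; a dataset survives
only if all of its pairwise tests have p > α (default 0.05).  Two open
choices were resolved as follows: "Student's t-test" is read literally
as the equal-variance test (Welch is available behind
`equal_var=False`), and the test panel runs per dinucleotide rather than
on 16-value profile vectors, because the keeping rule ("no difference on
any dinucleotide") is only meaningful component-wise.  No
multiple-testing correction is applied across the panel — the screen is
intentionally conservative about homogeneity, so with 16 tests per pair
a truly homogeneous pair is still discarded ~56% of the time at
α = 0.05; α is a screening knob, not an inference level.

## ORF and stop-codon statistics

The longest ORF is the maximal ATG→stop span over the three sense-strand
frames; its nucleotide length counts the ATG through the last sense
codon and excludes the stop, making "240 nt (80 aa)" internally
consistent (80 codons = 80 aa).  Ties break by smallest start, then
smallest frame.  Spans without an in-frame stop before the sequence end
are excluded by default (truncated 3′ ends are indistinguishable from
open-ended spans); `include_open_ended=True` counts them.  Stop-codon
content uses frame-1 non-overlapping codons (the codon-usage-table
convention), with a three-frame mean available.  Both the percentage of
stop codons and stops per 1,000 bases are reported; they differ by the
factor 10/3 and are sometimes conflated in the literature.  Under the
uniform i.i.d. null, 3/64 = 4.69% of codons are stops — the benchmark
that makes non-coding transcripts "random-like" (≈5%) versus mRNAs (≈4%).

## Synthetic data generator

Populations are drawn from a first-order Markov chain.  Given base
frequencies f and target abundances ρ, the implied dinucleotide matrix
p_XY = ρ_XY f_X f_Y is row-normalised into transitions
P(Y|X) = p_XY / Σ_Y′ p_XY′; the first base comes from the stationary
distribution (leading left eigenvector, power iteration, tolerance
1e-12).  Row renormalisation means the chain's long-run composition can
deviate from the requested targets, so the generator computes *realized*
ρ* in closed form (π_X P_XY / π_X π_Y) and a multiplicative fixed-point
calibration adjusts the requested values until the realized ones hit a
desired target exactly; calibration tests use realized, not requested,
targets.

Presets emulate three transcript populations against a synthetic
CG-suppressed genome (ρ*_CG = 0.25, ρ*_TA = 0.78, GC 41% — human-like
bulk values): mRNA-like TS_CG = 2.29 (GC 52%), pseudogene-like
TS_CG = 2.12 (GC 46%), lncRNA-like TS_CG = 1.96 (GC 44%), all with
TS_TA = 0.80.  The mRNA and lncRNA targets are the reported
population means for curated human RefSeq sets; the pseudogene value is
the midpoint, since only "intermediate" is established.  Transcript
lengths follow a log-normal model whose parameters are fitted
numerically so that the ≥200 nt *truncated* distribution has median
1.5 kb and mean 3.1 kb (right-skewed, as in curated lncRNA sets);
the 200 nt floor is the defining length cut-off for lncRNAs.

What the generator does *not* emulate: UTR/CDS architecture, splicing,
CpG-island positional clustering, pseudogene decay mutations, or
between-transcript biological variance in TS beyond counting noise.
Passing parameter-recovery and power tests therefore shows the
estimator and test machinery are correct under the stated composition
model — not that real RefSeq data will reproduce any particular mean,
which depends on the annotation snapshot.

## Problem sizes used in the shipped checks

Calibration of ρ* on i.i.d. sequence uses 10⁶ bases (tolerance ±0.02);
oracle equivalence uses 1,000 random sequences ≤300 nt against
brute-force window scanning and exhaustive ATG×stop enumeration;
the stop-codon null pools 10⁶ codons (±0.1 around 4.69%); parameter
recovery uses n = 1,000 transcripts of 1,500 nt per population (±0.05
on the mean TS_CG); two-group power uses 200 replicates of 50 vs 50
transcripts at p < 0.005; the cross-validation null rejection rate uses
1,000 replicate dataset pairs of 50 (16,000 tests, expected rate
α ± 0.02).  Fixed-length 1,500 nt transcripts are used for recovery and
power so that the per-transcript counting noise (sd of TS_CG ≈ 0.3 at
that length) is homogeneous; under the log-normal length model short
transcripts dominate the variance and the same comparisons remain
significant but with lower power.

## Known limitations

- The contaminant keyword list and the packaged whitelist are
  reconstructions; curation results on real RefSeq files depend on the
  snapshot and will not reproduce any particular historical count.
- ρ* is a ratio estimator; at short lengths it carries O(1/L) bias and
  heavy right skew, so dataset means over very short transcripts are
  slightly inflated.
- Only k ≤ 2 composition is modelled and measured; codon structure,
  CpG islands as regions, and higher-order dependence are out of scope.
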