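# Methods

## Problem and model

`sdrscan` locates sex-determining regions (SDRs) in a genome assembly from
whole-genome resequencing summaries of a sexed cohort, and decides between
male heterogamety (XX/XY) and female heterogamety (ZZ/ZW). It works from
three observations about how a heterogametic system looks when a cohort is
aligned to a reference that contains the sex-limited chromosome's sequence:

1. **Depth contrast.** Sequence present only in the heterogametic sex (a
   Y- or W-derived segment) attracts reads from that sex alone. The
   homogametic sex shows zero coverage over the segment; the heterogametic
   sex shows roughly half its autosomal depth, because the segment is
   hemizygous (single copy).
2. **Heterozygosity contrast.** Where the two sex chromosomes have diverged
   but still co-align to one reference locus, every heterogametic
   individual is heterozygous and every homogametic individual homozygous.
3. **False discoveries.** Genotype-state association *without* co-located
   depth variation is the signature of a spurious signal (paralogy,
   miscalling), not of a sex chromosome.

Two genome-wide scans feed a rule-based classifier:

- **Depth scan.** Per-base depth per sample is averaged in non-overlapping
  1 kb bins. Each bin gets a two-sided Welch two-sample t-test (unequal
  variances, Welch–Satterthwaite degrees of freedom) of male vs female
  per-sample bin means; p-values become −log10P and bins with −log10P
  strictly greater than 2 are retained. Separately, maximal *zero-depth
  tracts* are extracted: intervals where every sample of one sex stays at
  or below a depth ceiling (default 0) at every base.
- **Variant scan.** Each variant's genotype states (heterozygous vs
  homozygous, missing dropped) form a 2×2 table against sex, tested with a
  two-sided Fisher exact test computed by direct hypergeometric
  enumeration; two-sidedness uses the point-probability rule (all tables
  with probability ≤ the observed table's, with a 1+1e-7 relative
  tolerance, matching R's `fisher.test`). Variants *entirely* associated
  with sex — every cohort member genotyped, one sex all heterozygous, the
  other all homozygous — are flagged, and 0-anchored 5 kb tiles holding
  strictly more than 10 flagged variants become density windows.

With the 13-member default cohort the smallest attainable two-sided p is
1/C(13,7) = 1/1716 (−log10P ≈ 3.2345), attained exactly by the fully
sex-associated configuration.

Retained depth windows and density windows are unioned per contig (gaps
≤ `merge_gap` merged) into candidate regions, each classified by the rule
table: male-het variants plus a co-located female depth deficit →
XY-linked; female-het variants plus a male deficit → ZW-linked; het
association without co-located depth evidence → spurious; depth evidence
without a consistent variant direction (or conflicting directions) →
ambiguous. The cohort verdict is XY iff at least one XY-linked region
exists and no ZW-linked one (symmetrically for ZW), otherwise
undetermined — conflict is reported as undetermined rather than resolved
by majority.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bin_width` | 1000 bp | depth-scan bin size |
| `neglogp_threshold` | 2.0 | strict retention cutoff on −log10P |
| `density_window` | 5000 bp | tile size for flagged-variant density |
| `density_min_count` | 10 | tiles must exceed this count (strict >) |
| `min_contig_len` | 3000 bp | contigs strictly shorter are excluded |
| `merge_gap` | 1000 bp | one bin; max gap when unioning evidence |
| `colocalization_slop` | 5000 bp | one density tile; how far apart depth and variant evidence may sit and still count as co-located |
| `zero_depth_max` | 0 | per-base ceiling defining a zero-depth tract |
| `min_tract_len` | 1000 bp | one bin; shortest reported tract |
| `deficit_ratio` | 0.6 | a retained window only counts as a depth deficit if the deficit sex's mean is below this fraction of the other sex's |
| `p_floor` / `neglogp_cap` | 1e-300 / 300 | degenerate-variance handling |

Design choices where the procedure was genuinely open:

- **Degenerate variances.** Both sexes zero variance with equal means →
  p = 1; with unequal means → p is set to `p_floor` and −log10P to the cap
  (the t reference distribution is undefined, but the evidence is
  maximal); one-sided zero variance uses the ordinary Welch formula, which
  stays finite. Partial terminal bins are tested like any other, averaged
  over their true length.
- **No multiple-testing correction** on either scan: raw −log10P is
  thresholded deliberately, since downstream classification demands
  co-location of two independent evidence types rather than per-test
  control.
- **Cohort-complete full association.** A variant with any missing
  genotype is never "entirely associated", keeping the flagged set the
  strict minimum-p configuration for its margins.
- **Effect-size condition on depth deficits (`deficit_ratio`).** Zero
  tracts aside, a retained window supports an XY/ZW call only if the
  deficit sex's mean is below 0.6× the other's — the weakest signal
  consistent with losing one chromosome copy (hemizygosity gives ≈ 0.5×,
  absence ≈ 0×). Isolated false-positive windows (small-sample t-tests at
  p < 0.01 leave roughly 1–2% of null windows above threshold) differ by a
  few percent in mean, not by half, so they cannot convert a spurious
  het-association region into a sex-linkage call.
- **Density tiles are 0-anchored and non-overlapping** (deterministic,
  countable totals), and region variant direction is read from the flagged
  variants overlapping the slop-expanded region, with density windows kept
  as a separate evidence flag; a tile count fluctuating just below the
  strict >10 cutoff therefore cannot flip a classification on its own.
- **Repeat-confounded scaffolds** (male-het variants whose zero-coverage
  tracts also swallow part of one sex's samples) still classify by the
  rule table but emit a warning; down-weighting them is left to the
  analyst.

## Synthetic cohorts

The simulator emulates the *outputs* of the alignment/calling stack —
per-sample per-base depth tables, a GT-only multi-sample VCF, a sample
sheet, a contig table and a truth BED — without simulating reads. Defaults
are the study conditions the package targets: 7 males + 6 females at 13×
mean depth. Depth is drawn i.i.d. per base from Poisson(13 × factor)
(optionally negative-binomial via a gamma-Poisson mixture, shape
`negbin_dispersion`), with the factor set per planted feature: XY SDRs use
0.5 for males (hemizygous) and 0.0 for females; ZW mirrors; spurious-het
features leave depth untouched; repeat-confounded features zero all
females plus a random half of the males. Background variants arrive at
0.0286 per bp (the study-scale cohort rate of ≈16.6 M variants over a
≈579 Mb genome) with Hardy–Weinberg genotypes at a uniform(0.05, 0.95)
allele frequency; sex-linked variants inside SDR features arrive at
25/6000 per bp (the observed fully-associated density over the ~6 kb
region). After truth assignment, genotypes are perturbed by a symmetric
HET↔HOM state flip with probability 0.01 and set missing with probability
0.02 — realistic short-read cohort error levels, fixed once.

What the simulator does **not** emulate: read placement and mapping-quality
artefacts, linkage disequilibrium and recombination structure, indel/SNP
distinctions (both are just "variants"), depth autocorrelation from GC or
repeats outside the planted features, and the coupling between zero depth
and missing genotype calls (genotypes are drawn independently of simulated
depth). Passing recovery tests therefore demonstrate the *inference logic*
under the stated noise model, not robustness to real alignment pathology.

The pinned fixtures are study-scale miniatures: `xy_small` plants one 6 kb
XY SDR at the proximal end of the first of three 30 kb contigs plus one
5.5 kb spurious female-het region; `zw_small` is its mirror; `null_small`
plants nothing; `confounded` adds a 4013 bp repeat-confounded scaffold and
a sub-3 kb contig that the length filter must drop. These sizes keep a
full multi-seed recovery sweep (10 seeds × 3 fixtures plus 10
spurious-only cohorts) in the order of a minute on one CPU.

## Numerical notes

- Internal coordinates are 0-based half-open everywhere; 1-based depth/VCF
  positions are converted on read, BED on write.
- Fisher p-values are memoised on the 2×2 counts, so a cohort-scale scan
  performs only as many enumerations as there are distinct tables.
- Direction ties (equal het fractions) are NONE and can never support a
  verdict.
- All randomness flows from a single `numpy.random.Generator` seeded from
  the simulation config; identical config ⇒ byte-identical output files,
  and the pipeline itself is deterministic given its inputs.

## Limitations

The classifier assumes the reference assembly contains the sex-limited
sequence (built from or scaffolded with the heterogametic sex); if it does
not, the depth signature inverts into *excess* depth on X/Z-homologous
regions, which this rule table does not model. Verdicts rest on co-location
within `colocalization_slop`, a configurable stand-in for the study
practice of judging co-location by inspection. Counts printed for the
original cohort (e.g. genome-wide variant totals) depend on restricted raw
data and are out of reach of the simulator by design.
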