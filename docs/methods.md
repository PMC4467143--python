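# Methods

## Interaction scores from the reporter screen

Each well of the dual-luciferase screen yields a Firefly reading (the
reporter carrying the 3′UTR) and a Renilla reading (co-transfected
control). The normalized readout is log2(Firefly/Renilla); log base 2
is used so a unit change is a two-fold change in reporter output. A
Renilla reading ≤ 0 marks an invalid well (error); Firefly = 0 yields
−∞ and the well is dropped with a warning.

Within one screen (one 3′UTR × one replicate), log-ratios across all
miRNA mimics are converted to robust z-scores,
z = (x − median)/(1.4826·MAD), with 1.4826 the usual consistency
constant for the normal distribution. A screen whose MAD is zero (more
than half of the log-ratios identical, which occurs in noise-free
simulations) cannot be scaled; the low-level `robust_zscore` raises in
that case, while the screen-level pipeline falls back to unit scale
(z = x − median), which preserves effect sizes and keeps the zero-noise
path exact.

Mimics have sequence-independent systematic effects (toxicity,
transfection behavior). These are removed by centering per miRNA
against the analog panel: the interaction score of miRNA *i* is its
focal-screen z minus the median of its z-scores across the analog
screens of unrelated 3′UTRs. A miRNA with no analog baseline is
excluded and logged rather than scored against an undefined reference.
Scores from independent replicate screens are averaged arithmetically;
hit calling uses the averaged score with a *strict* inequality
(score < cutoff; a score exactly at the cutoff is not a hit).

The cutoff is chosen by ROC analysis of validated interactions
(positives) versus empty-3′UTR controls (negatives). Candidate
thresholds are the midpoints between consecutive distinct pooled
scores plus sentinels outside the range, so every achievable confusion
table is enumerated. The threshold maximizing accuracy is selected;
ties are broken toward higher specificity, then toward the more
negative threshold — a screen prefers few false positives over few
false negatives (the shipped default, −1.94, reflects a 99%-specific /
51%-sensitive operating point of this assay family).

## Seed-match sites

The seed of a mature miRNA is nucleotides 2–7 (6mer) or 2–8
(extended). Sites on the UTR are exact Watson–Crick reverse
complements of the seed, with two canonical refinements: an adenosine
in the UTR opposite miRNA position 1 (A1) and the extended match to
position 8 (m8). The four canonical types — 6mer, 7mer-A1, 7mer-m8,
8mer (m8+A1) — are collapsed to 6/7/8mer for reporting, and every
occurrence of the 6mer core is reported exactly once with the longest
applicable type (coordinates 1-based, scanning the given strand 5′→3′
only, since 3′UTR targeting is strand-defined). T is normalized to U
and matching is case-insensitive; miRNAs shorter than 8 nt are
rejected.

Seed-class enrichment groups miRNAs by the longest site type present
and compares each class's interaction scores with the no-site group by
a two-sample Kolmogorov–Smirnov test. The KS p-value is asymptotic:
with effective size m = n_a·n_b/(n_a+n_b), p = Q(λ) where Q is the
Kolmogorov survival function and λ = (√m + 0.12 + 0.11/√m)·D, the
classical Stephens refinement of the plain √m·D argument. The
refinement matters at this package's typical group sizes (tens vs
hundreds): simulated null p-values are then approximately uniform,
while the unrefined argument is visibly miscalibrated. p is floored at
2.2e−16. With groups of comparable small size (e.g. 30 vs 30) the
discreteness of D makes *any* KS p-value distribution sub-uniform;
the calibration statement above is for the unbalanced class-vs-rest
design the pipeline actually uses.

## Correlation to MYCN and the π-value

Per miRNA, the correlation with MYCN mRNA across cohort samples is
Spearman's rank correlation by default; Pearson is a configuration
switch and every record carries the method label. Two-sided p-values
are BH-adjusted across all testable miRNAs (constant rows are flagged
not-testable and excluded from the correction). Calls: inverse
(q ≤ 0.05, ρ < 0), positive (q ≤ 0.05, ρ > 0), otherwise n.s.

The signed significance π = −log10(p) · effect combines strength and
direction of evidence on one axis; for correlations the effect is ρ,
for progression it is Δslope. Inside the logarithm p is floored at
1e−300 so noise-free simulations (p = 0) stay finite.

The cohort is assumed MYCN non-amplified; amplified samples must be
excluded by the caller, since amplification decouples MYCN levels from
miRNA-mediated regulation.

## MYCN activity via preranked GSEA

For each miRNA, all genes are ranked by decreasing Spearman
correlation with that miRNA (ties broken lexicographically by gene id
for determinism). A miRNA that lowers MYCN protein levels should be
anti-correlated with MYC(N)-upregulated genes, i.e. those gene sets
should be enriched at the bottom of its ranking.

The enrichment score is the classical weighted running sum: walking
down the ranking, in-set genes add |statistic|/Σ_set|statistic|
(weight exponent 1; if all in-set statistics are zero, uniform weights
1/n_set are used), out-of-set genes subtract 1/(N − n_set); ES is the
extremum of largest magnitude. The extremum is selected on the running
sum rounded to 12 decimals so that 1-ulp accumulation noise cannot
flip a tie between a positive peak and a negative trough of equal
magnitude.

Because the input is a preranked list, the null is random gene sets:
`n_permutations` same-size sets drawn without replacement with
`numpy.random.default_rng(seed)`, one draw per permutation in order
(this fixed draw order makes runs reproducible and independently
checkable). NES = ES / mean(|null ES| of matching sign); the nominal p
and FDR are the matching-sign tail fractions — with a single ranked
list and a single set per call the pooled-null FDR estimate reduces to
the nominal p. A miRNA is negatively related to MYCN activity if any
gene set has NES < −2 and FDR < 0.25; the positive relation is the
mirrored rule (NES > +2, FDR < 0.25) applied when no set qualifies
negative, and a miRNA qualifying in both directions is flagged
ambiguous.

Known limitation: the random-gene null ignores inter-gene correlation.
When set genes are strongly co-expressed (as MYC target programs are),
the null understates the spread of ES and the call is
anti-conservative; in synthetic cohorts with a shared activity latent
variable this yields spurious "negative" calls for ~10–20% of
unrelated miRNAs. This is a property of the preranked random-gene
convention itself, not of this implementation.

## Relevance classification

Per screen hit: *relevant* if either axis shows inverse evidence
(expression call inverse, or activity call negative) and neither shows
positive evidence; *mycn-induced* if there is positive evidence and no
inverse evidence; *conflicting-excluded* when the axes oppose each
other (a miRNA cannot credibly both repress and be a readout of the
same protein); *no-data* when the miRNA is absent from the expression
platform; otherwise *not-supported*. The five categories partition the
hits, and the pipeline summary enforces that identity. A 2×2 χ² test
(Pearson, no continuity correction, 1 df) compares negative-enrichment
frequency between hits and non-hits.

## Murine progression dynamics

Cq values ≥ 32 are treated as non-detects and set missing. Global mean
normalization maps each retained value to expression = (sample mean
Cq) − Cq, so higher values mean higher abundance and each sample's
retained values average exactly zero. Samples with fewer than two
retained values are dropped with a warning.

Per miRNA, a single linear model
expression ~ intercept + time + genotype + time×genotype is fitted with
time numeric in weeks (1, 2, 6 in the default design) and genotype
coded TG = 1, WT = 0. The interaction coefficient *is* Δslope
(TG − WT), and its two-sided t-test p-value — BH-corrected across
miRNAs — tests the differential trajectory directly; fitting one joint
model rather than two separate regressions is what makes this p-value
well-defined. Zero-residual fits (noise-free data) are resolved
deterministically: an exactly zero interaction gives p = 1, a nonzero
one p → 0. Requirements per miRNA: ≥ 6 observations and both genotypes
at ≥ 2 distinct timepoints, else not-testable.

The signature score summarizes a directed miRNA list (e.g. known
MYC(N)-regulated miRNAs): each member is z-scored across samples
(population sd), and a sample's score is the mean of direction × z
over available members, with the covered fraction reported. The
direction list is an input; the package does not hardcode a published
signature, and test signatures are synthetic.

Two-group differential expression uses the mean difference on the
log2-like normalized scale as fold change and Student's equal-variance
t-test (Welch via a flag), BH-corrected. Cross-species comparison is
driven by an explicit murine-assay → human-miRNA mapping table; no
sequence-based matching is attempted.

## Synthetic data

The generators produce the structures the pipeline consumes with known
planted truth, under additive Gaussian noise on the log2 reporter
ratio and on Cq (the simplest model consistent with log-scale
readouts). Defaults mirror the study designs: 470 mimics, 29 planted
targets, two focal replicates, 36 analog screens; 160 cohort samples;
weeks 1/2/6 × two genotypes × n = 4.

- **Screen**: targeting miRNAs get a planted log2-ratio shift
  (default −3); analog screens carry no focal effect, so the
  per-miRNA analog median is ~0, and an optional per-miRNA bias shared
  by all screens exercises the centering step. Well-level scale factors
  cancel in the Firefly/Renilla ratio by construction.
- **Cohort**: one latent activity scalar per sample; MYCN = activity +
  noise; activity genes = activity + noise; planted miRNAs are built
  from the standardized MYCN row as −r·MYCN* + √(1−r²)·ε so the
  population correlation is exactly −r (and the sample correlation
  exactly −1 at r = 1, σ = 0). Non-planted miRNA and non-activity gene
  rows are pure noise scaled by `noise_sd`, so a zero-noise cohort has
  no spurious correlation structure (those rows degenerate to
  constants and are flagged not-testable downstream).
- **Time course**: Cq = baseline − slope·time + noise, lower Cq =
  higher expression. Because global mean normalization can only
  identify expression *relative to the per-sample panel mean*, the
  generator adds one ballast assay absorbing the summed planted drift
  per genotype, keeping the panel mean stable — the validity condition
  of global-mean normalization — so planted slopes are exactly
  identifiable. The ballast is flagged in the truth table.

What the generators do **not** emulate: plate-position and edge-well
effects, transfection-efficiency gradients, amplification chemistry,
count-like mean–variance relationships, batch structure, and realistic
miRNA co-expression families. Passing tests therefore demonstrate
correctness of the statistical machinery under its stated model, not
robustness to those real-data artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale designs chosen
to make the statistical checks well-powered while staying quick: 50
seeded screen replicates for sensitivity/specificity, 200 Monte-Carlo
replicates for Δslope recovery, 500 null replicates for KS
calibration, 100–300 GSEA permutations on cohorts of 200–500 genes.
The batch GSEA used by the pipeline shares the random-set null across
gene sets of equal size within one miRNA (the null depends only on the
ranked statistics and the set size) and draws its permutation block
from a per-miRNA `SeedSequence([seed, i])`, which keeps results
deterministic for a given configuration.

Other numerical conventions: BH adjustment is the standard step-up
(delegated to statsmodels), capped at 1 and order-preserving;
KS p floor 2.2e−16; π p floor 1e−300; correlation and t-tests come
from scipy; the genotype×time model from statsmodels OLS.
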