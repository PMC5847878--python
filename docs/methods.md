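# Methods note

This note records the statistical model behind `dietswitch`, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions the implementation
commits to.

## Study design and data model

The package targets a four-arm design on normalized log2 expression
data: a control group `C`, lifelong calorie restriction `CR`, lifelong
medium-fat diet `MF`, and a late-life switch group `CR-MF`. The
expression container is a genes × samples `pandas.DataFrame`; group
membership is a `pandas.Series` over sample ids. All statistics assume
the data are already normalized and approximately normal on the log2
scale within each group, with gene-specific variance shared across
groups (a pooled-variance model).

## Gene filtering

`filter_genes` keeps a gene iff

- interquartile range of the full row is **strictly** greater than
  `iqr_min` (default 0.1 log2 units), and
- at least `min_arrays` (default 5) samples exceed `intensity_min`
  (default 20) **strictly**, on the linear scale by default
  (`2^x > 20`, i.e. log2 value > log2 20 ≈ 4.322).

`intensity_scale="log2"` applies the threshold to the stored values
directly, for data whose units differ. Quartiles use
`numpy.percentile` with its default linear interpolation; this
convention is recorded on the `FilterResult` so downstream consumers
can detect it. Strict inequalities mean a gene exactly at a threshold
is removed — ties are resolved conservatively and deterministically.

## Moderated t-statistics

For contrast a−b with group sizes n_a, n_b, the per-gene pooled
variance s² has df = n_a + n_b − 2 residual degrees of freedom. The
empirical-Bayes model treats s² | σ² as scaled chi-square and σ² as
scaled inverse chi-square around a prior s₀² with d₀ degrees of
freedom, giving the posterior

s̃² = (d₀ s₀² + df s²)/(d₀ + df),  t = logFC / √(s̃² (1/n_a + 1/n_b)),

with t ~ t(df + d₀) under the null.

**Prior trend.** The prior scale is intensity-dependent: lowess of
log s² on mean intensity A (frac = `span` = 0.3, `it = 0`, i.e. no
robustness iterations). Under the model, E[log s² | σ²] is offset from
log σ² by b(df) = ψ(df/2) − log(df/2) (ψ the digamma function), and
the marginal fitted curve carries a further offset −b(d₀) from the
prior mixing; the prior scale is therefore recovered as

s₀² = exp( fitted − b(df) + b(d₀) ).

Omitting the b(d₀) term inflates the prior scale (by ≈ 31 % at
d₀ = 4, df = 4) and breaks null calibration; the correction is what
makes the implementation agree with the external R/limma cross-check
in the test suite to ~1e-8 in t and p.

**Prior degrees of freedom.** The residual spread of log s² around the
fitted trend, in excess of the sampling spread ψ′(df/2) (ψ′ the
trigamma function), estimates ψ′(d₀/2). d₀ is obtained by Newton
inversion of the trigamma function (monotone, quadratically
convergent; started from the large-argument approximation). When the
excess is ≤ 0 the data show no more spread than pure sampling noise,
and d₀ is capped at 1e6 (flagged `capped=True`) — numerically the
infinite-d₀ limit in which the prior is used alone. `trend="constant"`
replaces the lowess curve with the mean of log s², matching a
non-trended empirical-Bayes fit.

Defaults and rationale:

- `span = 0.3` — wide enough to be stable on a few thousand genes,
  narrow enough to track an exponential-in-A variance trend; the
  trend-recovery tests fit a planted slope of −0.2 per log2 unit to
  within ±0.05 at this span.
- `lowess it = 0` — robustness iterations downweight large s², which
  are expected under a chi-square with small df and must not be
  treated as outliers; with iterations on, d₀ is biased.
- at least 50 genes are required to fit the trend — below that the
  lowess curve and the residual-variance estimate are unstable, and
  the caller should use `trend="constant"` or `prior="ordinary"`.
- p-values are clipped to [tiny, 1]; genes with zero posterior
  variance (constant within groups and a capped prior of zero) are
  flagged in a `zero_variance` column and warned about rather than
  producing NaN.

`prior="ordinary"` bypasses moderation entirely (d₀ = 0) and matches
`scipy.stats.ttest_ind` to 1e-10; it exists as an oracle and for
designs with many replicates.

## Plasticity cascade

Three contrasts feed the classifier: CR vs MF, CR-MF vs CR, CR-MF vs
MF. With thresholds `p_de = 0.01`, `p_sim = 0.05`, `p_diff = 0.01`:

- DE set: p(CR vs MF) < p_de.
- `cr_associated`: in the DE set, p(CR-MF vs CR) ≥ p_sim **and**
  p(CR-MF vs MF) < p_diff **and** sign(logFC(CR-MF vs MF)) =
  sign(logFC(CR vs MF)). The sign condition rejects genes that are
  far from MF but on the wrong side; a zero fold change fails it
  (logged, not fatal).
- default mode (`mode="paper"`, a binary accounting of the DE set):
  every other DE gene is `mf_adapted`.
- `mode="extended"`: `mf_adapted` additionally requires
  p(CR-MF vs CR) < p_diff; the remainder is `intermediate`.

The asymmetric thresholds are deliberate: similarity to CR is a
failure to reject (so a lenient 0.05 keeps the test honest about its
power), while difference from MF is a positive claim (held to the
same 0.01 as the DE call). Raw p-values, not BH-adjusted ones, drive
the cascade; BH-adjusted values are reported alongside for gene-level
inspection. `percent_cr_associated(n_de, n_cr)` is round(100·n_cr/n_de,
1), with `None` when the DE set is empty.

## Ordination and shift statistic

Samples are first centered on the control group: per gene, the mean
over `C` samples is subtracted and the `C` samples are dropped (≥ 2
reference samples required). PCA treats samples as observations
(scikit-learn, full SVD, rank ≤ min(n_samples − 1, n_genes);
truncation warns). The shift statistic projects centroids in PC
space:

shift = ⟨c(CR-MF) − c(CR), c(MF) − c(CR)⟩ / ‖c(MF) − c(CR)‖²,

i.e. the scalar position of the switch centroid along the CR→MF axis:
exactly 0, 0.5, 1 when the switch group sits at CR, the midpoint, or
MF (verified to 1e-10 in the tests). The default number of components
is the smallest prefix reaching 80 % cumulative explained variance
(`min_cum_var = 0.8`) — enough to capture the diet axes while
excluding pure-noise directions; coincident CR and MF centroids make
the axis undefined and return NaN.

Upstream-regulator activation follows the consistency-score
convention: over a regulator's targets with p < threshold,
z = (n_consistent − n_inconsistent)/√n, where consistency means
sign(logFC) matches the network's expected sign; |z| > 2 labels
`activated`/`inhibited`. Phenotype correlation is plain Pearson with
pairwise NaN dropping; fewer than 3 complete pairs or a
zero-variance side yields NaN rather than an error.

## Synthetic generator

`generate_dataset` plants three gene classes — `null`, `plastic`
(switch mean = MF mean) and `persistent` (switch mean = CR mean) —
with exact counts by largest-remainder apportionment, shuffled.
Per gene: baseline A ~ U[4, 12] (the usable log2 intensity range of a
normalized array); σ² ~ d₀·σ₀²(A)/χ²(d₀) with
σ₀²(A) = exp(−0.8 − 0.2A) and d₀ = 4 — a decreasing
intensity–variance trend with σ₀ ranging ≈ 0.45 (dim) to ≈ 0.20
(bright), the regime variance moderation is designed for. Effect
sizes |δ| are folded-normal (default mean 1.0, sd 0.25 log2 units)
with Rademacher signs, so planted DE sets contain both directions.
Observations are i.i.d. normal around group means. Seeding uses
`numpy.random.SeedSequence(seed).spawn(2)` to split parameter and
noise streams, so identical arguments are bit-reproducible.

What it deliberately does **not** emulate: array-level technical
effects (batch, dye, background), correlation between genes,
non-normal heavy tails, missing values, mean–variance coupling beyond
the planted trend, and any genuine `intermediate` class (switch means
are exactly at CR or MF, so the generator provides clean anchors for
the shift statistic rather than a realistic continuum). An optional
`c_offset_sd` perturbs the control-group mean to decouple the
reference from MF.

## Validation regimes

The acceptance tests and `scripts/acceptance.py` fix their own problem
sizes as a package choice, selected once for power-per-runtime:
10,000 genes × 5/group for null calibration (exact binomial 99 % band
on the fraction of p < 0.01, plus a Kolmogorov–Smirnov uniformity
check); 5,000 genes × 8/group × 20 seeds for classifier recovery with
a strong-effect spec (δ mean 1.6, sd 0.2 — at least ~1.5σ effects, the
regime in which near-complete recovery is the correct expectation);
10,000 genes × 20 seeds for d₀ recovery; 2,000 genes × 6/group × 20
seeds for planted-shift ordination. Exact-oracle tests (classical t,
cascade truth table, shift anchors, activation closed form) are
size-independent.

## Limitations

- The pooled-variance model assumes homoscedasticity across groups;
  strong group-specific variance violates the t reference
  distribution.
- The cascade's `cr_associated` call rests on a non-rejection
  (similarity to CR), so its meaning degrades at very small n where
  power against CR is low.
- The shift statistic is a one-dimensional projection; genuinely
  heterogeneous responses (part of the transcriptome plastic, part
  persistent) yield intermediate values that should be read together
  with the gene-level labels, not instead of them.
- The lowess trend is fitted without robustness iterations by design;
  data containing genuine gross outliers in s² (e.g. corrupted rows)
  should be cleaned before fitting.
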