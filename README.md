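# dietswitch

Transcriptome plasticity analysis for diet-switch study designs, with a
matched synthetic-data generator.

## Scientific problem

Lifelong calorie restriction (CR) leaves a broad signature in the
transcriptome of metabolic tissues relative to an ad-libitum
medium-fat diet (MF). When CR animals are switched to the MF diet late
in life, each gene in that signature can respond in one of two ways:
it can **adapt** to the new diet (its expression moves to the MF
level), or it can **persist** at the CR level, remaining associated
with the former diet. Quantifying how much of the CR signature is
plastic versus persistent requires three things this package
implements:

1. a well-calibrated per-gene differential-expression test that is
   stable at small group sizes (moderated t-statistics with an
   intensity-dependent variance prior);
2. a three-contrast decision cascade that assigns each differential
   gene a plasticity label (`cr_associated`, `mf_adapted`, optionally
   `intermediate`);
3. a sample-level ordination view (PCA relative to a control
   reference) with a scalar **shift statistic** locating the switch
   group's centroid on the axis from the CR centroid to the MF
   centroid (0 = stayed at CR, 1 = fully adapted to MF).

A seeded synthetic generator with planted gene classes provides ground
truth for validating the whole chain, and small utilities cover
pathway-membership fractions, upstream-regulator activation z-scores,
and expression–phenotype correlation.

## Core model

For gene *g* with groupwise sample variance s²_g on df residual
degrees of freedom, and mean log2 intensity A_g, the moderated test
shrinks s²_g toward an intensity-dependent prior s₀²(A_g) fitted by
lowess on the (A_g, log s²_g) cloud. The prior degrees of freedom d₀
are estimated by matching the observed excess spread of log s²_g over
its theoretical scaled-chi-square spread (a trigamma inversion). The
posterior variance and statistic are

```
s̃²_g = (d₀·s₀²(A_g) + df·s²_g) / (d₀ + df)
t_g  = logFC_g / sqrt( s̃²_g · (1/n_a + 1/n_b) )      ~ t(df + d₀) under H0
```

Setting d₀ = 0 recovers the classical pooled-variance t-test, and
d₀ → ∞ uses the prior alone; both limits are exercised in the tests.

The plasticity cascade uses three contrasts — CR vs MF, switch vs CR,
switch vs MF. A gene is in the DE set if p(CR vs MF) < 0.01. A DE gene
is `cr_associated` if it is *not* distinguishable from CR
(p(switch vs CR) ≥ 0.05), *is* distinguishable from MF
(p(switch vs MF) < 0.01), and its switch-vs-MF fold change agrees in
sign with its CR-vs-MF fold change; otherwise it is `mf_adapted` (an
extended mode additionally separates an `intermediate` label).

## Worked example

```python
import numpy as np
from dietswitch import (
    GeneClassSpec, generate_dataset, filter_genes, run_de,
    classify_plasticity, summarize_classification, evaluate_recovery,
    reference_center, pca_samples, shift_statistic,
)

spec = GeneClassSpec(f_null=0.6, f_plastic=0.25, f_persistent=0.15,
                     delta_mean=1.6, delta_sd=0.2)
ds = generate_dataset(n_genes=3000, n_per_group=8, class_spec=spec, seed=11)

res = filter_genes(ds.matrix)      # IQR > 0.1 and >= 5 arrays above 20 (linear)
m = res.matrix                     # 2995 of 3000 genes retained

de_cr_mf = run_de(m, ds.sheet, "CR", "MF")
de_sw_cr = run_de(m, ds.sheet, "CR-MF", "CR")
de_sw_mf = run_de(m, ds.sheet, "CR-MF", "MF")

calls = classify_plasticity(de_cr_mf, de_sw_cr, de_sw_mf)
print(summarize_classification(calls))

metrics = evaluate_recovery(calls, ds.truth.loc[m.index])
print(metrics.sensitivity, metrics.specificity)

pca = pca_samples(reference_center(m, ds.sheet, "C"), 10)
print(shift_statistic(pca, ds.sheet))
```

Output (seed 11):

- Filtering keeps 2995 of 3000 genes (1 fails the IQR rule, 4 fail the
  intensity rule).
- The fitted variance prior for the CR-vs-MF contrast has
  d₀ ≈ 4.01 extra degrees of freedom, so each gene's test runs on
  ≈ 18.0 total df instead of 14.
- The cascade finds a DE set of 1181 genes: 414 `cr_associated`
  and 767 `mf_adapted`, i.e. `pct_cr_associated = 35.1`.
- Against the planted truth, sensitivity is 0.945 (persistent genes
  labelled `cr_associated`) and specificity is 1.0 (plastic genes
  labelled `mf_adapted`).
- The ordination shift statistic is 0.627 — the switch-group centroid
  sits about 63 % of the way from CR toward MF, consistent with a
  gene pool that is 0.25 plastic / 0.15 persistent.

The same chain is scriptable from the command line
(`dietswitch simulate | filter | de | classify | pathways | pca |
upstream | correlate`); see `dietswitch --help`.

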