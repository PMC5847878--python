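"""Intensity-based empirical-Bayes moderated t-statistics.

Per-gene two-group contrasts are tested with a moderated t-statistic
whose prior variance depends on mean log2 intensity.  The per-gene
residual variances ``s_g^2`` are modelled as scaled inverse-chi-square
draws around an intensity-dependent prior scale ``s0^2(A)`` with prior
degrees of freedom ``d0``; the posterior variance

    s~_g^2 = (d0 * s0_g^2 + df * s_g^2) / (d0 + df)

replaces the raw variance in the t-statistic, which then has
``df + d0`` degrees of freedom.  The prior trend is a local regression
of ``log s_g^2`` on ``A_g`` and ``d0`` is moment-matched by inverting
the trigamma function, the standard hierarchical-model estimator for
log chi-square spread.  With ``d0 = 0`` the statistic reduces exactly
to the classical pooled-variance two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

D0_CAP = 1e6
MIN_GENES_FOR_TREND = 50


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group contrast: logFC = mean(group_a) - mean(group_b)."""

    group_a: str
    group_b: str
    name: str = ""

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ValueError("contrast groups must differ")
        if not self.name:
            object.__setattr__(self, "name", f"{self.group_a}_vs_{self.group_b}")


@dataclass
class ModerationFit:
    """Fitted variance prior: trend-evaluated prior scale and prior df.

    ``d0`` is the prior degrees of freedom (``capped`` marks the
    effectively-infinite case, where per-gene variances are fully shrunk
    to the trend).  ``s0_sq`` holds the prior variance evaluated at each
    gene's mean intensity.
    """

    d0: float
    s0_sq: pd.Series
    df_resid: float
    span: float
    trend: str
    capped: bool = False
    var_log_resid: float = float("nan")


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_trend(
    s_sq,
    A,
    df_resid: float,
    span: float = 0.3,
    trend: str = "intensity",
    d0_cap: float = D0_CAP,
) -> ModerationFit:
    """Fit the intensity-dependent variance prior.

    Parameters
    ----------
    s_sq
        Per-gene residual variances (pandas Series or array).
    A
        Per-gene mean log2 intensities, aligned with ``s_sq``.
    df_resid
        Residual degrees of freedom of each variance estimate.
    span
        Local-regression bandwidth as a fraction of the data.
    trend
        ``"intensity"`` for a lowess smooth of log variance on
        intensity, ``"constant"`` for a flat (intensity-free) prior.

    Notes
    -----
    Under the hierarchical model ``s^2 ~ sigma^2 chi2(df)/df`` with
    ``sigma^2 ~ d0 sigma0^2 / chi2(d0)``,

        E[log s^2] = log sigma0^2 + b(df) - b(d0),
        b(x) = digamma(x/2) - log(x/2),

    so the fitted smooth of log variances is bias-corrected by
    ``-b(df) + b(d0)`` to target the prior scale rather than the mean of
    log variances (``b(d0) -> 0`` in the infinite-``d0`` limit).  The
    residual spread of ``log s^2`` around the trend equals
    ``trigamma(df/2) + trigamma(d0/2)``; ``d0`` is recovered by
    inverting the trigamma function, and capped (treated as infinite
    shrinkage) when the residual spread does not exceed the pure
    sampling contribution.
    """
    s_sq = pd.Series(np.asarray(s_sq, dtype=float), index=getattr(s_sq, "index", None))
    A = np.asarray(A, dtype=float)
    if len(s_sq) != len(A):
        raise ValueError("s_sq and A must be aligned")
    if len(s_sq) < MIN_GENES_FOR_TREND:
        raise ValueError(
            f"need at least {MIN_GENES_FOR_TREND} genes to fit a variance trend, "
            f"got {len(s_sq)}"
        )
    if not (np.isfinite(s_sq.to_numpy()).all() and np.isfinite(A).all()):
        raise ValueError("s_sq and A must be finite")
    nonpos = s_sq.index[s_sq.to_numpy() <= 0] if s_sq.index is not None else None
    if (s_sq.to_numpy() <= 0).any():
        names = list(nonpos[:10]) if nonpos is not None else []
        raise ValueError(f"non-positive variances for gene(s): {names}")
    if trend not in ("intensity", "constant"):
        raise ValueError("trend must be 'intensity' or 'constant'")

    z = np.log(s_sq.to_numpy())
    if trend == "intensity":
        fitted = lowess(z, A, frac=span, it=0, return_sorted=False)
    else:
        fitted = np.full_like(z, z.mean())
    resid = z - fitted
    var_resid = float(np.var(resid, ddof=1))
    sampling = float(polygamma(1, df_resid / 2.0))
    excess = var_resid - sampling
    if excess <= 0:
        d0, capped = d0_cap, True
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        capped = d0 >= d0_cap
        d0 = min(d0, d0_cap)
    b_df = float(digamma(df_resid / 2.0) - np.log(df_resid / 2.0))
    b_d0 = 0.0 if capped else float(digamma(d0 / 2.0) - np.log(d0 / 2.0))
    s0_sq = pd.Series(np.exp(fitted - b_df + b_d0), index=s_sq.index, name="s0_sq")
    return ModerationFit(
        d0=float(d0),
        s0_sq=s0_sq,
        df_resid=float(df_resid),
        span=span,
        trend=trend,
        capped=capped,
        var_log_resid=var_resid,
    )


def _group_stats(matrix: pd.DataFrame, sheet: pd.Series, group: str):
    samples = sheet.index[sheet == group]
    samples = [s for s in matrix.columns if s in set(samples)]
    if len(samples) < 2:
        raise ValueError(
            f"group {group!r} has {len(samples)} sample(s) in the matrix; "
            "need at least 2"
        )
    sub = matrix[samples].to_numpy(dtype=float)
    return sub.mean(axis=1), sub.var(axis=1, ddof=1), len(samples), sub


def moderated_t_test(
    matrix: pd.DataFrame,
    sheet: pd.Series,
    contrast: ContrastSpec,
    fit: ModerationFit | str = "ordinary",
) -> pd.DataFrame:
    """Per-gene moderated (or classical) two-sample t-test.

    Returns a DataFrame indexed by gene id with columns ``logFC``
    (mean(group_a) - mean(group_b), log2 units), ``A`` (mean log2
    intensity over both groups), ``s_sq`` (pooled residual variance),
    ``t_mod``, ``df_total``, ``p`` (two-sided), ``p_bh``
    (Benjamini-Hochberg adjusted, informational only) and
    ``zero_variance`` (flags genes whose posterior variance is zero; for
    these ``p`` is reported at the machine minimum rather than failing).

    With ``fit="ordinary"`` no moderation is applied and the result is
    the classical pooled-variance t-test.
    """
    mean_a, var_a, n_a, sub_a = _group_stats(matrix, sheet, contrast.group_a)
    mean_b, var_b, n_b, sub_b = _group_stats(matrix, sheet, contrast.group_b)
    df_resid = n_a + n_b - 2
    s_sq = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df_resid
    logfc = mean_a - mean_b
    A = np.concatenate([sub_a, sub_b], axis=1).mean(axis=1)

    if isinstance(fit, str):
        if fit != "ordinary":
            raise ValueError("fit must be a ModerationFit or the string 'ordinary'")
        d0 = 0.0
        s0_sq = np.zeros_like(s_sq)
    else:
        if not fit.s0_sq.index.equals(matrix.index):
            raise ValueError("ModerationFit was computed on a different gene set")
        if fit.df_resid != df_resid:
            warnings.warn(
                f"ModerationFit df_resid={fit.df_resid} differs from contrast "
                f"df_resid={df_resid}",
                stacklevel=2,
            )
        d0 = fit.d0
        s0_sq = fit.s0_sq.to_numpy()

    if d0 == 0:
        s_tilde = s_sq.copy()
        df_total = float(df_resid)
    else:
        s_tilde = (d0 * s0_sq + df_resid * s_sq) / (d0 + df_resid)
        df_total = float(df_resid + d0)

    zero_var = s_tilde <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} gene(s) with zero posterior variance; "
            "p reported at machine minimum",
            stacklevel=2,
        )
    se = np.sqrt(np.where(zero_var, np.nan, s_tilde) * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = np.where(zero_var, np.sign(logfc) * np.inf, logfc / se)
        t_mod = np.where(zero_var & (logfc == 0), 0.0, t_mod)
    p = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "A": A,
            "s_sq": s_sq,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "p_bh": multipletests(p, method="fdr_bh")[1],
            "zero_variance": zero_var,
        },
        index=matrix.index,
    )


def run_de(
    matrix: pd.DataFrame,
    sheet: pd.Series,
    group_a: str,
    group_b: str,
    prior: str = "intensity",
    span: float = 0.3,
) -> pd.DataFrame:
    """Convenience pipeline: pooled variances, trend fit, moderated test.

    ``prior`` selects the variance prior: ``"intensity"`` (lowess trend
    on mean intensity), ``"constant"`` (flat prior) or ``"ordinary"``
    (no moderation, classical t-test).
    """
    contrast = ContrastSpec(group_a, group_b)
    if prior == "ordinary":
        return moderated_t_test(matrix, sheet, contrast, "ordinary")
    if prior not in ("intensity", "constant"):
        raise ValueError("prior must be 'intensity', 'constant' or 'ordinary'")
    mean_a, var_a, n_a, sub_a = _group_stats(matrix, sheet, group_a)
    mean_b, var_b, n_b, sub_b = _group_stats(matrix, sheet, group_b)
    df_resid = n_a + n_b - 2
    s_sq = pd.Series(
        ((n_a - 1) * var_a + (n_b - 1) * var_b) / df_resid, index=matrix.index
    )
    A = np.concatenate([sub_a, sub_b], axis=1).mean(axis=1)
    fit = fit_variance_trend(s_sq, A, df_resid, span=span, trend=prior)
    return moderated_t_test(matrix, sheet, contrast, fit)
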