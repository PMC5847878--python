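"""Control-referenced ordination, regulator activation and correlation.

Sample-level PCA of the expression matrix after normalising every gene
to the control-diet group, with a scalar "shift" statistic locating the
diet-switch group's centroid on the line from the CR centroid (0) to
the MF centroid (1).  Also: a sign-concordance activation z-score for
upstream regulators (z > 2 activated, z < -2 inhibited) and per-gene
Pearson correlation of expression with a numeric phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


def reference_center(
    matrix: pd.DataFrame, sheet: pd.Series, reference_group: str = "C"
) -> pd.DataFrame:
    """Subtract the per-gene reference-group mean; drop reference samples.

    Every gene is normalised to the mean of the reference (control)
    samples, so the returned values are log2 expression relative to the
    control diet.  The reference samples themselves are excluded from
    the result.
    """
    ref = [s for s in matrix.columns if sheet.get(s) == reference_group]
    if len(ref) < 2:
        raise ValueError(
            f"reference group {reference_group!r} needs >= 2 samples in the "
            f"matrix, found {len(ref)}"
        )
    others = [s for s in matrix.columns if s not in set(ref)]
    ref_mean = matrix[ref].mean(axis=1)
    return matrix[others].sub(ref_mean, axis=0)


@dataclass
class OrdinationResult:
    """Sample scores and explained-variance fractions of a sample PCA."""

    scores: pd.DataFrame  # samples x components, columns PC1..PCk
    explained_variance_ratio: np.ndarray
    n_components: int
    scaled: bool = field(default=False)

    def centroids(self, sheet: pd.Series, n_components: int | None = None) -> pd.DataFrame:
        """Per-group mean scores over the first ``n_components`` axes."""
        k = self.n_components if n_components is None else n_components
        scores = self.scores.iloc[:, :k]
        groups = sheet.reindex(scores.index)
        return scores.groupby(groups, observed=True).mean()


def pca_samples(
    centered: pd.DataFrame,
    n_components: int = 10,
    scale: bool = False,
) -> OrdinationResult:
    """PCA with samples as observations and genes as variables.

    Genes are mean-centered across the retained samples before the
    decomposition; by default no unit-variance scaling is applied
    (covariance PCA), ``scale=True`` switches to correlation PCA.
    ``n_components`` beyond the matrix rank is truncated with a warning.
    """
    n_genes, n_samples = centered.shape
    if n_samples < 2 or n_genes < 2:
        raise ValueError("need at least 2 samples and 2 genes")
    rank = min(n_samples - 1, n_genes)
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncated",
            stacklevel=2,
        )
        n_components = rank
    X = centered.to_numpy(dtype=float).T  # samples x genes
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("scale=True with zero-variance gene(s)")
        X = X / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=centered.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_components=n_components,
        scaled=scale,
    )


def shift_statistic(
    result: OrdinationResult,
    sheet: pd.Series,
    switch_group: str = "CR-MF",
    from_group: str = "CR",
    to_group: str = "MF",
    n_components: int | None = None,
    min_cum_var: float = 0.8,
) -> float:
    """Position of the switch-group centroid between two anchor groups.

    shift = <c(switch) - c(from), c(to) - c(from)> / ||c(to) - c(from)||^2

    computed on group centroids in the retained component space: 0 means
    the switch group sits at the CR centroid, 1 at the MF centroid;
    values outside [0, 1] indicate over- or undershoot.  By default the
    leading components reaching ``min_cum_var`` cumulative explained
    variance are used.  Returns NaN when the anchor centroids coincide.
    """
    if n_components is None:
        cum = np.cumsum(result.explained_variance_ratio)
        n_components = int(np.searchsorted(cum, min_cum_var) + 1)
        n_components = min(n_components, result.n_components)
    cent = result.centroids(sheet, n_components)
    for g in (switch_group, from_group, to_group):
        if g not in cent.index:
            raise ValueError(f"group {g!r} has no retained samples")
    axis = cent.loc[to_group] - cent.loc[from_group]
    denom = float(axis @ axis)
    if denom == 0:
        return float("nan")
    return float((cent.loc[switch_group] - cent.loc[from_group]) @ axis / denom)


def load_regulator_network(path) -> pd.DataFrame:
    """Read a regulator->target sign network TSV.

    Columns: regulator_id, target_id, expected_sign (+1/-1, the expected
    direction of the target's expression change when the regulator is
    active).  Duplicate (regulator, target) pairs are rejected.
    """
    net = pd.read_csv(path, sep="\t", dtype={"expected_sign": int})
    for col in ("regulator_id", "target_id", "expected_sign"):
        if col not in net.columns:
            raise ValueError(f"{path}: network must have a {col!r} column")
    if not net["expected_sign"].isin([1, -1]).all():
        raise ValueError(f"{path}: expected_sign values must be +1 or -1")
    if net.duplicated(["regulator_id", "target_id"]).any():
        raise ValueError(f"{path}: duplicate (regulator, target) pair(s)")
    return net


def activation_zscore(
    network: pd.DataFrame,
    de: pd.DataFrame,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Sign-concordance activation z-score per regulator.

    Targets with a DE p-value below ``p_threshold`` are tallied: a
    target is consistent when the sign of its fold change matches the
    expected sign under regulator activation.  With ``n`` significant
    targets, z = (n_consistent - n_inconsistent) / sqrt(n); the state is
    ``activated`` (z > 2), ``inhibited`` (z < -2) or ``uncertain``.
    Regulators with no significant targets are reported uncertain with z
    NaN.  Targets with zero fold change count as inconsistent.
    """
    if network.duplicated(["regulator_id", "target_id"]).any():
        raise ValueError("duplicate (regulator, target) pair(s) in network")
    rows = []
    sig = de[de["p"] < p_threshold]
    signs = np.sign(sig["logFC"])
    for reg, targets in network.groupby("regulator_id", sort=True):
        hit = targets[targets["target_id"].isin(sig.index)]
        n = len(hit)
        if n == 0:
            rows.append(
                {
                    "regulator_id": reg,
                    "n": 0,
                    "n_consistent": 0,
                    "n_inconsistent": 0,
                    "z": float("nan"),
                    "state": "uncertain",
                }
            )
            continue
        observed = signs.loc[hit["target_id"]].to_numpy()
        n_cons = int((observed == hit["expected_sign"].to_numpy()).sum())
        n_inc = n - n_cons
        z = (n_cons - n_inc) / np.sqrt(n)
        state = "activated" if z > 2 else "inhibited" if z < -2 else "uncertain"
        rows.append(
            {
                "regulator_id": reg,
                "n": n,
                "n_consistent": n_cons,
                "n_inconsistent": n_inc,
                "z": float(z),
                "state": state,
            }
        )
    return pd.DataFrame(rows).set_index("regulator_id")


def correlate_phenotype(
    pheno: pd.Series,
    matrix: pd.DataFrame,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each gene's expression with a phenotype.

    Samples with a missing phenotype value are dropped pairwise; the
    number of complete pairs is reported per gene.  Two-sided p-values
    come from the t transform with n - 2 degrees of freedom.  Genes with
    fewer than 3 complete pairs or zero variance on either side get NaN
    r and p.
    """
    if genes is None:
        genes = list(matrix.index)
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ValueError(f"gene(s) not in matrix: {missing[:10]}")
    common = [s for s in matrix.columns if s in set(pheno.index)]
    if len(common) < 3:
        raise ValueError("phenotype and matrix share fewer than 3 samples")
    pv = pheno.reindex(common).to_numpy(dtype=float)
    rows = []
    for g in genes:
        x = matrix.loc[g, common].to_numpy(dtype=float)
        ok = np.isfinite(pv) & np.isfinite(x)
        n = int(ok.sum())
        if n < 3 or np.std(x[ok]) == 0 or np.std(pv[ok]) == 0:
            rows.append({"gene_id": g, "r": float("nan"), "p": float("nan"), "n": n})
            continue
        r, p = stats.pearsonr(x[ok], pv[ok])
        rows.append({"gene_id": g, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows).set_index("gene_id")
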