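"""Synthetic four-group expression data with planted ground truth.

The generator emulates a normalized log2 expression matrix from a
four-arm dietary study: a control group (C), lifelong calorie
restriction (CR), lifelong medium fat (MF) and a CR-to-MF diet-switch
group (CR-MF).  Each gene belongs to one of three planted classes:

``null``
    no diet effect anywhere (all four group means equal);
``plastic``
    a CR-vs-MF effect delta that the switch group loses — its mean
    equals the MF mean (the gene adapts to the new diet);
``persistent``
    a CR-vs-MF effect that the switch group keeps — its mean equals the
    CR mean (the gene stays CR-associated).

Per-gene variances are drawn from a scaled inverse-chi-square around an
intensity-dependent trend, giving the heteroscedastic, intensity-linked
noise that intensity-based variance moderation is designed to exploit.
Observations are normal on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("C", "CR", "CR-MF", "MF")


@dataclass(frozen=True)
class GeneClassSpec:
    """Gene-class mix and CR-vs-MF effect-size distribution.

    Fractions must sum to 1.  Effect magnitudes are drawn from
    N(delta_mean, delta_sd^2) (folded to be positive) on the log2 scale
    and signs are Rademacher (+/-1 with probability 1/2), so the planted
    DE set contains both up- and down-regulated genes.
    """

    f_null: float = 0.8
    f_plastic: float = 0.1
    f_persistent: float = 0.1
    delta_mean: float = 1.0
    delta_sd: float = 0.25

    def __post_init__(self):
        for name in ("f_null", "f_plastic", "f_persistent"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.f_null + self.f_plastic + self.f_persistent
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be >= 0")


@dataclass(frozen=True)
class VarianceModel:
    """Intensity range and intensity-dependent variance trend.

    Baseline mean log2 intensities A_g are uniform on [A_low, A_high].
    The prior variance trend is sigma0^2(A) = exp(c0 - c1 * A) with
    c1 >= 0, a positive, monotone non-increasing function of intensity;
    per-gene variances are scaled inverse-chi-square draws around it
    with ``d0_true`` prior degrees of freedom.

    Defaults put sigma0 near 0.30 at mid intensity (A = 8), ranging from
    about 0.45 at the dim end to 0.20 at the bright end — the magnitude
    of residual spread typical of normalized expression arrays.
    """

    A_low: float = 4.0
    A_high: float = 12.0
    c0: float = -0.8
    c1: float = 0.2
    d0_true: float = 4.0

    def __post_init__(self):
        if not self.A_low < self.A_high:
            raise ValueError("A_low must be < A_high")
        if self.c1 < 0:
            raise ValueError("c1 must be >= 0 (non-increasing trend)")
        if self.d0_true <= 0:
            raise ValueError("d0_true must be > 0")

    def sigma0_sq(self, A):
        return np.exp(self.c0 - self.c1 * np.asarray(A, dtype=float))


@dataclass
class SyntheticDataset:
    """Generated matrix, sample sheet and per-gene ground truth."""

    matrix: pd.DataFrame
    sheet: pd.Series
    truth: pd.DataFrame  # columns: class, delta, A, sigma2
    seed: int


@dataclass
class RecoveryMetrics:
    """Classifier performance against planted truth, within the DE set.

    sensitivity
        Share of truth-persistent genes in the detected DE set that were
        labelled cr_associated.
    specificity
        Share of truth-plastic genes in the detected DE set that were
        labelled mf_adapted.
    f_hat / f_true
        Estimated vs true CR-associated fraction of the DE set.

    Undefined ratios (zero denominators, e.g. an empty DE set) are NaN.
    """

    sensitivity: float
    specificity: float
    f_hat: float
    f_true: float
    n_de: int = 0
    n_persistent_in_de: int = 0
    n_plastic_in_de: int = 0


def _class_counts(n_genes: int, spec: GeneClassSpec) -> tuple[int, int, int]:
    # largest-remainder apportionment so counts match fractions up to rounding
    fracs = np.array([spec.f_null, spec.f_plastic, spec.f_persistent])
    raw = fracs * n_genes
    counts = np.floor(raw).astype(int)
    remainder = n_genes - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return int(counts[0]), int(counts[1]), int(counts[2])


def generate_dataset(
    n_genes: int,
    n_per_group: int,
    class_spec: GeneClassSpec | None = None,
    var_model: VarianceModel | None = None,
    seed: int = 0,
    c_offset_sd: float = 0.0,
) -> SyntheticDataset:
    """Generate a seeded four-group dataset with planted truth.

    Per gene: baseline intensity A_g ~ U[A_low, A_high]; variance
    sigma_g^2 ~ d0 * sigma0^2(A_g) / chi2(d0); the MF (and C) group mean
    is A_g, the CR mean is A_g + delta_g (delta_g = 0 for null genes),
    and the CR-MF mean equals the CR mean for persistent genes and the
    MF mean for plastic (and null) genes.  Observations are
    N(group mean, sigma_g^2).  ``c_offset_sd > 0`` optionally adds an
    independent per-gene normal offset to the C group mean (the control
    group is only used as an ordination reference downstream).

    Identical arguments produce bit-identical output.
    """
    if class_spec is None:
        class_spec = GeneClassSpec()
    if var_model is None:
        var_model = VarianceModel()
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (group variance undefined)")

    ss = np.random.SeedSequence(seed)
    rng_params, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    n_null, n_plastic, n_persistent = _class_counts(n_genes, class_spec)
    classes = np.array(
        ["null"] * n_null + ["plastic"] * n_plastic + ["persistent"] * n_persistent
    )
    rng_params.shuffle(classes)

    A = rng_params.uniform(var_model.A_low, var_model.A_high, n_genes)
    sigma2 = (
        var_model.d0_true
        * var_model.sigma0_sq(A)
        / rng_params.chisquare(var_model.d0_true, n_genes)
    )
    magnitude = np.abs(
        rng_params.normal(class_spec.delta_mean, class_spec.delta_sd, n_genes)
    )
    sign = rng_params.choice([-1.0, 1.0], n_genes)
    delta = np.where(classes == "null", 0.0, sign * magnitude)

    mean_mf = A
    mean_cr = A + delta
    mean_crmf = np.where(classes == "persistent", mean_cr, mean_mf)
    mean_c = A.copy()
    if c_offset_sd > 0:
        mean_c = mean_c + rng_params.normal(0.0, c_offset_sd, n_genes)

    width = len(str(n_genes))
    gene_ids = pd.Index(
        [f"gene_{i + 1:0{width}d}" for i in range(n_genes)], name="gene_id"
    )
    sample_ids, groups_col = [], []
    blocks = []
    sd = np.sqrt(sigma2)
    for group, mean in (
        ("C", mean_c),
        ("CR", mean_cr),
        ("CR-MF", mean_crmf),
        ("MF", mean_mf),
    ):
        noise = rng_noise.normal(0.0, 1.0, (n_genes, n_per_group))
        blocks.append(mean[:, None] + sd[:, None] * noise)
        tag = group.replace("-", "")
        sample_ids += [f"{tag}_{j + 1:02d}" for j in range(n_per_group)]
        groups_col += [group] * n_per_group

    matrix = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=gene_ids, columns=sample_ids
    )
    sheet = pd.Series(
        groups_col, index=pd.Index(sample_ids, name="sample_id"), name="group"
    )
    truth = pd.DataFrame(
        {"class": classes, "delta": delta, "A": A, "sigma2": sigma2}, index=gene_ids
    )
    return SyntheticDataset(matrix=matrix, sheet=sheet, truth=truth, seed=seed)


def evaluate_recovery(calls: pd.DataFrame, truth: pd.DataFrame) -> RecoveryMetrics:
    """Score plasticity calls against planted truth.

    All ratios are computed within the detected DE set (every label
    other than ``not_de``); zero denominators yield NaN rather than
    failing.
    """
    if set(calls.index) != set(truth.index):
        raise ValueError("calls and truth must index the same genes")
    truth = truth.reindex(calls.index)
    label = calls["label"].astype(str)
    in_de = label != "not_de"
    cls = truth["class"]

    pers_de = in_de & (cls == "persistent")
    plas_de = in_de & (cls == "plastic")
    n_de = int(in_de.sum())

    def ratio(num, den):
        return float(num) / den if den else float("nan")

    return RecoveryMetrics(
        sensitivity=ratio((pers_de & (label == "cr_associated")).sum(), pers_de.sum()),
        specificity=ratio((plas_de & (label == "mf_adapted")).sum(), plas_de.sum()),
        f_hat=ratio((label == "cr_associated").sum(), n_de),
        f_true=ratio(pers_de.sum(), n_de),
        n_de=n_de,
        n_persistent_in_de=int(pers_de.sum()),
        n_plastic_in_de=int(plas_de.sum()),
    )


def write_dataset(ds: SyntheticDataset, prefix: str) -> list[str]:
    """Write ``<prefix>_expr.tsv``, ``<prefix>_samples.tsv`` and
    ``<prefix>_truth.tsv``; returns the paths written."""
    expr, samples, truth = (
        f"{prefix}_expr.tsv",
        f"{prefix}_samples.tsv",
        f"{prefix}_truth.tsv",
    )
    ds.matrix.to_csv(expr, sep="\t", index_label="gene_id")
    ds.sheet.rename("group").to_csv(samples, sep="\t", index_label="sample_id")
    ds.truth.to_csv(truth, sep="\t", index_label="gene_id")
    return [expr, samples, truth]
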