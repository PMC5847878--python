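"""Three-contrast plasticity classification of diet-switch genes.

Genes differentially expressed between lifelong calorie restriction
(CR) and medium fat (MF) are screened for whether, after the CR-to-MF
diet switch, their expression stayed at the CR profile
(``cr_associated``) or adapted to the MF profile (``mf_adapted``).  A
gene is CR-associated when the switch group is statistically
indistinguishable from CR, remains significantly different from MF, and
changes in the same direction relative to MF as lifelong CR does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("cr_associated", "mf_adapted", "intermediate", "not_de")


@dataclass(frozen=True)
class PlasticityThresholds:
    """p-value thresholds of the screening cascade.

    p_de
        DE threshold for the CR vs MF contrast (membership of the DE set).
    p_sim
        Similarity threshold for CR-MF vs CR: p >= p_sim counts as "no
        differential expression", i.e. the switch group stayed at CR.
    p_diff
        Difference threshold for CR-MF vs MF: the switch group must stay
        significantly different from MF.
    """

    p_de: float = 0.01
    p_sim: float = 0.05
    p_diff: float = 0.01

    def __post_init__(self):
        for name in ("p_de", "p_sim", "p_diff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def _aligned(de_cr_vs_mf, de_crmf_vs_cr, de_crmf_vs_mf):
    idx = de_cr_vs_mf.index
    for other in (de_crmf_vs_cr, de_crmf_vs_mf):
        if len(other.index) != len(idx) or set(other.index) != set(idx):
            raise ValueError("the three DE tables must cover identical gene sets")
    return de_crmf_vs_cr.reindex(idx), de_crmf_vs_mf.reindex(idx)


def classify_plasticity(
    de_cr_vs_mf: pd.DataFrame,
    de_crmf_vs_cr: pd.DataFrame,
    de_crmf_vs_mf: pd.DataFrame,
    thresholds: PlasticityThresholds | None = None,
    mode: str = "paper",
) -> pd.DataFrame:
    """Label every gene from the three contrast tables.

    DE set: genes with p(CR vs MF) < ``p_de``.  Within it a gene is
    ``cr_associated`` iff p(CR-MF vs CR) >= ``p_sim`` AND
    p(CR-MF vs MF) < ``p_diff`` AND the CR vs MF and CR-MF vs MF fold
    changes share a sign (both measured against the MF baseline).  In
    ``"paper"`` mode every other DE gene is ``mf_adapted`` (binary
    accounting of the DE set); in ``"extended"`` mode ``mf_adapted``
    additionally requires p(CR-MF vs CR) < ``p_diff`` and the remainder
    is labelled ``intermediate``.  Genes outside the DE set are
    ``not_de``.

    A zero fold change where the direction check applies counts as a
    failed concordance and is logged.
    """
    if thresholds is None:
        thresholds = PlasticityThresholds()
    if mode not in ("paper", "extended"):
        raise ValueError("mode must be 'paper' or 'extended'")
    de_crmf_vs_cr, de_crmf_vs_mf = _aligned(de_cr_vs_mf, de_crmf_vs_cr, de_crmf_vs_mf)

    p1 = de_cr_vs_mf["p"].to_numpy()
    p2 = de_crmf_vs_cr["p"].to_numpy()
    p3 = de_crmf_vs_mf["p"].to_numpy()
    s1 = np.sign(de_cr_vs_mf["logFC"].to_numpy())
    s3 = np.sign(de_crmf_vs_mf["logFC"].to_numpy())

    de = p1 < thresholds.p_de
    concordant = (s1 == s3) & (s1 != 0) & (s3 != 0)
    zero_fc = de & (p2 >= thresholds.p_sim) & (p3 < thresholds.p_diff) & (
        (s1 == 0) | (s3 == 0)
    )
    if zero_fc.any():
        logger.info(
            "%d gene(s) with zero logFC where the direction check applies; "
            "concordance treated as failed",
            int(zero_fc.sum()),
        )
    cr = de & (p2 >= thresholds.p_sim) & (p3 < thresholds.p_diff) & concordant
    label = np.full(len(p1), "not_de", dtype=object)
    label[de] = "mf_adapted"
    if mode == "extended":
        label[de & ~cr & ~(p2 < thresholds.p_diff)] = "intermediate"
    label[cr] = "cr_associated"

    return pd.DataFrame(
        {
            "label": pd.Categorical(label, categories=list(LABELS)),
            "p_cr_vs_mf": p1,
            "p_crmf_vs_cr": p2,
            "p_crmf_vs_mf": p3,
            "lfc_sign_cr_vs_mf": s1,
            "lfc_sign_crmf_vs_mf": s3,
        },
        index=de_cr_vs_mf.index,
    )


def summarize_classification(calls: pd.DataFrame) -> dict:
    """Counts per label plus the CR-associated percentage of the DE set.

    ``pct_cr_associated`` is 100 * n_cr_associated / n_de rounded to one
    decimal, or None when the DE set is empty.
    """
    if len(calls) == 0:
        raise ValueError("calls must be non-empty")
    counts = calls["label"].value_counts()
    n_de = int(len(calls) - counts.get("not_de", 0))
    n_cr = int(counts.get("cr_associated", 0))
    pct = round(100.0 * n_cr / n_de, 1) if n_de else None
    return {
        "n_genes": int(len(calls)),
        "n_de": n_de,
        "n_cr_associated": n_cr,
        "n_mf_adapted": int(counts.get("mf_adapted", 0)),
        "n_intermediate": int(counts.get("intermediate", 0)),
        "n_not_de": int(counts.get("not_de", 0)),
        "pct_cr_associated": pct,
    }


def percent_cr_associated(n_de: int, n_cr_associated: int) -> float:
    """CR-associated share of the DE set, in percent to one decimal."""
    if n_de <= 0:
        raise ValueError("n_de must be positive")
    return round(100.0 * n_cr_associated / n_de, 1)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, members per line."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{ln}: GMT lines need name, description and at "
                    "least one member"
                )
            name, members = fields[0], [m for m in fields[2:] if m]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene-set name {name!r}")
            if not members:
                raise ValueError(f"{path}:{ln}: gene set {name!r} has no members")
            sets[name] = members
    return sets


def pathway_fraction(
    calls: pd.DataFrame, gene_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """CR-associated fraction of each gene set's DE members.

    For each set the denominator is its members that fall in the DE set;
    the fraction is the CR-associated share of those.  Sets with no DE
    members are flagged (``defined`` False, fraction NaN), not dropped.
    """
    if not gene_sets:
        raise ValueError("gene_sets must be non-empty")
    labels = calls["label"]
    de_genes = set(calls.index[labels != "not_de"])
    cr_genes = set(calls.index[labels == "cr_associated"])
    rows = []
    for name, members in gene_sets.items():
        members = set(members)
        n_de = len(members & de_genes)
        n_cr = len(members & cr_genes)
        rows.append(
            {
                "gene_set": name,
                "n_members": len(members),
                "n_de_members": n_de,
                "n_cr_associated": n_cr,
                "fraction_cr_associated": n_cr / n_de if n_de else float("nan"),
                "defined": bool(n_de),
            }
        )
    return pd.DataFrame(rows).set_index("gene_set")
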