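import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from dietswitch.ordination import (
    OrdinationResult,
    activation_zscore,
    correlate_phenotype,
    pca_samples,
    reference_center,
    shift_statistic,
)

from conftest import make_de_table


def matrix_from_groups(group_values, n_genes=None):
    """Build matrix + sheet from {group: list of per-sample gene vectors}."""
    cols, groups, data = [], [], []
    for group, samples in group_values.items():
        for j, vec in enumerate(samples):
            cols.append(f"{group.replace('-', '')}_{j}")
            groups.append(group)
            data.append(np.asarray(vec, dtype=float))
    values = np.array(data).T
    m = pd.DataFrame(
        values,
        index=pd.Index([f"g{i}" for i in range(values.shape[0])], name="gene_id"),
        columns=cols,
    )
    sheet = pd.Series(groups, index=pd.Index(cols, name="sample_id"), name="group")
    return m, sheet


class TestReferenceCenter:
    def test_shifts_by_reference_mean(self):
        m, sheet = matrix_from_groups(
            {"C": [[5.0], [5.0]], "CR": [[7.0]], "MF": [[2.0]]}
        )
        centered = reference_center(m, sheet, "C")
        assert list(centered.columns) == ["CR_0", "MF_0"]
        np.testing.assert_allclose(centered.to_numpy(), [[2.0, -3.0]])

    def test_constant_gene_centers_to_zero(self):
        m, sheet = matrix_from_groups(
            {"C": [[4.0], [4.0]], "CR": [[4.0]], "MF": [[4.0]]}
        )
        centered = reference_center(m, sheet, "C")
        assert (centered.to_numpy() == 0).all()

    def test_reference_mean_idempotent(self):
        # after centering, the reference-group mean is zero by construction
        rng = np.random.default_rng(0)
        m, sheet = matrix_from_groups(
            {"C": list(rng.normal(5, 1, (3, 10))), "CR": list(rng.normal(5, 1, (2, 10)))}
        )
        ref_mean = m[["C_0", "C_1", "C_2"]].mean(axis=1)
        centered_ref = m[["C_0", "C_1", "C_2"]].sub(ref_mean, axis=0)
        assert np.abs(centered_ref.mean(axis=1)).max() < 1e-12

    def test_missing_reference_rejected(self):
        m, sheet = matrix_from_groups({"CR": [[1.0], [2.0]]})
        with pytest.raises(ValueError, match="reference group"):
            reference_center(m, sheet, "C")


class TestPCA:
    def test_rank_one_structure_on_pc1(self):
        # two antipodal clusters along one gene axis -> PC1 explains ~100%
        m, sheet = matrix_from_groups(
            {"CR": [[1.0, 0.0]] * 3, "MF": [[-1.0, 0.0]] * 3}
        )
        res = pca_samples(m, 2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(1)
        vec = rng.normal(size=20)
        m, sheet = matrix_from_groups(
            {"CR": [vec, vec], "MF": [rng.normal(size=20), rng.normal(size=20)]}
        )
        res = pca_samples(m, 3)
        np.testing.assert_allclose(
            res.scores.loc["CR_0"].to_numpy(), res.scores.loc["CR_1"].to_numpy(),
            atol=1e-10,
        )

    def test_variance_conserved_over_full_rank(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(
            rng.normal(size=(50, 20)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(20)],
        )
        res = pca_samples(m, 19)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_excess_components_truncated_with_warning(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.normal(size=(10, 4)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(4)],
        )
        with pytest.warns(UserWarning, match="truncated"):
            res = pca_samples(m, 10)
        assert res.n_components == 3

    def test_gene_reordering_leaves_scores_invariant_up_to_sign(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(
            rng.normal(size=(30, 8)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(8)],
        )
        a = pca_samples(m, 3).scores.to_numpy()
        b = pca_samples(m.sample(frac=1, random_state=0), 3).scores.to_numpy()
        for k in range(3):
            assert np.allclose(a[:, k], b[:, k], atol=1e-8) or np.allclose(
                a[:, k], -b[:, k], atol=1e-8
            )


class TestShift:
    def shift_for(self, kind):
        # Two samples per group; the switch-group centroid is placed
        # exactly at the MF centroid, the CR centroid, or their midpoint.
        cr, mf = np.array([2.0, 0.0, 1.0]), np.array([-2.0, 1.0, 0.0])
        e1, e2 = np.array([0.02, -0.01, 0.0]), np.array([0.0, 0.015, -0.02])
        crmf = {
            "mf": [mf, mf + e2],
            "cr": [cr, cr + e1],
            "mid": [(cr + mf) / 2, (cr + mf) / 2 + (e1 + e2) / 2],
        }[kind]
        m, sheet = matrix_from_groups(
            {"CR": [cr, cr + e1], "MF": [mf, mf + e2], "CR-MF": crmf}
        )
        res = pca_samples(m, 3)
        return shift_statistic(res, sheet, n_components=3)

    def test_anchor_at_mf(self):
        assert self.shift_for("mf") == pytest.approx(1.0, abs=1e-10)

    def test_anchor_at_cr(self):
        assert self.shift_for("cr") == pytest.approx(0.0, abs=1e-10)

    def test_midpoint(self):
        assert self.shift_for("mid") == pytest.approx(0.5, abs=1e-10)

    def test_coincident_anchors_undefined(self):
        scores = pd.DataFrame(
            np.array([[1.0, 0.0], [1.0, 0.0], [0.5, 0.2]]),
            index=["CR_0", "MF_0", "CRMF_0"],
            columns=["PC1", "PC2"],
        )
        sheet = pd.Series(
            ["CR", "MF", "CR-MF"], index=["CR_0", "MF_0", "CRMF_0"], name="group"
        )
        res = OrdinationResult(scores, np.array([0.7, 0.3]), 2)
        assert np.isnan(shift_statistic(res, sheet, n_components=2))

    def test_invariant_under_orthogonal_rotation(self):
        rng = np.random.default_rng(5)
        scores = pd.DataFrame(
            rng.normal(size=(9, 4)),
            index=[f"{g}_{j}" for g in ("CR", "CRMF", "MF") for j in range(3)],
            columns=[f"PC{k + 1}" for k in range(4)],
        )
        sheet = pd.Series(
            ["CR"] * 3 + ["CR-MF"] * 3 + ["MF"] * 3,
            index=scores.index,
            name="group",
        )
        evr = np.array([0.4, 0.3, 0.2, 0.1])
        base = shift_statistic(
            OrdinationResult(scores, evr, 4), sheet, n_components=4
        )
        Q = ortho_group.rvs(4, random_state=6)
        rotated = pd.DataFrame(
            scores.to_numpy() @ Q, index=scores.index, columns=scores.columns
        )
        assert shift_statistic(
            OrdinationResult(rotated, evr, 4), sheet, n_components=4
        ) == pytest.approx(base, abs=1e-10)


class TestActivation:
    def make_network(self, signs):
        return pd.DataFrame(
            {
                "regulator_id": ["R"] * len(signs),
                "target_id": [f"g{i}" for i in range(len(signs))],
                "expected_sign": signs,
            }
        )

    def make_de(self, logfc, p=None):
        n = len(logfc)
        return make_de_table([f"g{i}" for i in range(n)], p or [0.001] * n, logfc)

    def test_all_consistent_targets_activated(self):
        res = activation_zscore(self.make_network([1] * 17), self.make_de([2.0] * 17))
        assert res.loc["R", "z"] == pytest.approx(4.1231, abs=1e-4)
        assert res.loc["R", "state"] == "activated"

    def test_three_one_split_uncertain(self):
        res = activation_zscore(
            self.make_network([1, 1, 1, 1]), self.make_de([1.0, 1.0, 1.0, -1.0])
        )
        assert res.loc["R", "z"] == pytest.approx(1.0)
        assert res.loc["R", "state"] == "uncertain"

    def test_all_inconsistent_inhibited(self):
        res = activation_zscore(self.make_network([1] * 9), self.make_de([-1.0] * 9))
        assert res.loc["R", "z"] == pytest.approx(-3.0)
        assert res.loc["R", "state"] == "inhibited"

    def test_no_significant_targets_undefined(self):
        res = activation_zscore(
            self.make_network([1, 1]), self.make_de([1.0, 1.0], p=[0.5, 0.9])
        )
        assert res.loc["R", "n"] == 0
        assert np.isnan(res.loc["R", "z"])
        assert res.loc["R", "state"] == "uncertain"

    def test_matches_brute_force_tally_on_random_networks(self):
        rng = np.random.default_rng(9)
        n_genes = 400
        genes = [f"g{i}" for i in range(n_genes)]
        de = make_de_table(
            genes, rng.random(n_genes) * 0.02, rng.normal(size=n_genes)
        )
        rows = []
        for r in range(1000):
            targets = rng.choice(n_genes, size=rng.integers(1, 12), replace=False)
            for t in targets:
                rows.append(
                    {
                        "regulator_id": f"R{r:04d}",
                        "target_id": f"g{t}",
                        "expected_sign": int(rng.choice([-1, 1])),
                    }
                )
        network = pd.DataFrame(rows)
        res = activation_zscore(network, de, p_threshold=0.01)
        for r, grp in network.groupby("regulator_id"):
            n_cons = n_inc = 0
            for _, row in grp.iterrows():
                if de.loc[row["target_id"], "p"] < 0.01:
                    obs = np.sign(de.loc[row["target_id"], "logFC"])
                    if obs == row["expected_sign"]:
                        n_cons += 1
                    else:
                        n_inc += 1
            n = n_cons + n_inc
            assert res.loc[r, "n"] == n
            if n:
                assert res.loc[r, "z"] == pytest.approx((n_cons - n_inc) / np.sqrt(n))

    def test_duplicate_pairs_rejected(self):
        net = self.make_network([1, 1])
        net.loc[1, "target_id"] = "g0"
        with pytest.raises(ValueError, match="duplicate"):
            activation_zscore(net, self.make_de([1.0, 1.0]))


class TestPhenotypeCorrelation:
    def matrix_of(self, rows):
        return pd.DataFrame(
            np.atleast_2d(rows),
            index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
            columns=[f"s{i}" for i in range(len(rows[0]))],
        )

    def pheno_of(self, values, cols=None):
        cols = cols or [f"s{i}" for i in range(len(values))]
        return pd.Series(values, index=cols, dtype=float)

    def test_exact_linear_relations(self):
        m = self.matrix_of([[1.0, 2.0, 3.0, 4.0]])
        up = correlate_phenotype(self.pheno_of([5.0, 7.0, 9.0, 11.0]), m)
        down = correlate_phenotype(self.pheno_of([-1.0, -2.0, -3.0, -4.0]), m)
        assert up.loc["g0", "r"] == pytest.approx(1.0)
        assert down.loc["g0", "r"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        m = self.matrix_of([[1.0, 2.0, 3.0, 5.0]])
        res = correlate_phenotype(self.pheno_of([1.0, 2.0, 3.0, 4.0]), m)
        assert res.loc["g0", "r"] == pytest.approx(0.9827, abs=1e-4)
        # closed form: r = 6.5 / sqrt(5 * 8.75)
        assert res.loc["g0", "r"] == pytest.approx(6.5 / np.sqrt(43.75), abs=1e-12)

    def test_missing_phenotype_dropped_pairwise(self):
        m = self.matrix_of([[1.0, 2.0, 3.0, 4.0, 5.0]])
        pheno = self.pheno_of([2.0, 4.0, np.nan, 8.0, 10.0])
        res = correlate_phenotype(pheno, m)
        assert res.loc["g0", "n"] == 4
        assert res.loc["g0", "r"] == pytest.approx(1.0)

    def test_degenerate_inputs_undefined(self):
        m = self.matrix_of([[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0]])
        res = correlate_phenotype(self.pheno_of([1.0, 2.0, 3.0, 4.0]), m)
        assert np.isnan(res.loc["g0", "r"])  # zero-variance gene
        pheno = self.pheno_of([1.0, 2.0, np.nan, np.nan])
        res = correlate_phenotype(pheno, m, ["g1"])
        assert np.isnan(res.loc["g1", "r"])  # < 3 complete pairs

    def test_unknown_gene_rejected(self):
        m = self.matrix_of([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="gx"):
            correlate_phenotype(self.pheno_of([1.0, 2.0, 3.0]), m, ["gx"])
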