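import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tsizesig import diffexp
from tsizesig.diffexp import (
    estimate_s0,
    hierarchical_cluster,
    permutation_fdr,
    pls_adjust,
    sam_analysis,
    sam_statistic,
    select_signature_genes,
)
from tsizesig.synthetic import SyntheticConfig, generate_discovery_cohort
from conftest import make_matrix
import oracles


class TestPLSAdjust:
    def _clinical(self, n, rng=None, node=None):
        rng = rng or np.random.default_rng(0)
        return pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(n)],
            "node": node if node is not None else rng.integers(0, 2, n),
            "grade": rng.integers(1, 4, n),
            "er": rng.choice(["Positive", "Negative"], n),
            "pgr": rng.choice(["Positive", "Negative"], n),
            "subtype": rng.choice(["LumA", "LumB", "Basal"], n),
        })

    def test_single_binary_covariate_equals_group_centering(self, rng):
        """PLS with one binary covariate reduces to within-group mean removal."""
        n = 20
        node = np.array([0] * 10 + [1] * 10)
        m = make_matrix(rng.normal(size=(30, n)))
        clin = self._clinical(n, node=node)
        out, adj = pls_adjust(m, clin, covariates=("node",), n_components=1)
        vals = m.values.to_numpy()
        expected = vals.copy()
        expected[:, node == 0] -= vals[:, node == 0].mean(axis=1, keepdims=True)
        expected[:, node == 1] -= vals[:, node == 1].mean(axis=1, keepdims=True)
        assert np.abs(out.values.to_numpy() - expected).max() < 1e-8

    def test_gene_exactly_linear_in_covariate_zeroed(self, rng):
        n = 16
        node = np.array([0, 1] * 8)
        vals = rng.normal(size=(5, n))
        vals[2] = 3.0 * node - 1.0
        m = make_matrix(vals)
        out, _ = pls_adjust(m, self._clinical(n, node=node),
                            covariates=("node",), n_components=1)
        assert out.values.to_numpy()[2].var() < 1e-10

    def test_noise_covariates_leave_expression_centered(self, rng):
        """Unrelated covariates: residuals ~ column-centered input, R2 small."""
        n, g = 60, 200
        m = make_matrix(rng.normal(size=(g, n)))
        out, _ = pls_adjust(m, self._clinical(n, rng=rng))
        vals = m.values.to_numpy()
        centered = vals - vals.mean(axis=1, keepdims=True)
        resid = out.values.to_numpy()
        r2 = 1.0 - (resid ** 2).sum(axis=1) / (centered ** 2).sum(axis=1)
        assert r2.mean() < 0.25 and np.median(r2) < 0.25

    def test_residuals_orthogonal_to_scores(self, rng):
        n = 24
        m = make_matrix(rng.normal(size=(40, n)))
        out, adj = pls_adjust(m, self._clinical(n, rng=rng), n_components=2)
        cross = adj.x_scores.T @ out.values.to_numpy().T
        assert np.abs(cross).max() < 1e-8

    def test_excess_components_rejected(self, rng):
        n = 12
        m = make_matrix(rng.normal(size=(5, n)))
        with pytest.raises(ValueError, match="rank"):
            pls_adjust(m, self._clinical(n), covariates=("node",), n_components=3)

    def test_constant_covariate_dropped_with_warning(self, rng, caplog):
        n = 12
        clin = self._clinical(n)
        clin["er"] = "Positive"
        m = make_matrix(rng.normal(size=(5, n)))
        out, adj = pls_adjust(m, clin, covariates=("node", "er"))
        assert "er_pos" not in adj.covariate_design.columns


class TestSamStatistic:
    def test_equal_means_give_zero(self, small_labels):
        m = make_matrix(np.tile([1.0, 1.0, 1.0, 1.0, 1.0, 1.0], (3, 1)))
        res = sam_statistic(m, small_labels, s0=0.5)
        assert (res["d_stat"] == 0).all()

    def test_zero_within_group_variance_hand_case(self):
        """Groups {0,0} vs {1,1} with s0=0.5: s=0 so d = 1/0.5 = 2."""
        m = make_matrix([[0.0, 0.0, 1.0, 1.0]])
        res = sam_statistic(m, ["T1", "T1", "T2", "T2"], s0=0.5)
        assert res["d_stat"].iloc[0] == pytest.approx(2.0)
        assert res["pooled_se"].iloc[0] == 0.0

    def test_s0_zero_equals_pooled_t(self, rng, small_labels):
        m = make_matrix(rng.normal(size=(100, 6)))
        res = sam_statistic(m, small_labels, s0=0.0)
        vals = m.values.to_numpy()
        for gi in range(100):
            t = oracles.pooled_t(vals[gi, :3], vals[gi, 3:])
            assert res["d_stat"].iloc[gi] == pytest.approx(t, abs=1e-10)

    def test_single_sample_class_rejected(self, rng):
        m = make_matrix(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match=">= 2"):
            sam_statistic(m, ["T1", "T2", "T2", "T2"], s0=0.1)


class TestEstimateS0:
    def test_constant_ses_return_constant(self):
        assert estimate_s0(np.full(7, 0.4)) == pytest.approx(0.4)

    def test_median_of_small_list(self):
        assert estimate_s0(np.array([1.0, 2.0, 3.0, 4.0, 5.0])) == 3.0

    def test_all_zero_ses_floored(self):
        assert estimate_s0(np.zeros(5)) == pytest.approx(1e-6)

    def test_percentile_search_matches_grid_oracle(self, rng):
        s = rng.gamma(2.0, 0.2, size=400)
        num = rng.normal(0, 0.5, size=400) * (s + 0.1)
        chosen = estimate_s0(s, method="percentile_search", d_num=num)
        # independent exhaustive search over the same percentile grid
        bins = pd.qcut(s, q=20, duplicates="drop")
        best, best_cv = None, np.inf
        for cand in np.percentile(s, np.arange(0, 101, 5)):
            d = num / (s + cand)
            spread = pd.Series(d).groupby(bins, observed=True).apply(
                lambda v: float(np.median(np.abs(v - np.median(v)))))
            cv = spread.std(ddof=1) / spread.mean()
            if cv < best_cv:
                best_cv, best = cv, cand
        assert chosen == pytest.approx(best)


class TestPermutationFDR:
    def test_exhaustive_enumeration_matches_oracle(self, rng):
        """n1=n2=3: all 20 arrangements enumerated; q equals the oracle."""
        vals = rng.normal(size=(12, 6))
        vals[0, 3:] += 4.0
        m = make_matrix(vals)
        labels = ["T1"] * 3 + ["T2"] * 3
        q = permutation_fdr(m, labels, s0=0.1, n_permutations=20, seed=0)
        q_oracle = oracles.exhaustive_sam_q(vals, np.array([True] * 3 + [False] * 3), 0.1)
        np.testing.assert_allclose(q.to_numpy(), q_oracle, atol=1e-12)

    def test_null_matrix_rarely_called(self, rng):
        m = make_matrix(rng.normal(size=(500, 20)))
        labels = ["T1"] * 10 + ["T2"] * 10
        q = permutation_fdr(m, labels, s0=0.2, n_permutations=200, seed=1)
        assert (q < 0.05).mean() <= 0.01

    def test_huge_effect_gene_ranks_first(self, rng):
        vals = rng.normal(size=(1000, 12))
        vals[123, 6:] += 20.0
        m = make_matrix(vals)
        labels = ["T1"] * 6 + ["T2"] * 6
        q = permutation_fdr(m, labels, s0=0.1, n_permutations=300, seed=2)
        assert q.idxmin() == "g123" and q.loc["g123"] < 0.01

    def test_q_monotone_in_abs_d_rank(self, rng, small_labels):
        m = make_matrix(rng.normal(size=(80, 6)))
        tab = sam_analysis(m, small_labels, n_permutations=100, seed=0)
        ordered = tab.sort_values("d_stat", key=np.abs, ascending=False)
        assert (np.diff(ordered["q_value"].to_numpy()) >= -1e-12).all()

    def test_degenerate_labels_rejected(self, rng):
        m = make_matrix(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError):
            permutation_fdr(m, ["T1"] * 6, s0=0.1, n_permutations=100, seed=0)


class TestSelection:
    def test_all_q_one_selects_nothing(self):
        tab = pd.DataFrame({"d_stat": [1.0, -1.0], "q_value": [1.0, 1.0]},
                           index=["a", "b"])
        up1, up2 = select_signature_genes(tab)
        assert up1 == set() and up2 == set()

    def test_threshold_application(self):
        tab = pd.DataFrame({
            "d_stat": [1.0, -2.0, 0.5, 0.1, -0.1],
            "q_value": [0.001, 0.005, 0.02, 0.5, 1.0],
        }, index=list("abcde"))
        up1, up2 = select_signature_genes(tab, fdr_threshold=0.01)
        assert up1 | up2 == {"a", "b"} and len(up1 | up2) == 2

    def test_direction_follows_sign(self):
        tab = pd.DataFrame({"d_stat": [2.0, -2.0], "q_value": [0.001, 0.001]},
                           index=["pos", "neg"])
        up1, up2 = select_signature_genes(tab, fdr_threshold=0.01)
        assert up2 == {"pos"} and up1 == {"neg"}


class TestHierarchicalCluster:
    def test_two_identical_template_groups_separate_perfectly(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        vals = np.column_stack([a] * 4 + [b] * 4)
        m = make_matrix(vals)
        labels = ["T1"] * 4 + ["T2"] * 4
        res = hierarchical_cluster(m, labels)
        ct = res["contingency"].to_numpy()
        assert sorted(ct.ravel().tolist()) == [0, 0, 4, 4]

    def test_constant_sample_named_in_error(self, rng):
        vals = rng.normal(size=(5, 3))
        vals[:, 1] = 2.0
        m = make_matrix(vals)
        with pytest.raises(ValueError, match="s1"):
            hierarchical_cluster(m)

    def test_no_worse_than_nearest_mean_oracle(self):
        """Misassignments bounded by a correlation-to-class-mean classifier."""
        cfg = SyntheticConfig(seed=8, n_genes=400, effect_size=3.0,
                              frac_confounded_genes=0.0)
        mat, clin, truth = generate_discovery_cohort(cfg)
        labels = clin.set_index("sample_id")["stage"].reindex(mat.sample_ids)
        sub = mat.subset_probes(sorted(truth.de_gene_ids))
        res = hierarchical_cluster(sub, labels.to_numpy())
        ct = res["contingency"].to_numpy()
        miss_cluster = min(ct[0, 0] + ct[1, 1], ct[0, 1] + ct[1, 0])

        vals = sub.values.to_numpy()
        t1 = (labels == "T1").to_numpy()
        mean1 = vals[:, t1].mean(axis=1)
        mean2 = vals[:, ~t1].mean(axis=1)
        miss_oracle = 0
        for j in range(vals.shape[1]):
            r1 = np.corrcoef(vals[:, j], mean1)[0, 1]
            r2 = np.corrcoef(vals[:, j], mean2)[0, 1]
            pred = "T1" if r1 >= r2 else "T2"
            miss_oracle += pred != labels.iloc[j]
        assert miss_cluster <= max(miss_oracle, 1)


class TestAdjustmentEfficacy:
    def test_confounded_genes_suppressed_by_adjustment(self):
        """Covariate-linked null genes: called when naive, silenced by PLS."""
        naive_rates, adj_rates = [], []
        for seed in (0, 1, 2, 4, 5):
            cfg = SyntheticConfig(seed=seed, n_genes=800, effect_size=0.0)
            mat, clin, truth = generate_discovery_cohort(cfg)
            labels = clin.set_index("sample_id")["stage"].reindex(mat.sample_ids)
            conf = sorted(truth.confounded_gene_ids)
            tab = sam_analysis(mat, labels, n_permutations=200, seed=1)
            naive_rates.append((tab["q_value"] < 0.05)[conf].mean())
            adj_mat, _ = pls_adjust(mat, clin)
            tab2 = sam_analysis(adj_mat, labels, n_permutations=200, seed=1)
            adj_rates.append((tab2["q_value"] < 0.05)[conf].mean())
        assert np.mean(naive_rates) > 0.5
        assert np.mean(adj_rates) < 0.05

    def test_power_monotone_in_effect_size(self):
        """Detection of true DE genes does not decrease along an effect ladder."""
        recalls = []
        for eff in (0.5, 1.5, 3.0):
            cfg = SyntheticConfig(seed=9, n_genes=500, effect_size=eff,
                                  frac_confounded_genes=0.0)
            mat, clin, truth = generate_discovery_cohort(cfg)
            labels = clin.set_index("sample_id")["stage"].reindex(mat.sample_ids)
            tab = sam_analysis(mat, labels, n_permutations=200, seed=1)
            recalls.append((tab["q_value"] < 0.05)[sorted(truth.de_gene_ids)].mean())
        assert recalls == sorted(recalls)
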