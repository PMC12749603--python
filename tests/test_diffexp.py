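import itertools

import numpy as np
import pytest
from scipy import stats

from necrosig import (
    DEConfig,
    ExpressionMatrix,
    GroupLabels,
    derive_signature,
    estimate_s0,
    permutation_q,
    run_diffexp,
    sam_statistic,
    signed_fold_change,
)
from necrosig import SimConfig, simulate_cohort, truth_report

from conftest import random_matrix


def two_group_labels(matrix, n1):
    ids = matrix.sample_ids
    return GroupLabels(group1=ids[:n1], group2=ids[n1:])


class TestSamStatistic:
    def test_identical_groups_d_zero(self):
        m = ExpressionMatrix(["g"], [f"s{i}" for i in range(6)],
                             np.array([[3.0, 4.0, 5.0, 3.0, 4.0, 5.0]]))
        d = sam_statistic(m, two_group_labels(m, 3), s0=0.5)
        assert d.loc["g", "d"] == pytest.approx(0.0)

    def test_s0_zero_equals_pooled_t(self):
        # independent oracle: classical pooled-variance two-sample t from scipy
        rng = np.random.default_rng(11)
        m = random_matrix(rng, n_genes=5, n_samples=9)
        labels = two_group_labels(m, 4)
        res = sam_statistic(m, labels, s0=0.0)
        t_oracle = stats.ttest_ind(m.values[:, :4], m.values[:, 4:], axis=1,
                                   equal_var=True).statistic
        np.testing.assert_allclose(res["d"].to_numpy(), t_oracle, atol=1e-10)

    def test_doubling_s0_never_increases_abs_d(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, n_genes=20, n_samples=10)
        labels = two_group_labels(m, 5)
        d1 = sam_statistic(m, labels, s0=0.3)["d"].abs()
        d2 = sam_statistic(m, labels, s0=0.6)["d"].abs()
        assert (d2 <= d1 + 1e-12).all()

    def test_small_group_rejected(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, n_genes=2, n_samples=4)
        with pytest.raises(ValueError, match="2 samples"):
            sam_statistic(m, two_group_labels(m, 1), s0=0.1)

    def test_zero_variance_with_zero_s0_instructs(self):
        m = ExpressionMatrix(["g"], [f"s{i}" for i in range(4)],
                             np.array([[1.0, 1.0, 1.0, 1.0]]))
        with pytest.raises(ValueError, match="s0 > 0"):
            sam_statistic(m, two_group_labels(m, 2), s0=0.0)


class TestEstimateS0:
    def test_median_mode(self):
        assert estimate_s0(np.array([1.0, 1.0, 1.0]), mode="median") == 1.0
        assert estimate_s0(np.array([1.0, 2.0, 9.0]), mode="median") == 2.0

    def test_fixed_mode(self):
        assert estimate_s0(np.array([1.0]), mode="fixed", fixed_value=0.5) == 0.5

    def test_percentile_search_degenerate_constant(self):
        s = np.full(50, 0.7)
        num = np.linspace(-1, 1, 50)
        s0 = estimate_s0(s, mode="percentile-search", d_numerators=num)
        assert s0 == pytest.approx(0.7)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_s0(np.array([]), mode="median")


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "m1,m2,expected", [(4.0, 2.0, 4.0), (2.0, 4.0, -4.0), (3.0, 3.0, 1.0)]
    )
    def test_known_values(self, m1, m2, expected):
        vals = np.array([[m1, m1, m2, m2]])
        m = ExpressionMatrix(["g"], ["a", "b", "c", "d"], vals)
        fc = signed_fold_change(m, two_group_labels(m, 2))
        assert fc.loc["g"] == pytest.approx(expected)

    def test_magnitude_always_at_least_one(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, n_genes=30, n_samples=10)
        fc = signed_fold_change(m, two_group_labels(m, 5))
        assert (fc.abs() >= 1.0).all()


def brute_force_q(values, n1, s0, q_max_cap=100.0):
    """Independent permutation-FDR oracle: exhaustive enumeration, plain loops."""
    n = values.shape[1]
    obs_d = _plain_d(values[:, :n1], values[:, n1:], s0)
    abs_obs = np.abs(obs_d)
    qs = []
    all_splits = list(itertools.combinations(range(n), n1))
    for i, di in enumerate(abs_obs):
        obs_count = sum(1 for dj in abs_obs if dj >= di)
        false_counts = []
        for split in all_splits:
            mask = np.zeros(n, dtype=bool)
            mask[list(split)] = True
            dstar = _plain_d(values[:, mask], values[:, ~mask], s0)
            false_counts.append(sum(1 for ds in np.abs(dstar) if ds >= di))
        qs.append(min(100.0 * np.median(false_counts) / obs_count, q_max_cap))
    # monotone non-increasing in |d|
    order = np.argsort(-abs_obs)
    running = -np.inf
    out = np.empty(len(qs))
    for idx in order:
        running = max(running, qs[idx])
        out[idx] = running
    return out


def _plain_d(x1, x2, s0):
    n1, n2 = x1.shape[1], x2.shape[1]
    num = x1.mean(axis=1) - x2.mean(axis=1)
    sp = np.sqrt(((x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1))
                  / (n1 + n2 - 2)) * (1 / n1 + 1 / n2))
    return num / (sp + s0)


class TestPermutationQ:
    def test_exhaustive_matches_brute_force_oracle(self, caplog):
        rng = np.random.default_rng(21)
        vals = rng.normal(7, 1, size=(6, 6))
        vals[0, :3] += 4.0  # one strong gene
        m = ExpressionMatrix([f"g{i}" for i in range(6)],
                             [f"s{j}" for j in range(6)], vals)
        labels = two_group_labels(m, 3)
        cfg = DEConfig(n_permutations=1000, seed=1, s0_mode="fixed", s0_value=0.2)
        with caplog.at_level("WARNING"):
            q = permutation_q(m, labels, cfg, s0=0.2)
        assert "exhaustive" in caplog.text  # 1000 > C(6,3)=20 distinct splits
        oracle = brute_force_q(vals, 3, s0=0.2)
        np.testing.assert_allclose(q.to_numpy(), oracle, atol=1e-10)

    def test_perfect_separation_gene_gets_q_zero(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(7, 1, size=(50, 20))
        vals[0, :10] += 8.0
        m = ExpressionMatrix([f"g{i}" for i in range(50)],
                             [f"s{j}" for j in range(20)], vals)
        q = permutation_q(m, two_group_labels(m, 10),
                          DEConfig(n_permutations=100, seed=4))
        assert q.iloc[0] == 0.0

    def test_identical_values_all_q_100(self):
        m = ExpressionMatrix(["g1", "g2"], [f"s{j}" for j in range(8)],
                             np.full((2, 8), 5.0))
        res = run_diffexp(m, two_group_labels(m, 4),
                          DEConfig(n_permutations=50, seed=3, s0_mode="fixed",
                                   s0_value=0.5))
        assert (res.table["d"] == 0).all()
        assert (res.table["q_percent"] == 100.0).all()

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, n_genes=30, n_samples=16)
        labels = two_group_labels(m, 8)
        cfg = DEConfig(n_permutations=60, seed=42)
        q1 = permutation_q(m, labels, cfg)
        q2 = permutation_q(m, labels, cfg)
        assert (q1 == q2).all()

    def test_q_monotone_in_abs_d(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(7, 1, size=(40, 12))
        vals[:5, :6] += rng.uniform(1, 3, size=(5, 1))
        m = ExpressionMatrix([f"g{i}" for i in range(40)],
                             [f"s{j}" for j in range(12)], vals)
        res = run_diffexp(m, two_group_labels(m, 6),
                          DEConfig(n_permutations=80, seed=7))
        t = res.table.sort_values("d", key=np.abs, ascending=False)
        assert (np.diff(t["q_percent"].to_numpy()) >= -1e-12).all()


class TestDeriveSignature:
    def _planted(self, seed=0):
        rng = np.random.default_rng(seed)
        n_genes, n1, n2 = 105, 12, 12
        vals = rng.normal(7, 0.5, size=(n_genes, n1 + n2))
        vals[:3, :n1] += 2.0  # UP fc=4
        vals[3:5, :n1] -= 2.0  # DOWN fc=-4
        m = ExpressionMatrix([f"g{i}" for i in range(n_genes)],
                             [f"s{j}" for j in range(n1 + n2)], vals)
        return m, two_group_labels(m, n1)

    def test_planted_genes_recovered_exactly(self):
        m, labels = self._planted()
        cfg = DEConfig(n_permutations=200, seed=5, fc_min=2.5, q_max_percent=0.5)
        de = run_diffexp(m, labels, cfg)
        sig = derive_signature(de, name="planted")
        assert sig.up_genes == {"g0", "g1", "g2"}
        assert sig.down_genes == {"g3", "g4"}

    def test_infinite_fc_min_errors(self):
        m, labels = self._planted()
        cfg = DEConfig(n_permutations=50, seed=5, fc_min=np.inf)
        de = run_diffexp(m, labels, cfg)
        with pytest.raises(ValueError, match="no genes pass"):
            derive_signature(de, cfg)

    def test_high_q_excluded_despite_fc(self):
        m, labels = self._planted()
        de = run_diffexp(m, labels, DEConfig(n_permutations=100, seed=5))
        t = de.table
        # manually raise q of a passing gene and re-threshold
        t.loc["g0", "q_percent"] = 50.0
        sig = derive_signature(
            type(de)(table=t, s0=de.s0, config=de.config), name="x")
        assert "g0" not in sig.genes


class TestConfigValidation:
    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            DEConfig(n_permutations=10)

    def test_bad_fc_min(self):
        with pytest.raises(ValueError, match="fc_min"):
            DEConfig(n_permutations=10, seed=1, fc_min=0.5)

    def test_bad_permutations(self):
        with pytest.raises(ValueError, match="n_permutations"):
            DEConfig(n_permutations=0, seed=1)


class TestRecoveryOnSyntheticCohort:
    def test_unbalanced_groups_supported(self):
        cfg = SimConfig(seed=8, n_pos=30, n_neg=60, n_genes=400, n_up=8, n_down=8)
        m, clin, _, truth = simulate_cohort(cfg)
        labels = GroupLabels.from_clinical(clin)
        de = run_diffexp(m, labels, DEConfig(n_permutations=100, seed=1))
        sig = derive_signature(de, name="r")
        rep = truth_report(sig, truth)
        assert rep.sensitivity >= 0.9 and rep.precision >= 0.9
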