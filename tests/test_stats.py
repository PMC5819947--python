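"""Permutation tests, BH-FDR, cluster filtering and gated correlations."""

import itertools

import numpy as np
import pytest

from stn_gammaburst import stats as stm


def bh_bruteforce(p, alpha=0.05):
    """Brute-force BH: largest k with p_(k) <= k*alpha/m; reject those."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_max = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_max]] = True
    return mask


def flood_fill_components(mask):
    """4-connectivity component labelling by explicit BFS."""
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            i, j = stack.pop()
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                        and mask[ni, nj] and not labels[ni, nj]):
                    labels[ni, nj] = current
                    stack.append((ni, nj))
    return labels, current


class TestPermutationTest:
    def test_identical_paired_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = stm.permutation_test(a, a, family="paired", n_perm=200, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_data_p_one(self):
        res = stm.permutation_test(np.full(6, 2.0), np.full(6, 2.0),
                                   family="two_sample", n_perm=200, seed=0)
        assert res.p_value == 1.0

    def test_strong_effect_small_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(3.0, 1.0, 20)
        b = rng.normal(0.0, 1.0, 20)
        res = stm.permutation_test(a, b, family="two_sample",
                                   n_perm=999, seed=1)
        assert res.p_value <= 0.01

    def test_seeded_reproducibility(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        r1 = stm.permutation_test(a, b, family="paired", n_perm=500, seed=42)
        r2 = stm.permutation_test(a, b, family="paired", n_perm=500, seed=42)
        assert r1.p_value == r2.p_value

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """Paired n=4: the sign-flip null has 16 equally likely outcomes;
        the Monte-Carlo p must sit within 2/sqrt(n_perm) of the exact p."""
        d = np.array([0.8, 1.4, -0.3, 0.9])
        obs = d.mean()
        exact_stats = [np.mean(np.array(s) * d)
                       for s in itertools.product([-1, 1], repeat=4)]
        exact_p = np.mean(np.abs(exact_stats) >= abs(obs) - 1e-12)
        res = stm.permutation_test(d, family="one_sample", n_perm=5000, seed=3)
        assert abs(res.p_value - exact_p) <= 2.0 / np.sqrt(5000)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stm.permutation_test(np.array([1.0]), family="one_sample")
        with pytest.raises(ValueError):
            stm.permutation_test(np.arange(4.0), np.arange(3.0), family="paired")
        with pytest.raises(ValueError):
            stm.permutation_test(np.arange(4.0), family="two_sample")
        with pytest.raises(ValueError):
            stm.permutation_test(np.arange(4.0), np.arange(4.0), family="anova")


class TestFDR:
    def test_worked_example_all_significant(self):
        mask, thr = stm.fdr_correct(np.array([0.005, 0.01, 0.03, 0.04]))
        assert mask.all()
        assert thr == pytest.approx(0.04)

    def test_all_ones_none_significant(self):
        mask, thr = stm.fdr_correct(np.ones(10))
        assert not mask.any()
        assert thr == 0.0

    def test_single_p(self):
        mask, thr = stm.fdr_correct(np.array([0.04]))
        assert mask.all() and thr == pytest.approx(0.04)

    def test_empty_input(self):
        mask, thr = stm.fdr_correct(np.array([]))
        assert mask.size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            stm.fdr_correct(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            stm.fdr_correct(np.array([0.5, 1.2]))

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            mask, _ = stm.fdr_correct(p)
            assert np.array_equal(mask, bh_bruteforce(p))


class TestClusterFilter:
    def test_149_removed_150_kept(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[:10, :15] = True            # 150-bin cluster
        kept = stm.cluster_filter(mask, min_size=150)
        assert kept.sum() == 150
        mask2 = np.zeros((50, 50), dtype=bool)
        mask2[:10, :15] = True
        mask2[0, 0] = False              # 149-bin cluster
        assert stm.cluster_filter(mask2, min_size=150).sum() == 0

    def test_empty_mask(self):
        mask = np.zeros((5, 5), dtype=bool)
        assert stm.cluster_filter(mask).sum() == 0

    def test_diagonals_not_connected(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True   # touching only diagonally
        assert stm.cluster_filter(mask, min_size=2).sum() == 0

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(30):
            mask = rng.random((20, 30)) < 0.4
            labels, n = flood_fill_components(mask)
            for min_size in (1, 3, 8):
                got = stm.cluster_filter(mask, min_size=min_size)
                expected = np.zeros_like(mask)
                for lab in range(1, n + 1):
                    comp = labels == lab
                    if comp.sum() >= min_size:
                        expected |= comp
                assert np.array_equal(got, expected)

    def test_idempotent_and_monotone(self, rng):
        mask = rng.random((30, 30)) < 0.35
        once = stm.cluster_filter(mask, min_size=5)
        assert np.array_equal(stm.cluster_filter(once, min_size=5), once)
        bigger = stm.cluster_filter(mask, min_size=10)
        assert np.all(bigger <= once)


class TestVelocityCorrelation:
    def _maps(self, rng, n_pat=6, n_tr=20, n_f=12, n_t=15, coupled_bin=None):
        maps, vels = [], []
        for _ in range(n_pat):
            v = rng.uniform(50, 300, n_tr)
            m = rng.normal(size=(n_tr, n_f, n_t))
            if coupled_bin is not None:
                m[:, coupled_bin[0], coupled_bin[1]] = v
            maps.append(m)
            vels.append(v)
        return maps, vels

    def test_perfect_monotone_association(self, rng):
        # a 2x2 block of perfectly velocity-coupled bins in a small grid:
        # the sign-flip null over 12 patients can reach p small enough for
        # BH to keep the block
        maps, vels = [], []
        for _ in range(12):
            v = rng.uniform(50, 300, 20)
            m = rng.normal(size=(20, 6, 6))
            for (i, j) in ((2, 2), (2, 3), (3, 2), (3, 3)):
                m[:, i, j] = v
            maps.append(m)
            vels.append(v)
        out = stm.tf_velocity_correlation(maps, vels, np.arange(6),
                                          np.arange(6), n_perm=2000, seed=0,
                                          min_cluster_size=1)
        assert np.allclose(out.rho[:, 2, 2], 1.0)
        assert out.mask[2, 2] and out.mask[3, 3]

    def test_independent_power_nothing_significant(self, rng):
        frac = []
        for rep in range(5):
            maps, vels = self._maps(rng)
            out = stm.tf_velocity_correlation(maps, vels, np.arange(12),
                                              np.arange(15), n_perm=300,
                                              seed=rep, min_cluster_size=1)
            frac.append(out.mask_fdr.mean())
        assert np.mean(frac) < 0.02

    def test_spearman_invariant_under_monotone_transform(self, rng):
        maps, vels = self._maps(rng, n_pat=3)
        out1 = stm.tf_velocity_correlation(maps, vels, np.arange(12),
                                           np.arange(15), n_perm=100, seed=0)
        maps2 = [np.exp(m / 3.0) for m in maps]          # strictly monotone
        vels2 = [v ** 3 for v in vels]
        out2 = stm.tf_velocity_correlation(maps2, vels2, np.arange(12),
                                           np.arange(15), n_perm=100, seed=0)
        assert np.allclose(out1.rho, out2.rho)

    def test_constant_velocity_patient_excluded(self, rng):
        maps, vels = self._maps(rng, n_pat=3)
        vels[1] = np.full_like(vels[1], 100.0)
        out = stm.tf_velocity_correlation(maps, vels, np.arange(12),
                                          np.arange(15), n_perm=100, seed=0)
        assert out.rho.shape[0] == 2
        assert out.excluded_patients[0][0] == 1


class TestClinicalCorrelation:
    def test_linear_normal_data_uses_pearson(self, rng):
        x = rng.normal(50, 10, 14)
        res = stm.correlate_clinical(x, 2.0 * x)
        assert res.method == "pearson"
        assert res.statistic == pytest.approx(1.0)

    def test_outlier_triggers_spearman(self, rng):
        x = np.concatenate([rng.normal(0, 1, 13), [40.0]])
        y = rng.normal(size=14)
        res = stm.correlate_clinical(x, y)
        assert res.method == "spearman"

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            stm.correlate_clinical(np.arange(4.0), np.arange(4.0))

    def test_negative_link_sign_recovered_with_table1(self, rng):
        """A negative monotone UPDRS -> burst-rate-change link is recovered
        with the right sign in >=95% of repetitions."""
        from stn_gammaburst.fixtures import load_table1
        updrs = load_table1()["updrs_med_on"].dropna().to_numpy()
        hits = 0
        for rep in range(40):
            change = 60.0 - 1.2 * updrs + rng.normal(0, 8, len(updrs))
            res = stm.correlate_clinical(updrs, change)
            hits += res.statistic < 0
        assert hits >= 38

    def test_super_uniform_null_p_values(self, rng):
        """Permutation p-values under the null are super-uniform: the
        rejection rate at alpha never exceeds alpha by more than MC error."""
        alpha = 0.1
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            res = stm.permutation_test(a, b, family="two_sample",
                                       n_perm=199, seed=rep)
            rejections += res.p_value <= alpha
        limit = alpha + 2.5 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejections / n_rep <= limit
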