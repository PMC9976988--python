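"""Permutation tests, FDR, deviation scores and the AbC statistic."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest

from taskgrad.inference import (
    abc_test,
    cohens_d,
    fdr_bh,
    group_contrast_report,
    perm_correlation,
    perm_one_sample,
    perm_two_sample,
    z_deviation,
)


# ---------------------------------------------------------------------------
# independent oracles


def exhaustive_sign_flip_p(x):
    """Exact two-tailed one-sample p over all 2^n sign patterns."""
    x = np.asarray(x, dtype=float)
    n = x.size

    def t_of(v):
        s = v.std(ddof=1)
        return np.inf if s == 0 else abs(v.mean() / (s / np.sqrt(n)))

    t_obs = t_of(x)
    hits = sum(t_of(np.array(sgn) * x) >= t_obs - 1e-12
               for sgn in product([-1, 1], repeat=n))
    return hits / 2**n


def exhaustive_label_p(a, b, stat):
    """Exact p over all C(n, na) group splits for a symmetric |stat|."""
    pooled = np.concatenate([a, b])
    n, na = pooled.size, len(a)
    obs = abs(stat(np.asarray(a, float), np.asarray(b, float)))
    hits = total = 0
    for ia in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(ia)] = True
        val = abs(stat(pooled[mask], pooled[~mask]))
        hits += val >= obs - 1e-12
        total += 1
    return hits / total


def brute_force_bh(p):
    """BH adjusted p straight from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def _t_two(a, b):
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0:
        return np.inf
    return (a.mean() - b.mean()) / np.sqrt(pooled * (1 / na + 1 / nb))


# ---------------------------------------------------------------------------


class TestZDeviation:
    def test_printed_formula_unit_cases(self):
        assert z_deviation(1.0, 1.0, 2.0) == 0.0
        assert z_deviation(3.0, 1.0, 2.0) == 1.0
        with pytest.raises(ValueError):
            z_deviation(1.0, 0.0, 0.0)

    def test_controls_self_normalize(self, rng):
        """Controls scored against their own mu/sigma: mean 0, SD 1."""
        x = rng.normal(2.0, 3.0, size=400)
        z = z_deviation(x, x.mean(), x.std(ddof=1))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestCohensD:
    def test_hand_computation(self):
        assert cohens_d([0.0, 2.0], [-1.0, 1.0]) == pytest.approx(1 / np.sqrt(2))

    def test_antisymmetry_and_zero(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=25)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))
        assert cohens_d(a, a) == 0.0


class TestPermOneSample:
    def test_symmetric_two_values_give_p_one(self):
        r = perm_one_sample([-1.0, 1.0], n_perm=500, seed=3)
        assert r.p_perm == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        """Monte-Carlo p within 3 MC SEs of the exact sign-flip p."""
        for seed in range(4):
            x = np.random.default_rng(seed).normal(0.4, 1.0, size=9)
            exact = exhaustive_sign_flip_p(x)
            r = perm_one_sample(x, n_perm=4000, seed=seed)
            se = np.sqrt(exact * (1 - exact) / 4000)
            assert abs(r.p_perm - exact) <= 3 * se + 1 / 4001

    def test_same_seed_bit_identical(self, rng):
        x = rng.normal(size=15)
        r1 = perm_one_sample(x, 999, seed=42)
        r2 = perm_one_sample(x, 999, seed=42)
        assert r1.p_perm == r2.p_perm and r1.statistic == r2.statistic

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            perm_one_sample([2.0, 2.0, 2.0], 100, 0)


class TestPermTwoSample:
    def test_matches_exhaustive_enumeration(self):
        a = np.array([0.2, 1.1, -0.4])
        b = np.array([1.9, 2.3, 0.8])
        exact = exhaustive_label_p(a, b, _t_two)
        r = perm_two_sample(a, b, n_perm=4000, seed=11)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(r.p_perm - exact) <= 3 * se + 1 / 4001

    def test_saturates_at_floor_for_huge_shift(self, rng):
        a = rng.normal(0.0, 0.1, size=20)
        b = rng.normal(50.0, 0.1, size=20)
        r = perm_two_sample(a, b, n_perm=999, seed=0)
        assert r.p_perm == pytest.approx(1 / 1000)

    def test_effect_size_attached(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=12)
        r = perm_two_sample(a, b, 99, 0)
        assert r.effect_size_d == pytest.approx(cohens_d(a, b))

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            perm_two_sample([1.0, 1.0], [1.0, 1.0], 10, 0)


class TestFdrBH:
    def test_textbook_vector(self):
        adj, rej = fdr_bh([0.01, 0.02, 0.03, 0.5], 0.05)
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.5])
        assert list(rej) == [True, True, True, False]

    def test_matches_brute_force_definition(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 30))
            adj, _ = fdr_bh(p)
            np.testing.assert_allclose(adj, brute_force_bh(p), atol=1e-12)

    def test_equal_ps_unchanged_and_dominance(self, rng):
        adj, _ = fdr_bh([0.2, 0.2, 0.2])
        np.testing.assert_allclose(adj, 0.2)
        p = rng.uniform(1e-6, 1.0, size=25)
        adj, _ = fdr_bh(p)
        assert np.all(adj >= p - 1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


class TestAbc:
    def test_identical_groups_give_zero_area_p_one(self, rng):
        A = rng.normal(size=(5, 8))
        cc = abc_test(A, A.copy(), n_perm=200, seed=0, per_bin=False)
        assert cc.abc == 0.0 and cc.p_perm == 1.0

    def test_constant_offset_exact_area(self, rng):
        A = rng.normal(size=(6, 10))
        B = A + 0.37
        cc = abc_test(A, B, n_perm=99, seed=1, per_bin=False)
        assert cc.abc == pytest.approx(0.37)

    def test_symmetry_and_linear_scaling(self, rng):
        A, B = rng.normal(size=(6, 10)), rng.normal(size=(6, 10))
        c1 = abc_test(A, B, 500, seed=7, per_bin=False)
        c2 = abc_test(B, A, 500, seed=7, per_bin=False)
        assert c1.abc == pytest.approx(c2.abc)
        se = np.sqrt(0.25 / 500)
        assert abs(c1.p_perm - c2.p_perm) <= 3 * se
        c3 = abc_test(3.0 * A, 3.0 * B, 10, seed=7, per_bin=False)
        assert c3.abc == pytest.approx(3.0 * c1.abc)

    def test_matches_exhaustive_enumeration(self, rng):
        A, B = rng.normal(size=(3, 6)), rng.normal(0.8, 1.0, size=(3, 6))

        def abc_stat(xa, xb):
            return np.mean(np.abs(xa.mean(axis=0) - xb.mean(axis=0)))

        pooled = np.vstack([A, B])
        obs = abc_stat(A, B)
        hits = total = 0
        for ia in combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(ia)] = True
            hits += abc_stat(pooled[mask], pooled[~mask]) >= obs - 1e-12
            total += 1
        exact = hits / total
        cc = abc_test(A, B, n_perm=4000, seed=2, per_bin=False)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(cc.p_perm - exact) <= 3 * se + 1 / 4001

    def test_per_bin_results_carry_fdr(self, rng):
        A, B = rng.normal(size=(8, 5)), rng.normal(size=(8, 5))
        cc = abc_test(A, B, 199, seed=3)
        assert len(cc.per_bin) == 5
        assert all(r.p_fdr >= r.p_perm - 1e-15 for r in cc.per_bin)

    def test_bin_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="bin"):
            abc_test(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)), 10, 0)


class TestPermCorrelation:
    def test_perfect_correlation_floors_p(self, rng):
        x = rng.normal(size=30)
        r = perm_correlation(x, x, n_perm=999, seed=0)
        assert r.statistic == pytest.approx(1.0)
        assert r.p_perm == pytest.approx(1 / 1000)

    def test_spearman_monotone_invariance(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        r1 = perm_correlation(x, y, method="spearman", n_perm=500, seed=9)
        r2 = perm_correlation(np.exp(x), y**3, method="spearman",
                              n_perm=500, seed=9)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_perm == r2.p_perm

    def test_nuisance_recovers_construction(self, rng):
        """x driven by a nuisance covariate; residual link is recovered."""
        n = 300
        cov = rng.normal(size=n)
        noise = rng.normal(size=n)
        x = 2.0 * cov + noise
        y = noise + 0.1 * rng.normal(size=n)
        r = perm_correlation(x, y, nuisance=cov, n_perm=999, seed=4)
        target = np.corrcoef(noise, y)[0, 1]
        assert r.statistic == pytest.approx(target, abs=0.05)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            perm_correlation(np.ones(10), rng.normal(size=10), n_perm=10, seed=0)


class TestGroupContrastReport:
    def _profiles(self, rng, m=4):
        return {
            "CTR": pd.DataFrame(rng.normal(size=(10, m))),
            "FLE": pd.DataFrame(rng.normal(size=(8, m))),
            "TLE": pd.DataFrame(rng.normal(size=(9, m))),
        }

    def test_row_counts_exact(self, rng):
        rep = group_contrast_report(self._profiles(rng), n_perm=49, seed=0)
        # 4 families: control, two deviations, patient-vs-patient
        assert len(rep) == 4 * 4
        assert set(rep["comparison"]) == {
            "CTR_vs_zero", "FLE_deviation", "TLE_deviation", "FLE_vs_TLE"}

    def test_p_values_on_grid(self, rng):
        rep = group_contrast_report(self._profiles(rng), n_perm=49, seed=1)
        k = rep["p_perm"].to_numpy() * 50
        np.testing.assert_allclose(k, np.round(k), atol=1e-9)
        assert (rep["p_perm"] >= 1 / 50 - 1e-12).all()

    def test_tiny_group_rejected(self, rng):
        profiles = self._profiles(rng)
        profiles["FLE"] = profiles["FLE"].iloc[:1]
        with pytest.raises(ValueError, match="fewer than 2"):
            group_contrast_report(profiles, n_perm=9, seed=0)
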