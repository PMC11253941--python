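"""Differentiation, rank tests, Mantel, relatedness, PCA oracles."""

from itertools import combinations, permutations

import numpy as np
import pytest
from scipy import stats

from clinescan.datatypes import MISSING
from clinescan.popstructure import (
    RelatednessPruner,
    allele_frequencies,
    corr_r2,
    mann_whitney,
    mantel_test,
    pairwise_wc_fst,
    pca,
)

from conftest import make_table


class TestAlleleFrequencies:
    def test_simple_counts(self):
        t = make_table([[0], [1], [2]])
        res = allele_frequencies(t)
        assert res["freq"].iloc[0] == pytest.approx(0.5)

    def test_call_fraction_threshold(self):
        """7 of 10 called < 80% rule -> excluded."""
        calls = np.ones((10, 1), dtype=np.int16)
        calls[:3, 0] = MISSING
        res = allele_frequencies(make_table(calls), min_call_fraction=0.8)
        assert bool(res["excluded"].iloc[0])

    def test_matches_brute_force_counting(self, rng):
        calls = rng.integers(0, 3, (20, 30)).astype(np.int16)
        calls[rng.random(calls.shape) < 0.2] = MISSING
        res = allele_frequencies(make_table(calls))
        for j in range(30):
            col = calls[:, j]
            obs = col[col != MISSING]
            expect = obs.sum() / (2 * len(obs)) if len(obs) else 0.0
            assert res["freq"].iloc[j] == pytest.approx(expect)

    def test_all_missing_never_nan(self):
        calls = np.full((5, 1), MISSING, dtype=np.int16)
        res = allele_frequencies(make_table(calls))
        assert np.isfinite(res["freq"]).all()
        assert bool(res["excluded"].iloc[0])


class TestWeirCockerhamFst:
    def test_no_differentiation_near_zero(self):
        # both pops at p=0.5 with exact HWE genotype counts 1:2:1
        col = [0, 1, 1, 2] * 5
        a = make_table(np.array(col).reshape(-1, 1))
        b = make_table(np.array(col).reshape(-1, 1))
        assert abs(pairwise_wc_fst(a, b).theta) < 0.05

    def test_fixed_difference_is_one(self):
        a = make_table(np.full((10, 1), 2, dtype=np.int16))
        b = make_table(np.zeros((10, 1), dtype=np.int16))
        assert pairwise_wc_fst(a, b).theta == pytest.approx(1.0)

    def test_hand_evaluated_oracle(self):
        """Frozen symbolic evaluation of the a/b/c components for
        genotypes {2,2,1,1,0} vs {0,0,1,1,2}:
        n=5 each, p=(0.6, 0.4), h=(0.4, 0.4) => a=-0.015, b=0.075, c=0.2,
        theta = -0.015/0.26."""
        a = make_table(np.array([[2], [2], [1], [1], [0]], dtype=np.int16))
        b = make_table(np.array([[0], [0], [1], [1], [2]], dtype=np.int16))
        res = pairwise_wc_fst(a, b)
        assert res.per_site["a"].iloc[0] == pytest.approx(-0.015, abs=1e-12)
        assert res.per_site["b"].iloc[0] == pytest.approx(0.075, abs=1e-12)
        assert res.per_site["c"].iloc[0] == pytest.approx(0.2, abs=1e-12)
        assert res.theta == pytest.approx(-0.015 / 0.26, abs=1e-12)

    def test_monomorphic_only_raises(self):
        a = make_table(np.zeros((5, 1), dtype=np.int16))
        b = make_table(np.zeros((5, 1), dtype=np.int16))
        with pytest.raises(ValueError):
            pairwise_wc_fst(a, b)


class TestMannWhitney:
    def test_symmetric_groups_z_zero(self):
        res = mann_whitney([1, 2], [1, 2])
        assert res.u == pytest.approx(2.0)
        assert res.z == pytest.approx(0.0)

    def test_exact_enumeration_oracle(self):
        """For small n the normal-approximation p brackets the exact
        permutation p computed by enumerating all group assignments."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        pooled = a + b
        n1 = len(a)
        obs_u = mann_whitney(a, b).u

        def u_of(idx):
            grp = [pooled[i] for i in idx]
            rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
            r = stats.rankdata(grp + rest)[: len(grp)].sum()
            return r - n1 * (n1 + 1) / 2

        us = [u_of(idx) for idx in combinations(range(6), 3)]
        exact_one_sided = sum(u <= obs_u for u in us) / len(us)
        assert exact_one_sided == pytest.approx(1 / 20)
        # exact two-sided p = 0.1; normal approximation error at n=3
        # is itself ~0.05, so the band is the approximation's, not ours
        res = mann_whitney(a, b)
        assert res.p == pytest.approx(0.1, abs=0.06)

    def test_z_close_to_exact_for_small_groups(self, rng):
        """Normal-approximation and exact enumeration agree for n<=6."""
        for _ in range(5):
            a = rng.normal(size=5).round(1)
            b = rng.normal(size=6).round(1)
            res = mann_whitney(a, b)
            pooled = np.concatenate([a, b])
            us = []
            for idx in combinations(range(11), 5):
                r = stats.rankdata(pooled)[list(idx)].sum()
                us.append(r - 5 * 6 / 2)
            us = np.array(us)
            exact_two = min(1.0, 2 * min((us <= res.u).mean(),
                                         (us >= res.u).mean()))
            assert res.p == pytest.approx(exact_two, abs=0.08)

    def test_degenerate_identical_values(self):
        res = mann_whitney([1, 1], [1, 1, 1])
        assert res.degenerate and res.z is None


class TestMantel:
    @staticmethod
    def _dist(rng, n):
        x = rng.normal(size=(n, 2))
        d = np.linalg.norm(x[:, None] - x[None], axis=-1)
        return d

    def test_perfect_correlation(self, rng):
        d1 = self._dist(rng, 6)
        res = mantel_test(d1, 2 * d1, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_exhaustive_permutation_oracle(self, rng):
        """4x4 matrices: empirical p consistent with brute force over
        all 24 simultaneous row/column permutations."""
        d1, d2 = self._dist(rng, 4), self._dist(rng, 4)
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(d1[iu], d2[iu])[0, 1]
        rs = []
        for perm in permutations(range(4)):
            p = list(perm)
            rs.append(np.corrcoef(d1[iu], d2[np.ix_(p, p)][iu])[0, 1])
        exact = np.mean(np.abs(rs) >= abs(r_obs) - 1e-12)
        res = mantel_test(d1, d2, n_perm=4999, seed=1)
        assert res.r == pytest.approx(r_obs)
        assert res.p == pytest.approx(exact, abs=0.05)

    def test_independent_null_p_uniform(self, rng):
        """Null calibration: p over replicates is roughly uniform."""
        ps = []
        for _ in range(60):
            res = mantel_test(self._dist(rng, 7), self._dist(rng, 7),
                              n_perm=199, seed=int(rng.integers(2 ** 31)))
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_matrix_flagged(self):
        d = np.ones((4, 4)) - np.eye(4)
        rng = np.random.default_rng(0)
        res = mantel_test(d, self._dist(rng, 4), n_perm=9, seed=0)
        assert res.degenerate


class TestRelatedness:
    def test_duplicate_sample_removed(self, rng):
        p = rng.uniform(0.1, 0.9, 800)
        calls = rng.binomial(2, p, size=(100, 800)).astype(np.int16)
        calls[99] = calls[0]  # duplicate genotype column
        t = make_table(calls)
        pruner = RelatednessPruner(threshold=0.25).fit(t)
        assert pruner.relatedness_.iloc[0, 99] > 0.9
        assert len(pruner.removed_ids_) >= 1
        assert not ({"s0", "s99"} <= set(pruner.kept_ids_))

    def test_parent_offspring_about_half(self, rng):
        """Mendelian child of two simulated parents: r ~ 0.5.  The panel
        must be large enough (100 founders) that the allele-frequency
        estimate does not attenuate the cross-product."""
        m, nf = 5000, 100
        p = rng.uniform(0.1, 0.9, m)
        founders = rng.binomial(2, p, size=(nf, m)).astype(np.int16)

        def gamete(g):
            return np.where(g == 1, rng.integers(0, 2, m), g // 2)

        child = (gamete(founders[0]) + gamete(founders[1])).astype(np.int16)
        calls = np.vstack([founders, child[None]])
        pruner = RelatednessPruner(threshold=0.99, min_maf=0.05).fit(
            make_table(calls))
        r_po = pruner.relatedness_.iloc[0, nf]
        assert r_po == pytest.approx(0.5, abs=0.05)
        r_unrel = pruner.relatedness_.iloc[2, nf]
        assert abs(r_unrel) < 0.05

    def test_unrelated_simulation_no_removals(self, rng):
        m = 2000
        p = rng.uniform(0.1, 0.9, m)
        calls = rng.binomial(2, p, size=(30, m)).astype(np.int16)
        pruner = RelatednessPruner(threshold=0.25).fit(make_table(calls))
        assert pruner.removed_ids_ == []

    def test_idempotent(self, rng):
        calls = rng.integers(0, 3, (8, 500)).astype(np.int16)
        calls[7] = calls[1]
        t = make_table(calls)
        once = RelatednessPruner(0.25).fit_transform(t)
        twice = RelatednessPruner(0.25).fit_transform(once)
        assert twice.sample_ids == once.sample_ids

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            RelatednessPruner(threshold=0.0).fit(make_table([[0], [1]]))


class TestPca:
    def test_single_varying_variable(self, rng):
        x = np.column_stack([rng.normal(size=20), np.ones(20)])
        _, ratios = pca(x, standardize=False)
        assert ratios[0] == pytest.approx(1.0)

    def test_analytic_two_variable_case(self, rng):
        """Covariance [[2,1],[1,2]] has eigenvalues 3 and 1 -> PC1 75%."""
        cov = np.array([[2.0, 1.0], [1.0, 2.0]])
        x = rng.multivariate_normal([0, 0], cov, size=200_000)
        _, ratios = pca(x, standardize=False)
        assert ratios[0] == pytest.approx(0.75, abs=0.01)

    def test_ratios_sorted_and_sum_to_one(self, rng):
        x = rng.normal(size=(50, 8))
        _, ratios = pca(x, standardize=True)
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() == pytest.approx(1.0, abs=1e-9)


class TestCorrR2:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2, _ = corr_r2(x, 3 * x + 1)
        assert (slope, intercept, r2) == (pytest.approx(3.0),
                                          pytest.approx(1.0),
                                          pytest.approx(1.0))

    def test_closed_form_oracle(self):
        """n=5 hand vectors: R^2 from the sum-formula evaluation."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        r2_expect = sxy ** 2 / (((x - x.mean()) ** 2).sum()
                                * ((y - y.mean()) ** 2).sum())
        assert corr_r2(x, y)[2] == pytest.approx(r2_expect, abs=1e-12)

    def test_zero_variance_x(self):
        with pytest.raises(ValueError):
            corr_r2([1, 1, 1], [1, 2, 3])
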