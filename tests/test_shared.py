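"""Overlap permutation tests, shift directions, parallelism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clinescan.datatypes import MISSING
from clinescan.shared import (
    expected_parallel_fraction,
    gene_parallel_calls,
    overlap_permutation_test,
    parallel_chisq,
    parallel_permutation,
    shift_directions,
)

from conftest import make_table


class TestOverlapPermutation:
    def test_self_overlap_extreme(self, rng):
        genes = [f"g{i}" for i in range(1000)]
        s = set(rng.choice(genes, 50, replace=False))
        res = overlap_permutation_test(s, s, genes, genes,
                                       n_replicates=999, seed=1)
        assert res.observed == 50
        assert res.z > 5
        assert res.p == pytest.approx(1 / 1000)

    def test_disjoint_universes(self):
        ua = [f"a{i}" for i in range(100)]
        ub = [f"b{i}" for i in range(100)]
        res = overlap_permutation_test(set(ua[:10]), set(ub[:10]), ua, ub,
                                       n_replicates=200, seed=0)
        assert res.observed == 0
        assert res.null_mean == 0.0
        assert res.z is None

    def test_null_mean_matches_collapse_expectation(self, rng):
        """Null mean == |U| (1-(1-1/|U|)^a)(1-(1-1/|U|)^b): the exact
        expectation for with-replacement draws with duplicates collapsed."""
        u = [f"g{i}" for i in range(400)]
        a = set(rng.choice(u, 30, replace=False))
        b = set(rng.choice(u, 40, replace=False))
        res = overlap_permutation_test(a, b, u, u,
                                       n_replicates=4000, seed=2)
        nu = 400
        expect = nu * (1 - (1 - 1 / nu) ** 30) * (1 - (1 - 1 / nu) ** 40)
        mc_se = res.null_sd / np.sqrt(res.n_replicates)
        assert res.observed >= 0
        assert abs(res.null_mean - expect) < 3 * mc_se + 1e-9

    def test_z_and_p_directionally_consistent(self, rng):
        u = [f"g{i}" for i in range(200)]
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            a = set(r2.choice(u, 20, replace=False))
            b = set(r2.choice(u, 20, replace=False))
            res = overlap_permutation_test(a, b, u, u, n_replicates=500,
                                           seed=seed)
            if res.z is not None and res.z > 0:
                assert res.p <= 0.6
            if res.z is not None and res.z < -0.5:
                assert res.p > 0.4

    def test_three_way_supported_and_deterministic(self, rng):
        u = [f"g{i}" for i in range(300)]
        a = set(u[:40]); b = set(u[20:60]); c = set(u[30:70])
        r1 = overlap_permutation_test(a, b, u, u, set_c=c, universe_c=u,
                                      n_replicates=300, seed=9)
        r2 = overlap_permutation_test(a, b, u, u, set_c=c, universe_c=u,
                                      n_replicates=300, seed=9)
        assert r1.observed == len(a & b & c)
        assert (r1.z, r1.p) == (r2.z, r2.p)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_permutation_test({"x"}, {"a"}, ["a"], ["a"], 10, 0)


class TestShiftDirections:
    def test_basic_directions(self):
        low = make_table(np.array([[0], [1], [0]], dtype=np.int16))   # 0.2
        high = make_table(np.array([[2], [1], [1]], dtype=np.int16))  # 0.67
        out = shift_directions(low, high, ["chr1:100"])
        assert out["direction"].iloc[0] == "up"

    def test_call_fraction_rule(self):
        """5 of 10 called at one end -> direction none (60% rule)."""
        low_calls = np.ones((10, 1), dtype=np.int16)
        low_calls[:5, 0] = MISSING
        low = make_table(low_calls)
        high = make_table(np.full((10, 1), 2, dtype=np.int16))
        out = shift_directions(low, high, ["chr1:100"], 0.6)
        assert out["direction"].iloc[0] == "none"

    def test_swapped_polarization_flipped(self):
        low = make_table(np.array([[0], [0]], dtype=np.int16))
        high_sites = pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                                   "ref": ["G"], "alt": ["A"]})
        from clinescan.datatypes import GenotypeTable
        high = GenotypeTable(["t0", "t1"], high_sites,
                             np.array([[0], [0]], dtype=np.int16))
        # low alt freq 0; high has ref/alt swapped so dosage 0 = alt freq 1
        out = shift_directions(low, high, ["chr1:100"])
        assert out["direction"].iloc[0] == "up"
        assert out["freq_high"].iloc[0] == pytest.approx(1.0)

    def test_matches_brute_force_counting(self, rng):
        calls_low = rng.integers(0, 3, (12, 20)).astype(np.int16)
        calls_high = rng.integers(0, 3, (12, 20)).astype(np.int16)
        low, high = make_table(calls_low), make_table(calls_high)
        out = shift_directions(low, high, list(low.site_ids), 0.0)
        for j, site in enumerate(low.site_ids):
            fl = calls_low[:, j].sum() / 24
            fh = calls_high[:, j].sum() / 24
            expect = "none" if fl == fh else ("up" if fh > fl else "down")
            assert out.set_index("site").loc[site, "direction"] == expect


class TestGeneParallelCalls:
    @staticmethod
    def _dirs(**by_transect):
        out = {}
        for t, pairs in by_transect.items():
            out[t] = pd.DataFrame({"site": [p[0] for p in pairs],
                                   "direction": [p[1] for p in pairs]})
        return out

    assign = pd.DataFrame({"site": ["s1", "s2"], "gene_id": ["gA", "gA"]})

    def test_single_snp_concordant(self):
        d = self._dirs(T1=[("s1", "up")], T2=[("s1", "up")],
                       T3=[("s1", "up")])
        out = gene_parallel_calls(
            d, pd.DataFrame({"site": ["s1"], "gene_id": ["gA"]}))
        assert bool(out.loc[out["gene_id"] == "gA", "concordant"].iloc[0])

    def test_conjunction_rule(self):
        d = self._dirs(T1=[("s1", "up"), ("s2", "up")],
                       T2=[("s1", "up"), ("s2", "down")])
        out = gene_parallel_calls(d, self.assign, rule="all")
        assert not bool(out["concordant"].iloc[0])
        out_any = gene_parallel_calls(d, self.assign, rule="any")
        assert bool(out_any["concordant"].iloc[0])

    def test_none_direction_excludes_snp(self):
        d = self._dirs(T1=[("s1", "up"), ("s2", "none")],
                       T2=[("s1", "up"), ("s2", "down")])
        out = gene_parallel_calls(d, self.assign)
        assert out["n_snps"].iloc[0] == 1
        assert bool(out["concordant"].iloc[0])

    def test_neutral_single_snp_genes_quarter(self, rng):
        """Three transects of independent random directions: concordant
        fraction ~ 25% (the analytic null)."""
        n = 4000
        sites = [f"s{i}" for i in range(n)]
        d = {t: pd.DataFrame({
            "site": sites,
            "direction": rng.choice(["up", "down"], n)})
            for t in ("T1", "T2", "T3")}
        assign = pd.DataFrame({"site": sites,
                               "gene_id": [f"g{i}" for i in range(n)]})
        out = gene_parallel_calls(d, assign)
        frac = out["concordant"].mean()
        se = np.sqrt(0.25 * 0.75 / n)
        assert frac == pytest.approx(0.25, abs=3 * se)

    def test_two_transects_half(self, rng):
        n = 4000
        sites = [f"s{i}" for i in range(n)]
        d = {t: pd.DataFrame({"site": sites,
                              "direction": rng.choice(["up", "down"], n)})
             for t in ("T1", "T2")}
        assign = pd.DataFrame({"site": sites,
                               "gene_id": [f"g{i}" for i in range(n)]})
        frac = gene_parallel_calls(d, assign)["concordant"].mean()
        assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))


class TestParallelChisq:
    def test_exact_quarter_is_zero(self):
        chi2, p, _ = parallel_chisq(25, 100, 0.25)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n_par,n_tot", [(5, 5), (101, 173), (116, 150)])
    def test_hand_formula_oracle(self, n_par, n_tot):
        """chi2 equals the two-cell sum (O-E)^2/E evaluated by hand."""
        e1, e2 = n_tot * 0.25, n_tot * 0.75
        expect = (n_par - e1) ** 2 / e1 + (n_tot - n_par - e2) ** 2 / e2
        chi2, p, _ = parallel_chisq(n_par, n_tot)
        assert chi2 == pytest.approx(expect, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(expect, 1), abs=1e-12)

    def test_small_expected_cell_warns(self):
        _, _, warn = parallel_chisq(3, 3)
        assert warn

    def test_analytic_expectation(self):
        assert expected_parallel_fraction(3) == 0.25
        assert expected_parallel_fraction(2) == 0.5


class TestParallelPermutation:
    def test_extreme_observed_smallest_p(self, rng):
        flags = np.zeros(500, bool)
        res = parallel_permutation(flags, 20, observed=20, n_iter=999, seed=3)
        assert res.p == pytest.approx(1 / 1000)

    def test_null_mean_binomial(self, rng):
        flags = rng.random(2000) < 0.13
        res = parallel_permutation(flags, 100, observed=0,
                                   n_iter=2000, seed=4)
        expect = 100 * flags.mean()
        mc_se = res.null_sd / np.sqrt(2000)
        assert abs(res.null_mean - expect) < 3 * mc_se + 1e-9

    def test_null_distribution_binomial_ks(self, rng):
        """Null counts match Binomial(n_select, frac) within KS 0.05."""
        flags = rng.random(3000) < 0.25
        res = parallel_permutation(flags, 50, observed=0, n_iter=1000, seed=5)
        rng2 = np.random.default_rng(6)
        draws = rng2.integers(0, flags.size, size=(1000, 50))
        ref = flags[draws].sum(axis=1)
        # compare empirical CDFs of the permutation null and binomial ref
        grid = np.arange(0, 51)
        f1 = np.searchsorted(np.sort(ref), grid, "right") / 1000
        binom_cdf = stats.binom.cdf(grid, 50, flags.mean())
        assert np.max(np.abs(f1 - binom_cdf)) < 0.05

    def test_same_seed_identical(self, rng):
        flags = rng.random(300) < 0.2
        a = parallel_permutation(flags, 30, observed=10, n_iter=200, seed=8)
        b = parallel_permutation(flags, 30, observed=10, n_iter=200, seed=8)
        assert (a.z, a.p, a.cutoff_95) == (b.z, b.p, b.cutoff_95)
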