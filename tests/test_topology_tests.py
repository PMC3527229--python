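"""RELL bootstrap and KH/SH/WSH/AU topology tests."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from cladesig.errors import SitelhParseError
from cladesig.synthetic_data import simulate_sitelh
from cladesig.topology_tests import (
    DEFAULT_AU_SCALES,
    SitewiseLnL,
    au_fit,
    au_test,
    kh_test,
    read_sitelh,
    rell_bootstrap,
    sh_test,
    topology_report,
    write_sitelh,
    wsh_test,
)


class TestSitelhIO:
    def test_read_matrix(self, tmp_path):
        p = tmp_path / "x.sitelh"
        p.write_text("2 3\ntr1 -1 -2 -3\ntr2 -1 -2 -4\n")
        S = read_sitelh(p)
        assert S.tree_ids == ["tr1", "tr2"]
        assert S.L.shape == (2, 3) and S.L[1, 2] == -4

    def test_row_count_mismatch(self, tmp_path):
        p = tmp_path / "bad.sitelh"
        p.write_text("2 3\ntr1 -1 -2 -3\n")
        with pytest.raises(SitelhParseError):
            read_sitelh(p)

    def test_non_numeric(self, tmp_path):
        p = tmp_path / "bad2.sitelh"
        p.write_text("1 3\ntr1 -1 x -3\n")
        with pytest.raises(SitelhParseError):
            read_sitelh(p)

    def test_round_trip(self, tmp_path, rng):
        S = simulate_sitelh(3, 25, seed=4)
        p = tmp_path / "rt.sitelh"
        write_sitelh(S, p)
        back = read_sitelh(p)
        assert back.tree_ids == S.tree_ids
        np.testing.assert_allclose(back.L, S.L, rtol=1e-9)


class TestRellBootstrap:
    def test_constant_rows_give_observed_total(self):
        S = SitewiseLnL(["a", "b"], np.array([[-2.0] * 10, [-3.0] * 10]))
        R = rell_bootstrap(S, 50, seed=1)
        np.testing.assert_allclose(R[0], -20.0)
        np.testing.assert_allclose(R[1], -30.0)

    def test_seed_determinism(self):
        S = simulate_sitelh(2, 40, seed=2)
        a = rell_bootstrap(S, 20, seed=9)
        b = rell_bootstrap(S, 20, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_replicate_mean_near_observed(self):
        S = simulate_sitelh(2, 200, seed=5)
        R = rell_bootstrap(S, 10000, seed=6)
        sd_site = S.L[0].std() * np.sqrt(S.n_sites)
        assert abs(R[0].mean() - S.totals[0]) < 3 * sd_site / np.sqrt(10000)


class TestKH:
    def test_identical_rows_p_one(self):
        S = SitewiseLnL(["a", "b"], np.tile(np.arange(-10.0, 0.0), (2, 1)))
        assert kh_test(S, 0, 1, B=200, seed=0) == 1.0

    def test_dominant_tree_small_p(self):
        n = 2000
        L = np.vstack([np.full(n, -1.0), np.full(n, -1.0)])
        rng = np.random.default_rng(3)
        L[0] += rng.normal(0.05, 0.5, n)  # tree 0 better on average
        S = SitewiseLnL(["good", "bad"], L)
        assert kh_test(S, 0, 1, B=2000, seed=1) < 0.01

    def test_same_tree_rejected(self):
        S = simulate_sitelh(2, 10, seed=0)
        with pytest.raises(ValueError):
            kh_test(S, 1, 1)

    def test_null_p_values_approximately_uniform(self):
        """Exchangeable site deltas: two-sided KH p over replicates ~ U(0,1).

        (The one-sided p is reported for the post-hoc worse tree and is
        therefore uniform on (0, 1/2); the two-sided fold is the variant
        with a uniform null.)
        """
        ps = []
        for k in range(400):
            S = simulate_sitelh(2, 200, seed=10_000 + k)
            ps.append(kh_test(S, 0, 1, B=600, seed=k, two_sided=True))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_matches_normal_tail_on_iid_deltas(self):
        rng = np.random.default_rng(12)
        n, B = 1500, 8000
        deltas = rng.normal(0.01, 1.0, n)
        S = SitewiseLnL(["a", "b"], np.vstack([np.zeros(n), -deltas]))
        p = kh_test(S, 0, 1, B=B, seed=3)
        p_an = norm.sf(abs(deltas.sum()) / np.sqrt(n * deltas.var()))
        assert abs(p - p_an) < 3 * np.sqrt(p_an * (1 - p_an) / B)


class TestSH:
    def test_identical_rows_all_p_one(self):
        S = SitewiseLnL(["a", "b", "c"], np.tile(np.arange(-5.0, 0.0), (3, 1)))
        np.testing.assert_allclose(sh_test(S, B=100, seed=0), 1.0)

    def test_two_trees_equals_max_centered_kh(self):
        S = simulate_sitelh(2, 300, offsets=[0.01, 0.0], seed=7)
        R = rell_bootstrap(S, 4000, seed=5)
        p_sh = sh_test(S, replicates=R)
        p_kh = kh_test(S, 0, 1, replicates=R)
        worse = int(np.argmin(S.totals))
        assert p_sh[worse] == p_kh

    def test_dominated_tree_never_decreases_p(self):
        S = simulate_sitelh(3, 250, offsets=[0.02, 0.0, -0.01], seed=8)
        p3 = sh_test(S, B=3000, seed=2)
        S4 = SitewiseLnL(
            S.tree_ids + ["dominated"],
            np.vstack([S.L, S.L.min(axis=0) - 1.0]),
        )
        p4 = sh_test(S4, B=3000, seed=2)
        assert np.all(p4[:3] >= p3 - 1e-12)

    def test_sh_at_least_kh_for_non_best(self):
        S = simulate_sitelh(4, 300, offsets=[0.02, 0.0, -0.005, 0.01], seed=9)
        R = rell_bootstrap(S, 3000, seed=4)
        best = int(np.argmax(S.totals))
        p_sh = sh_test(S, replicates=R)
        for t in range(4):
            if t == best:
                continue
            assert p_sh[t] >= kh_test(S, best, t, replicates=R) - 1e-12


class TestWSH:
    def test_identical_rows_all_p_one(self):
        S = SitewiseLnL(["a", "b"], np.tile(np.arange(-5.0, 0.0), (2, 1)))
        np.testing.assert_allclose(wsh_test(S, B=100, seed=0), 1.0)

    def test_scale_invariance(self):
        S = simulate_sitelh(3, 200, offsets=[0.01, 0.0, -0.01], seed=11)
        p1 = wsh_test(S, B=1500, seed=6)
        S2 = SitewiseLnL(S.tree_ids, S.L * 7.0)
        p2 = wsh_test(S2, B=1500, seed=6)
        np.testing.assert_allclose(p1, p2)

    def test_heteroscedastic_disagreement_stays_valid(self):
        # tree 2's differences have much larger variance: WSH reweights
        rng = np.random.default_rng(13)
        n = 400
        L = np.vstack(
            [np.zeros(n), -0.02 + rng.normal(0, 0.1, n),
             -0.02 + rng.normal(0, 3.0, n)]
        )
        S = SitewiseLnL(["a", "b", "c"], L)
        p_s = sh_test(S, B=2000, seed=7)
        p_w = wsh_test(S, B=2000, seed=7)
        assert np.all((0 <= p_w) & (p_w <= 1)) and np.all((0 <= p_s) & (p_s <= 1))


class TestAU:
    def test_flat_half_bp_gives_half(self):
        p, d, c, degen = au_fit(np.full(10, 0.5), np.array(DEFAULT_AU_SCALES), 10000)
        assert p == 0.5 and not degen and d == 0.0 and c == 0.0

    def test_dominant_tree_degenerate(self):
        n = 500
        L = np.vstack([np.zeros(n), np.full(n, -0.5)])  # tree 0 wins every site
        S = SitewiseLnL(["good", "bad"], L)
        p, flags = au_test(S, B_per_scale=500, seed=3)
        assert p[0] == 1.0 and flags[0]
        assert p[1] == 0.0 and flags[1]

    def test_agrees_with_kh_on_two_tree_normals(self):
        S = simulate_sitelh(2, 1500, offsets=[0.012, 0.0], seed=14)
        B = 4000
        p_au, flags = au_test(S, B_per_scale=B, seed=15)
        p_kh = kh_test(S, 0, 1, B=B, seed=15)
        worse = int(np.argmin(S.totals))
        assert not flags[worse]
        se = np.sqrt(max(p_kh * (1 - p_kh), 1e-9) / B)
        assert abs(p_au[worse] - p_kh) < 5 * se + 0.01

    def test_scales_must_straddle_one(self):
        S = simulate_sitelh(2, 50, seed=0)
        with pytest.raises(ValueError):
            au_test(S, B_per_scale=10, scales=(0.5, 0.6), seed=0)


class TestReport:
    def test_report_columns_and_determinism(self):
        S = simulate_sitelh(3, 200, offsets=[0.02, 0.0, -0.02], seed=20)
        r1 = topology_report(S, B=800, seed=5)
        r2 = topology_report(S, B=800, seed=5)
        assert r1.drop(columns=["tree"]).equals(r2.drop(columns=["tree"]))
        assert {"lnL", "delta", "p_KH", "p_SH", "p_WSH", "p_AU"} <= set(r1.columns)
        assert r1["delta"].min() == 0.0
        assert ((r1[["p_KH", "p_SH", "p_WSH", "p_AU"]] >= 0).all().all())
        assert ((r1[["p_KH", "p_SH", "p_WSH", "p_AU"]] <= 1).all().all())
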