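"""Windowed statistics against hand sums and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ovintro as ov
from ovintro.panel import Window

from conftest import tiny_panel
from oracles import d_stat_oracle, fd_oracle, wc_fst_oracle


def two_group_popmap(n_samples_per_group=2):
    sb, bg = {}, {"A": "A", "B": "B"}
    for g in ("A", "B"):
        for i in range(n_samples_per_group):
            sb[f"{g}{i}"] = g
    return ov.PopMap(sb, bg)


class TestFstWindow:
    def test_identical_balanced_frequencies_zero(self):
        # both groups 50/50 at every site, equal sizes
        mat = [[0, 1, 0, 1, 0, 1, 0, 1]] * 12
        panel = tiny_panel(mat, samples=["A0", "A1", "B0", "B1"])
        w = Window("chr1", 0, panel.contigs["chr1"])
        v = ov.fst_window(panel, two_group_popmap(), "A", "B", w, min_sites=1)
        assert abs(v) < 1e-12

    def test_fixed_difference_is_one(self):
        mat = [[0, 0, 0, 0, 1, 1, 1, 1]] * 12
        panel = tiny_panel(mat, samples=["A0", "A1", "B0", "B1"])
        w = Window("chr1", 0, panel.contigs["chr1"])
        v = ov.fst_window(panel, two_group_popmap(), "A", "B", w, min_sites=1)
        assert v == pytest.approx(1.0)

    def test_matches_weir_cockerham_oracle(self):
        # 2 groups x 4 haplotypes x 3 sites, written out by hand
        mat = [
            [0, 1, 1, 1, 0, 0, 0, 1],
            [1, 1, 0, 1, 0, 0, 0, 0],
            [0, 0, 1, 0, 1, 1, 1, 0],
        ]
        panel = tiny_panel(mat, samples=["A0", "A1", "B0", "B1"])
        w = Window("chr1", 0, panel.contigs["chr1"])
        got = ov.fst_window(panel, two_group_popmap(), "A", "B", w, min_sites=1)
        gtA = [[(r[0], r[1]), (r[2], r[3])] for r in mat]
        gtB = [[(r[4], r[5]), (r[6], r[7])] for r in mat]
        assert got == pytest.approx(wc_fst_oracle(gtA, gtB), abs=1e-12)

    def test_min_sites_gives_nan(self):
        mat = [[0, 1, 1, 1, 0, 0, 0, 1]] * 3
        panel = tiny_panel(mat, samples=["A0", "A1", "B0", "B1"])
        w = Window("chr1", 0, panel.contigs["chr1"])
        assert np.isnan(ov.fst_window(panel, two_group_popmap(), "A", "B", w, min_sites=10))

    def test_symmetry(self, default_run):
        _, panel, _, pm = default_run
        w = Window("chr1", 0, 50_000)
        ab = ov.fst_window(panel, pm, "DOM1", "WLD", w)
        ba = ov.fst_window(panel, pm, "WLD", "DOM1", w)
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_hudson_estimator_available(self, default_run):
        _, panel, _, pm = default_run
        w = Window("chr1", 0, 50_000)
        v = ov.fst_window(panel, pm, "DOM1", "WLD", w, estimator="hudson")
        assert np.isfinite(v) and -0.1 <= v <= 1.0


class TestDxy:
    def test_identical_fixed_zero(self):
        assert ov.dxy_window(np.ones(5), np.ones(5), 50_000) == 0.0

    def test_single_fixed_difference(self):
        assert ov.dxy_window(np.array([1.0]), np.array([0.0]), 50_000) == pytest.approx(2.0e-5)

    def test_three_site_hand_sum(self):
        pA = np.array([0.2, 0.5, 1.0])
        pB = np.array([0.8, 0.5, 0.0])
        # 0.2*0.2+0.8*0.8 = 0.68; 0.5; 1.0 -> wait: hand sum below
        # site1: 0.2*(1-0.8)+0.8*(1-0.2) = 0.04+0.64 = 0.68? no: 0.2*0.2=0.04, 0.8*0.8=0.64
        assert ov.dxy_window(pA, pB, 10_000) == pytest.approx(
            (0.2 * 0.2 + 0.8 * 0.8 + 2 * 0.5 * 0.5 + 1.0) / 10_000
        )

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        pA, pB = rng.random(20), rng.random(20)
        assert ov.dxy_window(pA, pB, 1000) == pytest.approx(ov.dxy_window(pB, pA, 1000))

    def test_zero_sites_zero(self):
        assert ov.dxy_window(np.array([]), np.array([]), 1000) == 0.0


class TestDStat:
    def test_p1_equals_p2_gives_zero(self):
        rng = np.random.default_rng(1)
        p = rng.random(8)
        p3, pO = rng.random(8), np.zeros(8)
        assert ov.d_stat_window(p, p, p3, pO) == pytest.approx(0.0, abs=1e-12)

    def test_single_pure_abba_site(self):
        assert ov.d_stat_window([0.0], [1.0], [1.0], [0.0]) == pytest.approx(1.0)

    def test_four_site_toy_equals_oracle(self):
        p1 = [0.1, 0.0, 0.5, 0.9]
        p2 = [0.8, 0.2, 0.5, 0.1]
        p3 = [0.9, 0.9, 0.1, 0.2]
        pO = [0.0, 0.1, 0.0, 0.05]
        assert ov.d_stat_window(p1, p2, p3, pO) == pytest.approx(
            d_stat_oracle(p1, p2, p3, pO), abs=1e-12
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(1, 10), st.integers(0, 10_000))
    def test_equals_double_loop_oracle_on_random_tables(self, n_sites, seed):
        rng = np.random.default_rng(seed)
        p1, p2, p3, pO = (rng.random(n_sites) for _ in range(4))
        got = ov.d_stat_window(p1, p2, p3, pO)
        exp = d_stat_oracle(p1, p2, p3, pO)
        assert got == pytest.approx(exp, abs=1e-12)


class TestFd:
    def test_donor_equals_recipient_excess_gives_one(self):
        p1 = np.array([0.0, 0.1, 0.2])
        p23 = np.array([0.9, 0.8, 0.7])
        pO = np.zeros(3)
        assert ov.fd_window(p1, p23, p23, pO) == pytest.approx(1.0)

    def test_p3_equals_p1_balanced_sites_give_zero(self):
        # with P3 identical to P1 and P2 deviations balanced across sites,
        # the ABBA-BABA sum cancels exactly: numerator 0 -> f_d = 0
        p13 = np.array([0.5, 0.5])
        p2 = np.array([0.3, 0.7])
        pO = np.zeros(2)
        assert ov.fd_window(p13, p2, p13, pO) == pytest.approx(0.0, abs=1e-12)

    def test_per_site_max_rule_matches_hand_oracle(self):
        # third site has p2 > p3, exercising the dynamic-donor max rule
        p1 = [0.1, 0.0, 0.1]
        p2 = [0.6, 0.5, 0.9]
        p3 = [0.9, 0.8, 0.4]
        pO = [0.0, 0.0, 0.0]
        assert ov.fd_window(p1, p2, p3, pO) == pytest.approx(
            fd_oracle(p1, p2, p3, pO), abs=1e-12
        )

    def test_negative_d_window_is_nan(self):
        # strong BABA excess
        p1 = np.array([1.0, 1.0])
        p2 = np.array([0.0, 0.0])
        p3 = np.array([1.0, 1.0])
        pO = np.zeros(2)
        assert np.isnan(ov.fd_window(p1, p2, p3, pO))


class TestZScan:
    def test_value_at_mean_two_tailed_p_one(self):
        out = ov.z_scan([1.0, 2.0, 3.0], tail="two")
        assert out["p"][1] == pytest.approx(1.0)

    def test_upper_tail_value_from_normal_table(self):
        # a window at z = 3.2905 has upper-tail p ~ 5.0e-4, i.e. below the
        # 0.001 significance level used by the scans
        base = np.linspace(-1.0, 1.0, 100)
        v = 3.0
        for _ in range(100):  # fixed point: last element lands at z = 3.2905
            arr = np.r_[base, v]
            v = arr.mean() + 3.2905 * arr.std(ddof=1)
        out = ov.z_scan(np.r_[base, v], tail="upper")
        assert out["z"].iloc[-1] == pytest.approx(3.2905, rel=1e-6)
        assert out["p"].iloc[-1] == pytest.approx(5.0e-4, rel=1e-2)
        assert bool(out["significant"].iloc[-1])

    def test_constant_vector_warns_p_one(self):
        with pytest.warns(UserWarning, match="constant"):
            out = ov.z_scan([2.0, 2.0, 2.0])
        assert (out["p"] == 1.0).all()

    def test_significance_flag_threshold(self):
        x = np.zeros(2000)
        x[0] = 50.0  # extreme outlier: z >> 3.29
        out = ov.z_scan(x, tail="upper")
        assert bool(out["significant"][0])
        assert out["significant"][1:].sum() == 0


class TestPermutationThreshold:
    def test_deterministic_for_fixed_seed(self, default_run):
        _, panel, _, pm = default_run
        args = dict(n_draw=6, reps=2, size=100_000, step=100_000, seed=9)
        a = ov.fst_permutation_threshold(panel, pm, ["DOM1", "DOM2"], "WLD", **args)
        b = ov.fst_permutation_threshold(panel, pm, ["DOM1", "DOM2"], "WLD", **args)
        assert a == b and np.isfinite(a)

    def test_identical_populations_give_near_zero(self):
        rng = np.random.default_rng(2)
        n = 25
        base = (rng.random((2000, 2 * n)) < rng.random(2000)[:, None]).astype(np.int8)
        mat = np.concatenate([base, base], axis=1)  # "wild" = duplicated domestic
        panel = tiny_panel(
            mat, samples=[f"d{i}" for i in range(n)] + [f"w{i}" for i in range(n)]
        )
        pm = ov.PopMap(
            {f"d{i}": "dom" for i in range(n)} | {f"w{i}": "wild" for i in range(n)},
            {"dom": "dom", "wild": "wild"},
        )
        thr = ov.fst_permutation_threshold(
            panel, pm, ["dom"], "wild", n_draw=20, reps=5,
            size=panel.contigs["chr1"], step=panel.contigs["chr1"], min_sites=5, seed=1,
        )
        assert thr <= 0.02

    def test_insufficient_samples_raises(self, default_run):
        _, panel, _, pm = default_run
        with pytest.raises(ValueError, match="at least"):
            ov.fst_permutation_threshold(panel, pm, ["DOM1"], "WLD", n_draw=33, reps=1)


class TestScanDriver:
    def test_scan_columns_and_invariants(self, default_run):
        _, panel, _, pm = default_run
        df = ov.scan_windows(panel, pm, "EU_OA", "DOM1", "WLD", "OUT")
        assert {"fst", "dxy", "D", "fd", "z_fd", "p_fd", "z_fst", "p_fst"} <= set(df.columns)
        assert (df["dxy"].dropna() >= 0).all()
        d = df["D"].dropna()
        assert ((d >= -1) & (d <= 1)).all()
        # fd defined only where D >= 0 (up to the zero tolerance)
        defined = df[np.isfinite(df["fd"])]
        assert (defined["D"] >= -1e-12).all()

    def test_polarization_excludes_polymorphic_outgroup_sites(self):
        freqs = {
            "A": np.array([0.5, 0.5, 0.5]),
            "O": np.array([0.05, 0.5, 0.95]),
        }
        pol, keep = ov.polarize_by_outgroup(freqs, "O")
        assert list(keep) == [True, False, True]
        assert pol["A"][2] == pytest.approx(0.5)
        assert pol["O"][2] == pytest.approx(0.05)  # flipped to ancestral scale
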