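import numpy as np
import pytest
from scipy import stats

from nebkha import PatchPattern, RectWindow, build_grid, distance_sl_test
from nebkha.gridstats import (
    CorrelationResult,
    cohort_density_correlations,
    pearson_test,
    plot_stats,
    static_vs_dynamic,
)
from nebkha.synthetic import generate_csr_cohort


class TestBuildGrid:
    @pytest.mark.parametrize(
        "w,h,side,expected",
        [
            (42, 42, 21, 4),
            (84, 126, 42, 6),
            (125, 250, 21, 55),  # floor(125/21) * floor(250/21) = 5 * 11
        ],
    )
    def test_tiling_counts(self, w, h, side, expected):
        grid = build_grid(RectWindow(0, 0, w, h), side)
        assert len(grid) == expected

    def test_oversized_side_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            grid = build_grid(RectWindow(0, 0, 10, 10), 11)
        assert len(grid) == 0

    def test_offset_shifts_lattice(self):
        grid = build_grid(RectWindow(0, 0, 50, 50), 21, origin_offset=(4, 4))
        assert len(grid) == 4
        assert grid.origins.min() == 4.0


class TestPlotStats:
    def test_single_patch_counted_once(self):
        w = RectWindow(0, 0, 42, 42)
        grid = build_grid(w, 21)
        pat = PatchPattern(w, [10.5], [10.5], [1.0], label="A_S")
        table = plot_stats({"A_S": pat}, grid)
        assert table["count_A_S"].sum() == 1
        assert table["count_A_S"].max() == 1
        assert table["density_A_S"].max() == pytest.approx(1 / 441)
        assert table["fvc_A_S"].max() == pytest.approx(np.pi / 4 / 441)

    def test_centroid_on_shared_edge_assigned_to_one_plot(self):
        w = RectWindow(0, 0, 42, 42)
        grid = build_grid(w, 21)
        pat = PatchPattern(w, [21.0], [10.0], [0.2])
        table = plot_stats([pat], grid)
        assert table.filter(like="count").to_numpy().sum() == 1

    def test_counts_conserved_when_grid_tiles_window(self, square_window, small_sizes):
        rng = np.random.default_rng(2)
        pat = generate_csr_cohort(square_window, 150, small_sizes, rng, label="UI")
        grid = build_grid(square_window, 20)  # exact 5x5 tiling
        table = plot_stats({"UI": pat}, grid)
        assert table["count_UI"].sum() == len(pat)

    def test_csr_counts_are_poisson_dispersed(self, point_sizes):
        """Index of dispersion of CSR plot counts ~ 1 (chi-square bounds)."""
        w = RectWindow(0, 0, 125, 250)
        rng = np.random.default_rng(4)
        pat = generate_csr_cohort(w, 200, point_sizes, rng)
        grid = build_grid(w, 21)
        counts = plot_stats([pat], grid).filter(like="count").to_numpy().ravel()
        n = counts.size
        disp = (n - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = stats.chi2.ppf([0.005, 0.995], n - 1)
        assert lo < disp < hi


class TestCorrelation:
    def test_matches_from_scratch_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = pearson_test(x, y)
        manual = np.mean((x - x.mean()) * (y - y.mean())) / (
            x.std(ddof=0) * y.std(ddof=0)
        )
        assert res.r == pytest.approx(manual, abs=1e-12)

    def test_p_value_matches_permutation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        res = pearson_test(x, y)
        perm = stats.permutation_test(
            (x, y),
            lambda a, b: stats.pearsonr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=10_000,
            alternative="two-sided",
            rng=np.random.default_rng(2),
        )
        assert res.p_value == pytest.approx(perm.pvalue, abs=0.02)

    def test_zero_variance_flagged(self):
        res = pearson_test(np.ones(10), np.arange(10))
        assert not res.defined and res.note == "zero variance"

    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).normal(size=20)
        assert pearson_test(x, x).r == pytest.approx(1.0)


class TestDistanceSL:
    @staticmethod
    def _adults_and_ui(rng, w, seed_shadow):
        from nebkha.synthetic import CohortSizeModel

        adults = generate_csr_cohort(
            w, 60, CohortSizeModel("A_M", 1.4, 0.25), rng, label="A_M"
        )
        if seed_shadow:
            # recruits only within 5 m of adults (seed-shadow construction)
            k = rng.integers(0, len(adults), 150)
            ang = rng.uniform(0, 2 * np.pi, 150)
            dist = rng.uniform(1.0, 5.0, 150)
            x = np.clip(adults.x[k] + dist * np.cos(ang), 0.2, w.width - 0.2)
            y = np.clip(adults.y[k] + dist * np.sin(ang), 0.2, w.height - 0.2)
            ui = PatchPattern(w, x, y, np.full(150, 0.1), label="UI")
        else:
            ui = generate_csr_cohort(
                w, 150, CohortSizeModel("UI", 0.12, 0.35), rng, label="UI"
            )
        return adults, ui

    def test_seed_shadow_detected(self, square_window):
        """Recruits confined to adult surroundings: supported >= 95/100."""
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            adults, ui = self._adults_and_ui(rng, square_window, True)
            res = distance_sl_test([adults], ui, square_window, (20.0, 50.0))
            hits += res.verdict == "supported"
        assert hits >= 95

    def test_null_rejection_rate_near_alpha(self, square_window):
        """Independent recruits: per-side rejection frequency ~ alpha."""
        sig = 0
        reps = 150
        for rep in range(reps):
            rng = np.random.default_rng(2000 + rep)
            adults, ui = self._adults_and_ui(rng, square_window, False)
            res = distance_sl_test([adults], ui, square_window, (20.0,))
            cr = res.per_side[20.0]
            sig += cr.defined and cr.p_value < 0.05
        # binomial 99.5% bounds around 0.05 with n = 150
        assert 1 <= sig <= 17

    def test_undefined_when_recruits_absent(self, square_window):
        rng = np.random.default_rng(5)
        adults, _ = self._adults_and_ui(rng, square_window, False)
        ui = PatchPattern.empty(square_window, "UI")
        res = distance_sl_test([adults], ui, square_window, (20.0, 50.0))
        assert res.verdict == "rejected"
        assert all(not cr.defined for cr in res.per_side.values())


class TestCohortCorrelations:
    def test_shared_parents_positively_correlated(self, square_window, small_sizes):
        from nebkha.synthetic import generate_thomas_cohort

        rs = []
        for rep in range(15):
            rng = np.random.default_rng(3000 + rep)
            a, parents = generate_thomas_cohort(
                square_window, 8e-4, 15, 4.0, small_sizes, rng, label="A_S"
            )
            b, _ = generate_thomas_cohort(
                square_window, 8e-4, 15, 4.0, small_sizes, rng,
                parents=parents, fixed=[a], label="A_M",
            )
            grid = build_grid(square_window, 21)
            corr = cohort_density_correlations({"A_S": a, "A_M": b}, grid)
            rs.append(corr[("A_S", "A_M")].r)
        assert np.mean(rs) > 0.5

    def test_independent_cohorts_rarely_significant(self, square_window, small_sizes):
        false_pos = 0
        for rep in range(40):
            rng = np.random.default_rng(4000 + rep)
            a = generate_csr_cohort(square_window, 80, small_sizes, rng, label="A_S")
            b = generate_csr_cohort(
                square_window, 80, small_sizes, rng, fixed=[a], label="A_M"
            )
            grid = build_grid(square_window, 21)
            cr = cohort_density_correlations({"A_S": a, "A_M": b}, grid)[("A_S", "A_M")]
            false_pos += cr.defined and cr.p_value < 0.05
        assert false_pos <= 7  # binomial upper bound around 0.05 * 40


class TestStaticVsDynamic:
    @staticmethod
    def _fake_corr(n_sig, n_pairs=10):
        out = {}
        for i in range(n_pairs):
            p = 0.01 if i < n_sig else 0.5
            out[(f"c{i}", f"d{i}")] = CorrelationResult(0.5, p, 55)
        return out

    @pytest.mark.parametrize(
        "n_sig,verdict",
        [(4, "dynamic"), (10, "static"), (0, "dynamic"), (5, "static")],
    )
    def test_threshold(self, n_sig, verdict):
        res = static_vs_dynamic(self._fake_corr(n_sig))
        assert res.verdict == verdict
        assert res.n_significant == n_sig

    def test_monotone_in_significant_pairs(self):
        """Adding a significant pair can never flip static -> dynamic."""
        for k in range(10):
            a = static_vs_dynamic(self._fake_corr(k)).verdict
            b = static_vs_dynamic(self._fake_corr(k + 1)).verdict
            assert not (a == "static" and b == "dynamic")
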