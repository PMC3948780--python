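import numpy as np
import pytest

from nebkha import pcf_edge
from nebkha.envelopes import (
    DeviationInterval,
    build_envelope,
    cluster_scale,
    deviation_strength,
    find_deviation_intervals,
    gof_test,
    loosmore_u,
)
from nebkha.nullmodels import simulate_univariate_null
from nebkha.summary import SummaryFunction
from nebkha.synthetic import generate_thomas_cohort


def _sf(r, values, bandwidth=0.0):
    return SummaryFunction(
        r, values, "pcf", bandwidth, 10, reliable=np.ones(len(r), bool)
    )


R = np.linspace(0.0, 10.0, 21)  # step 0.5


class TestBuildEnvelope:
    def test_degenerate_batch(self):
        obs = _sf(R, np.ones_like(R))
        sims = [_sf(R, np.ones_like(R)) for _ in range(10)]
        env = build_envelope(obs, sims)
        assert np.all(env.lo == 1) and np.all(env.hi == 1) and np.all(env.mean == 1)
        assert env.n_sims == 10

    def test_pointwise_exceedance_probability(self):
        """Null observed leaves the min/max band with prob 2/(n+1) per point."""
        rng = np.random.default_rng(0)
        n_sims, n_pts, reps = 49, 50, 400
        outside = 0
        for _ in range(reps):
            fns = rng.normal(size=(n_sims + 1, n_pts))
            obs, sims = fns[0], fns[1:]
            outside += np.sum((obs > sims.max(0)) | (obs < sims.min(0)))
        rate = outside / (reps * n_pts)
        assert rate == pytest.approx(2 / (n_sims + 1), rel=0.15)

    def test_bounds_monotone_in_batch_size(self):
        rng = np.random.default_rng(1)
        sims = [_sf(R, rng.normal(1, 0.2, R.size)) for _ in range(40)]
        obs = _sf(R, np.ones_like(R))
        small = build_envelope(obs, sims[:20])
        big = build_envelope(obs, sims)
        assert np.all(big.lo <= small.lo) and np.all(big.hi >= small.hi)

    def test_mismatched_grid_rejected(self):
        obs = _sf(R, np.ones_like(R))
        bad = _sf(R + 0.1, np.ones_like(R))
        with pytest.raises(ValueError):
            build_envelope(obs, [bad])


class TestFindDeviationIntervals:
    @staticmethod
    def _env(lo=0.8, hi=1.2):
        obs = _sf(R, np.ones_like(R))
        sims = [_sf(R, np.full_like(R, lo)), _sf(R, np.full_like(R, hi))]
        return build_envelope(obs, sims)

    def test_inside_everywhere_gives_empty_list(self):
        env = self._env()
        assert find_deviation_intervals(env.observed, env) == []

    def test_constructed_exceedance_interval(self):
        env = self._env()
        vals = np.ones_like(R)
        vals[(R >= 2) & (R <= 6)] = 1.3
        obs = _sf(R, vals)
        (iv,) = find_deviation_intervals(obs, env)
        assert (iv.r_start, iv.r_end, iv.sign) == (2.0, 6.0, "above")

    def test_single_point_noise_discarded(self):
        env = self._env()
        vals = np.ones_like(R)
        vals[::4] = 1.5  # isolated exceedances separated by inside points
        obs = _sf(R, vals)
        assert find_deviation_intervals(obs, env, min_width=2) == []
        assert len(find_deviation_intervals(obs, env, min_width=1)) > 0

    def test_below_sign(self):
        env = self._env()
        vals = np.ones_like(R)
        vals[(R >= 1) & (R <= 3)] = 0.5
        obs = _sf(R, vals)
        (iv,) = find_deviation_intervals(obs, env)
        assert iv.sign == "below"


class TestGofTest:
    def test_constant_offset_closed_form(self):
        """A function offset by delta over the interval scores u = delta^2 L."""
        rng = np.random.default_rng(2)
        base = rng.normal(1, 0.1, R.size)
        delta = 0.7
        obs = _sf(R, base + delta)
        sims = [_sf(R, base.copy()) for _ in range(99)]
        iv = DeviationInterval(R[4], R[12], "above", 4, 12)
        tested = gof_test(iv, obs, sims, k=1)
        length = R[12] - R[4] + 0.5  # gradient weights include the end steps
        assert tested.u_observed == pytest.approx(delta**2 * length, rel=1e-9)
        assert tested.rank_high == 1 and tested.significant

    def test_tiny_hand_computed_case(self):
        """3 functions on 2 grid points, u values checked by hand.

        obs = (1, 2), sims = (0, 0) and (2, 4); dr = (1, 1).
        loo means: for obs -> (1, 2); for s1 -> (1.5, 3); for s2 -> (0.5, 1).
        u: obs -> 0; s1 -> 2.25 + 9; s2 -> 2.25 + 9.
        """
        r2 = np.array([0.0, 1.0])
        obs = _sf(r2, np.array([1.0, 2.0]))
        sims = [_sf(r2, np.array([0.0, 0.0])), _sf(r2, np.array([2.0, 4.0]))]
        iv = DeviationInterval(0.0, 1.0, "above", 0, 1)
        tested = gof_test(iv, obs, sims, k=1)
        assert tested.u_observed == pytest.approx(0.0)
        mat = np.array([[1, 2], [0, 0], [2, 4]], float)
        u = loosmore_u(mat, np.array([1.0, 1.0]))
        assert u == pytest.approx([0.0, 11.25, 11.25])
        assert tested.rank_low == 1 and tested.significant

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        base = [rng.normal(1, 0.3, R.size) for _ in range(50)]
        obs_vals = rng.normal(1, 0.3, R.size)
        iv = DeviationInterval(R[2], R[10], "above", 2, 10)
        t1 = gof_test(iv, _sf(R, obs_vals), [_sf(R, b) for b in base], k=1)
        t2 = gof_test(
            iv, _sf(R, obs_vals + 5.0), [_sf(R, b + 5.0) for b in base], k=1
        )
        assert t1.u_observed == pytest.approx(t2.u_observed, rel=1e-9)
        assert (t1.rank_high, t1.rank_low) == (t2.rank_high, t2.rank_low)

    def test_ties_resolved_in_favor_of_observed(self):
        obs = _sf(R, np.ones_like(R))
        sims = [_sf(R, np.ones_like(R)) for _ in range(9)]
        iv = DeviationInterval(R[0], R[5], "above", 0, 5)
        tested = gof_test(iv, obs, sims, k=1)
        # all u identical: ties count the observed as most extreme both ways
        assert tested.rank_high == 1 and tested.rank_low == 1

    def test_interval_outside_grid_rejected(self):
        obs = _sf(R, np.ones_like(R))
        iv = DeviationInterval(0, 99, "above", 0, 99)
        with pytest.raises(ValueError):
            gof_test(iv, obs, [_sf(R, np.ones_like(R))], k=1)


class TestDeviationStrength:
    @staticmethod
    def _env_with_obs(lo, hi, obs_vals):
        obs = _sf(R, obs_vals)
        sims = [_sf(R, np.full_like(R, lo)), _sf(R, np.full_like(R, hi))]
        return build_envelope(obs, sims)

    def test_constant_envelope_arithmetic(self):
        env = self._env_with_obs(0.8, 1.2, np.full_like(R, 1.5))
        iv = DeviationInterval(R[0], R[-1], "above", 0, R.size - 1)
        assert deviation_strength(iv, env).strength == pytest.approx(0.5)

    def test_wider_envelope_weaker(self):
        iv = DeviationInterval(R[0], R[-1], "above", 0, R.size - 1)
        narrow = deviation_strength(
            iv, self._env_with_obs(0.9, 1.2, np.full_like(R, 1.5))
        ).strength
        wide = deviation_strength(
            iv, self._env_with_obs(0.5, 1.2, np.full_like(R, 1.5))
        ).strength
        assert wide < narrow

    def test_inside_envelope_scores_zero(self):
        env = self._env_with_obs(0.8, 1.2, np.ones_like(R))
        iv = DeviationInterval(R[0], R[-1], "above", 0, R.size - 1)
        assert deviation_strength(iv, env).strength == 0.0


class TestClusterScale:
    @staticmethod
    def _iv(r_start, r_end, sign="above", significant=True):
        return DeviationInterval(
            r_start, r_end, sign, int(r_start * 2), int(r_end * 2),
            significant=significant,
        )

    def test_first_significant_above_interval(self):
        assert cluster_scale([self._iv(0.0, 10.0)], R) == 10.0

    def test_none_without_significant_intervals(self):
        assert cluster_scale([self._iv(0, 10, significant=False)], R) is None
        assert cluster_scale([], R) is None

    def test_interval_far_from_origin_ignored(self):
        assert cluster_scale([self._iv(5.0, 10.0)], R) is None

    def test_respects_first_valid_r(self):
        assert cluster_scale([self._iv(1.5, 9.0)], R, first_valid_r=1.5) == 9.0

    def test_recovers_thomas_cluster_diameter(self, square_window, small_sizes):
        """Scale within a factor 2 of the ~4 sigma cluster diameter."""
        sigma = 5.0
        r = np.linspace(0, 45, 91)
        scales = []
        for rep in range(20):
            rng = np.random.default_rng(600 + rep)
            pat, _ = generate_thomas_cohort(
                square_window, 0.0015, 10, sigma, small_sizes, rng
            )
            if len(pat) < 20:
                continue
            obs = pcf_edge(pat, r)
            sims = []
            for _ in range(198):
                s = simulate_univariate_null(pat, [], square_window, rng=rng)
                sims.append(pcf_edge(s, r, obs.bandwidth))
            env = build_envelope(obs, sims[:99])
            tested = [
                gof_test(iv, obs, sims[99:], 1)
                for iv in find_deviation_intervals(obs, env)
            ]
            fv = obs.r[env.valid]
            scales.append(
                cluster_scale(tested, r, float(fv[0]) if fv.size else None)
            )
        recovered = [s for s in scales if s is not None and 10 <= s <= 40]
        assert len(scales) >= 15
        assert len(recovered) >= 0.8 * len(scales)
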