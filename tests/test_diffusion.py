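"""MSD fitting, osd speeds and the osd² mixture model."""

import numpy as np
import pandas as pd
import pytest

from sptq import (
    Trajectory,
    MSDCurve,
    simulate_trajectories,
    compute_msd_ensemble,
    fit_msd_linear,
    compute_osd_speed,
    fit_cdf_mixture,
    select_state_number,
    constrain_from_reference,
    steps_table,
)
from sptq.diffusion import MixtureFit

from conftest import unconfined_config

T0 = 0.00576  # s, interval between consecutive frames


def truth_trajectories(truth):
    return [
        Trajectory(e.emitter_id, np.arange(len(e.frames)), e.xy)
        for e in truth.emitters
        if len(e.frames) > 6
    ]


def sample_osd2(rng, n, fracs, d_primes, t):
    """Draw osd² from the mixture: component i is Exp(mean 4·D'_i·t)."""
    comp = rng.choice(len(fracs), size=n, p=fracs)
    return rng.exponential(4 * np.asarray(d_primes)[comp] * t)


class TestMSD:
    def test_static_trajectories_msd_zero(self):
        trajs = [Trajectory(i, np.arange(20), np.full((20, 2), float(i))) for i in range(3)]
        curve = compute_msd_ensemble(trajs, max_lag=5)
        assert np.all(curve.msd_um2 == 0.0)

    def test_unconfined_msd_matches_closed_form(self):
        """Free diffusion at D_conv = 0.5: MSD(mΔt) = 4·0.5·mΔt within 3%."""
        truth = simulate_trajectories(unconfined_config(0.5, seed=50, n_frames=40000))
        trajs = truth_trajectories(truth)
        curve = compute_msd_ensemble(trajs, max_lag=4, frame_interval=T0)
        assert (curve.n_pairs >= 1e4).all()
        np.testing.assert_allclose(curve.msd_um2, 2.0 * curve.lags_s, rtol=0.03)

    def test_localization_noise_adds_constant_offset(self):
        """Noise σ adds 4σ² to every MSD lag (unconfined)."""
        sigma = 0.04
        truth = simulate_trajectories(
            unconfined_config(0.5, seed=51, n_frames=40000, loc_sigma=sigma)
        )
        obs = truth.to_table(observed=True)
        trajs = [
            Trajectory(int(eid), np.arange(len(g)), g[["x_um", "y_um"]].to_numpy())
            for eid, g in obs.groupby("emitter_id")
            if len(g) > 6
        ]
        curve = compute_msd_ensemble(trajs, max_lag=4, frame_interval=T0)
        offset = curve.msd_um2 - 2.0 * curve.lags_s
        np.testing.assert_allclose(offset, 4 * sigma**2, rtol=0.15)

    def test_fit_exact_line(self):
        curve = MSDCurve(
            lags_s=np.arange(1, 6) * T0,
            msd_um2=2.0 * np.arange(1, 6) * T0,
            n_pairs=np.full(5, 100),
        )
        fit = fit_msd_linear(curve, n_lags=4)
        assert fit.d_paper == pytest.approx(2.0)
        assert fit.d_conv == pytest.approx(0.5)
        assert fit.d_paper == 4 * fit.d_conv  # identity holds exactly

    def test_all_zero_msd_gives_zero_d(self):
        curve = MSDCurve(np.arange(1, 5) * T0, np.zeros(4), np.full(4, 10))
        assert fit_msd_linear(curve).d_paper == 0.0

    def test_negative_slope_clamped(self):
        # MSDCurve forbids negative values at construction; emulate a noisy
        # estimator output by overwriting after validation
        curve = MSDCurve(np.arange(1, 5) * T0, np.zeros(4), np.full(4, 10))
        curve.msd_um2 = -np.arange(1, 5) * T0 * 0.1
        fit = fit_msd_linear(curve)
        assert fit.d_paper == 0.0 and fit.clamped


class TestOsdSpeed:
    def test_speed_arithmetic(self):
        steps = pd.DataFrame(
            {"osd_um": [0.1, 0.0], "dt_s": [T0, T0], "x_mid": [0, 0], "y_mid": [0, 0]}
        )
        out = compute_osd_speed(steps)
        assert out["speed_um_s"].iloc[0] == pytest.approx(0.1 / T0)  # 17.36 µm/s
        assert out["speed_um_s"].iloc[1] == 0.0

    def test_mixed_intervals_rejected(self):
        steps = pd.DataFrame({"osd_um": [0.1, 0.1], "dt_s": [T0, 2 * T0]})
        with pytest.raises(ValueError, match="uniform"):
            compute_osd_speed(steps)

    def test_fast_state_is_faster_on_average(self, two_state_truth):
        tab = two_state_truth.to_table()
        speeds = {}
        for state, g in tab.groupby("state"):
            sq = []
            for _, e in g.groupby("emitter_id"):
                e = e.sort_values("frame")
                d = np.linalg.norm(np.diff(e[["x_um", "y_um"]].to_numpy(), axis=0), axis=1)
                sq.append(d)
            speeds[state] = np.concatenate(sq).mean() / T0
        assert speeds[0] > speeds[1]  # state 0 = fast (D_conv 2.0 vs 0.05)


class TestMixtureFit:
    def test_single_state_matches_moment_estimator(self):
        """One-state osd² is exponential with mean 4·D'·t: the CDF fit and
        the sample-mean estimator agree within 3%."""
        rng = np.random.default_rng(60)
        osd2 = rng.exponential(4 * 1.0 * T0, size=20000)
        fit = fit_cdf_mixture(osd2, n=1, t=T0)
        d_moment = osd2.mean() / (4 * T0)
        assert fit.d_primes[0] == pytest.approx(1.0, rel=0.03)
        assert fit.d_primes[0] == pytest.approx(d_moment, rel=0.03)

    def test_two_state_recovery(self):
        rng = np.random.default_rng(61)
        osd2 = sample_osd2(rng, 20000, [0.6, 0.4], [0.05, 2.0], T0)
        fit = fit_cdf_mixture(osd2, n=2, t=T0)
        p_slow = fit.fractions[1]  # states sorted descending by D'
        assert p_slow == pytest.approx(0.6, abs=0.02)
        assert fit.d_primes[0] == pytest.approx(2.0, rel=0.10)
        assert fit.d_primes[1] == pytest.approx(0.05, rel=0.10)

    def test_model_is_a_proper_cdf(self):
        fit = MixtureFit(
            n=2, fractions=[0.3, 0.7], d_primes=[2.0, 0.05], t=T0, rss=0.0
        )
        assert fit.cdf(np.array([0.0]))[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.cdf(np.array([1e9]))[0] == pytest.approx(1.0, abs=1e-12)
        x = np.linspace(0, 0.1, 50)
        assert np.all(np.diff(fit.cdf(x)) >= 0)

    def test_d_states_are_4x_d_primes(self):
        fit = MixtureFit(n=1, fractions=[1.0], d_primes=[0.7], t=T0, rss=0.0)
        assert fit.d_states[0] == 4 * 0.7

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError, match="500"):
            fit_cdf_mixture(np.ones(100), n=1, t=T0)

    def test_constrained_fit_respects_interval(self):
        rng = np.random.default_rng(62)
        osd2 = sample_osd2(rng, 20000, [0.6, 0.4], [0.05, 2.0], T0)
        interval = (1.0, 1.5)  # deliberately excludes the true 2.0
        fit = fit_cdf_mixture(osd2, n=2, t=T0, d1_constraint=interval)
        assert interval[0] - 1e-9 <= fit.d_primes[0] <= interval[1] + 1e-9

    def test_constraint_inactive_when_optimum_inside(self):
        rng = np.random.default_rng(63)
        osd2 = sample_osd2(rng, 20000, [0.6, 0.4], [0.05, 2.0], T0)
        free = fit_cdf_mixture(osd2, n=2, t=T0)
        boxed = fit_cdf_mixture(osd2, n=2, t=T0, d1_constraint=(1.0, 3.0))
        assert boxed.d_primes[0] == pytest.approx(free.d_primes[0], rel=1e-3)
        assert boxed.fractions[0] == pytest.approx(free.fractions[0], abs=1e-3)


class TestStateNumberSelection:
    def test_single_state_data_selects_one(self):
        rng = np.random.default_rng(64)
        osd2 = rng.exponential(4 * 0.5 * T0, size=20000)
        n, fits = select_state_number(osd2, T0)
        assert n == 1

    def test_two_state_data_selects_two(self):
        rng = np.random.default_rng(65)
        osd2 = sample_osd2(rng, 20000, [0.6, 0.4], [0.05, 2.0], T0)
        n, fits = select_state_number(osd2, T0)
        assert n == 2
        # the third state buys less than the configured improvement factor
        assert fits[2].rss < 2.0 * fits[3].rss


class TestReferenceConstraint:
    def test_hand_computed_interval(self):
        """Replicates {2.0, 2.2}: mean 2.1, sample s.d. 0.1414, interval
        2.1 ± 0.2828."""
        fits = [
            MixtureFit(n=2, fractions=[0.5, 0.5], d_primes=[d, 0.05], t=T0, rss=0.0)
            for d in (2.0, 2.2)
        ]
        lo, hi = constrain_from_reference(fits)
        assert lo == pytest.approx(2.1 - 2 * np.std([2.0, 2.2], ddof=1))
        assert lo == pytest.approx(1.81715, abs=1e-4)
        assert hi == pytest.approx(2.38284, abs=1e-4)

    def test_identical_replicates_degenerate_interval(self):
        fits = [
            MixtureFit(n=1, fractions=[1.0], d_primes=[1.5], t=T0, rss=0.0)
            for _ in range(3)
        ]
        lo, hi = constrain_from_reference(fits)
        assert lo == hi == 1.5

    def test_single_replicate_warns(self):
        fit = MixtureFit(n=1, fractions=[1.0], d_primes=[1.5], t=T0, rss=0.0)
        with pytest.warns(UserWarning, match="single reference replicate"):
            lo, hi = constrain_from_reference([fit])
        assert lo == hi == 1.5
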