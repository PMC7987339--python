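"""Spot detection, Gaussian fitting and drift correction."""

import numpy as np
import pandas as pd
import pytest

from sptq import (
    SimulationConfig,
    simulate_trajectories,
    render_movie,
    detect_candidates,
    fit_gaussian2d,
    estimate_drift_fft,
    localize_stack,
)
from sptq.reconstruction import apply_drift_correction


def gaussian_frame(shape, spots, sigma=1.2, background=0.0):
    """Render noiseless point-sampled Gaussian spots (model of the fitter)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    img = np.full(shape, background, dtype=float)
    for (r, c, amp) in spots:
        img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
    return img


def brute_force_candidates(frame):
    """Exhaustive re-implementation of the two detection rules."""
    frame = np.asarray(frame, float)
    thr = frame.mean() + 3 * frame.std()
    h, w = frame.shape
    out = []
    for r in range(3, h - 3):
        for c in range(3, w - 3):
            if frame[r, c] <= thr:
                continue
            win = frame[max(r - 2, 0) : r + 3, max(c - 2, 0) : c + 3]
            if frame[r, c] < win.max():
                continue
            # lexicographic tie-break among equal maxima
            tied = False
            for rr in range(max(r - 2, 0), min(r + 3, h)):
                for cc in range(max(c - 2, 0), min(c + 3, w)):
                    if (rr, cc) < (r, c) and frame[rr, cc] == frame[r, c]:
                        tied = True
            if not tied:
                out.append((r, c))
    return out


class TestDetectCandidates:
    def test_all_zero_frame_yields_nothing(self):
        assert detect_candidates(np.zeros((32, 32))) == []

    def test_constant_frame_yields_nothing(self):
        assert detect_candidates(np.full((32, 32), 7.0)) == []

    def test_single_spot_matches_brute_force(self):
        frame = gaussian_frame((48, 48), [(20, 30, 50.0)], background=1.0)
        got = detect_candidates(frame)
        assert got == [(20, 30)]
        assert got == brute_force_candidates(frame)

    def test_equal_peaks_tie_break_within_window(self):
        # 2 px apart: inside each other's 5×5 window, lexicographic winner kept
        frame = np.zeros((32, 32))
        frame[15, 15] = 10.0
        frame[15, 17] = 10.0
        got = detect_candidates(frame)
        assert got == [(15, 15)]
        assert got == brute_force_candidates(frame)

    def test_equal_peaks_outside_window_both_kept(self):
        # 3 px apart: distinct 5×5 neighbourhoods, both are genuine candidates
        frame = np.zeros((32, 32))
        frame[15, 15] = 10.0
        frame[15, 18] = 10.0
        got = detect_candidates(frame)
        assert got == [(15, 15), (15, 18)]
        assert got == brute_force_candidates(frame)

    def test_random_frames_match_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            frame = rng.poisson(4.0, size=(24, 24)).astype(float)
            frame[10, 12] += 60
            assert detect_candidates(frame) == brute_force_candidates(frame)

    def test_border_candidates_dropped(self):
        frame = gaussian_frame((32, 32), [(1, 1, 50.0)])
        assert detect_candidates(frame) == []


class TestFitGaussian2D:
    def test_pixel_centered_spot_recovered_exactly(self):
        frame = gaussian_frame((21, 21), [(10, 10, 40.0)], sigma=1.2, background=2.0)
        rec = fit_gaussian2d(frame, (10, 10))
        assert rec["fit_ok"]
        assert rec["y_px"] == pytest.approx(10.0, abs=1e-6)
        assert rec["x_px"] == pytest.approx(10.0, abs=1e-6)

    def test_subpixel_offset_recovered(self):
        frame = gaussian_frame((21, 21), [(10.30, 9.80, 40.0)], sigma=1.2, background=2.0)
        rec = fit_gaussian2d(frame, (10, 10))
        assert rec["fit_ok"]
        assert rec["y_px"] == pytest.approx(10.30, abs=1e-3)
        assert rec["x_px"] == pytest.approx(9.80, abs=1e-3)

    def test_flat_window_fails_cleanly(self):
        rec = fit_gaussian2d(np.full((15, 15), 3.0), (7, 7))
        assert not rec["fit_ok"]

    def test_sigma_out_of_bounds_rejected(self):
        # huge sigma: effectively a tilted plane inside the 7x7 window
        frame = gaussian_frame((21, 21), [(10, 10, 40.0)], sigma=12.0)
        rec = fit_gaussian2d(frame, (10, 10))
        assert not rec["fit_ok"]


def _locs(frame_positions):
    rows = []
    for f, pts in frame_positions.items():
        for x, y in pts:
            rows.append({"frame": f, "x_px": x, "y_px": y})
    return pd.DataFrame(rows)


class TestDriftEstimation:
    def _static_cloud(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(5, 27, size=(n, 2))

    def test_identical_blocks_zero_shift(self):
        pts = self._static_cloud()
        frames = {f: [(x, y) for x, y in pts] for f in range(0, 200, 5)}
        trace = estimate_drift_fft(_locs(frames), shape=(32, 32), block_size=100)
        assert np.allclose(trace.dx_px, 0.0, atol=0.05)
        assert np.allclose(trace.dy_px, 0.0, atol=0.05)

    def test_constructed_two_pixel_shift_recovered(self):
        pts = self._static_cloud()
        frames = {}
        for f in range(0, 100, 2):
            frames[f] = [(x, y) for x, y in pts]
        for f in range(100, 200, 2):
            frames[f] = [(x + 2.0, y + 1.0) for x, y in pts]
        trace = estimate_drift_fft(_locs(frames), shape=(40, 40), block_size=100)
        assert trace.dx_px[-1] == pytest.approx(2.0, abs=0.1)
        assert trace.dy_px[-1] == pytest.approx(1.0, abs=0.1)

    def test_empty_block_carries_previous_shift(self):
        pts = self._static_cloud()
        frames = {f: [(x, y) for x, y in pts] for f in range(0, 100, 2)}
        frames[299] = [(x, y) for x, y in pts]  # leaves block 1 empty
        with pytest.warns(UserWarning, match="empty drift block"):
            trace = estimate_drift_fft(_locs(frames), shape=(32, 32), block_size=100)
        assert trace.dx_px[1] == trace.dx_px[0]

    def test_linear_drift_in_simulated_movie_recovered(self):
        """Movie with 0.05 px/frame injected drift: slope within 20%.

        Cross-correlation needs shared structure between blocks, so the
        movie contains fiducial-style persistent emitters on a jittered
        grid; the field is widened so 22 px of total drift stays in frame.
        """
        from sptq.simulate import GroundTruth, Emitter
        from sptq import CellGeometry

        cfg = SimulationConfig(
            states=((1.0, 0.0),), n_frames=440, seed=30, photons_per_frame=800,
            background_photons_per_pixel=3,
        )
        rng = np.random.default_rng(31)
        pts = [
            np.array([x, y]) + rng.uniform(-0.06, 0.06, 2)
            for x in -1.6 + 0.85 * np.arange(5)
            for y in (-0.28, 0.28)
        ]
        frames = np.arange(cfg.n_frames)
        emitters = [
            Emitter(
                emitter_id=i, state=0, frames=frames,
                xy=np.tile(p, (cfg.n_frames, 1)),
                activation_frame=0, bleach_frame=cfg.n_frames,
            )
            for i, p in enumerate(pts)
        ]
        truth = GroundTruth(emitters=emitters, config=cfg, geometry=CellGeometry())
        stack = render_movie(truth, cfg, shape=(14, 50), drift_px_per_frame=(0.05, 0.0))
        table, _ = localize_stack(stack, correct_drift=False)
        trace = estimate_drift_fft(table, stack.frames.shape[1:], block_size=110)
        span = trace.block_centers[-1] - trace.block_centers[0]
        expected = 0.05 * span
        assert trace.dx_px[-1] == pytest.approx(expected, rel=0.2)
        assert abs(trace.dy_px[-1]) < 0.2 * expected

        corrected = apply_drift_correction(table, trace, stack.pixel_size)
        # correcting twice is idempotent: residual drift below 0.1 px
        trace2 = estimate_drift_fft(corrected, stack.frames.shape[1:], block_size=110)
        assert np.max(np.abs(trace2.dx_px)) <= 0.1 + 0.02 * expected


class TestLocalizeStack:
    def test_empty_stack_gives_empty_table(self):
        from sptq.simulate import ImageStack

        stack = ImageStack(
            frames=np.zeros((10, 16, 16), dtype=np.uint16),
            pixel_size=0.173,
            frame_interval=0.00576,
            is_activation=np.zeros(10, dtype=bool),
        )
        table, image = localize_stack(stack)
        assert len(table) == 0

    def test_descriptor_mismatch_raises(self):
        from sptq.simulate import ImageStack

        with pytest.raises(ValueError, match="descriptor"):
            stack = ImageStack(
                frames=np.zeros((10, 16, 16), dtype=np.uint16),
                pixel_size=0.173,
                frame_interval=0.00576,
                is_activation=np.zeros(8, dtype=bool),
            )
            localize_stack(stack)

    def test_precision_improves_with_photons(self):
        """Localization scatter shrinks monotonically over 3 photon levels
        and stays within 2x the sqrt(N) shot-noise scaling."""
        scatters = {}
        for photons in (200, 800, 3200):
            cfg = SimulationConfig(
                states=((1.0, 0.0),), n_frames=220, seed=31, photons_per_frame=photons,
                background_photons_per_pixel=2, mean_activations_per_pulse=0.0,
            )
            truth = simulate_trajectories(cfg)
            # a single static emitter at a fixed position
            from sptq.simulate import Emitter

            frames = np.arange(1, 220)
            frames = frames[~cfg.frame_kind()[frames]]
            truth.emitters = [
                Emitter(0, 0, 0, 220, frames, np.tile([[0.31, 0.17]], (len(frames), 1)))
            ]
            stack = render_movie(truth, cfg)
            table, _ = localize_stack(stack, correct_drift=False)
            assert len(table) > 50
            scatters[photons] = np.hypot(
                table["x_px"].std(), table["y_px"].std()
            )
        assert scatters[200] > scatters[800] > scatters[3200]
        sigma_px = 0.13 / 0.173
        bound = 2 * sigma_px / np.sqrt(800)
        assert scatters[800] <= 2 * bound * np.sqrt(2)  # per-axis bound, 2 axes
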