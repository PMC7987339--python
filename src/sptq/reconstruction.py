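"""Super-resolution reconstruction: spot detection, Gaussian fitting, drift.

Per frame, candidate emitters are pixels above a robust intensity threshold
(frame mean + 3·s.d. by default) that are maximal within their centred
5×5 neighbourhood; each candidate is refined by least-squares fitting of a
symmetric 2D Gaussian plus constant offset to the surrounding 7×7 window.
Slow lateral stage drift is estimated by Fourier cross-correlation of
temporally blocked reconstructions and subtracted from all positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

LOC_COLUMNS = [
    "frame",
    "x_px",
    "y_px",
    "x_um",
    "y_um",
    "photons",
    "sigma_um",
    "background",
    "fit_ok",
]

#: acceptable fitted PSF widths, in pixels; outside → fit counted as failed
SIGMA_BOUNDS_PX = (0.5, 3.5)


def detect_candidates(
    frame: np.ndarray, n_sigma: float = 3.0, use_mean_baseline: bool = True
) -> list[tuple[int, int]]:
    """Find candidate peak pixels in one frame.

    A pixel qualifies when it is (a) strictly above the threshold
    mean + ``n_sigma``·s.d. of the frame's pixel intensities (pure
    ``n_sigma``·s.d. when ``use_mean_baseline`` is False) and (b) maximal
    within its centred 5×5 neighbourhood, with ties resolved in favour of
    the lexicographically smallest (row, col) pixel so one spot yields one
    candidate.  Pixels closer than 3 px to the border are dropped so the
    7×7 fitting window always fits.

    Returns (row, col) tuples.  A constant frame (zero s.d.) yields no
    candidates.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 7:
        raise ValueError("frame must be 2D and at least 7x7")
    sd = frame.std()
    if sd == 0:
        return []
    thr = (frame.mean() if use_mean_baseline else 0.0) + n_sigma * sd
    local_max = frame >= ndimage.maximum_filter(frame, size=5, mode="nearest")
    cand = np.argwhere((frame > thr) & local_max)
    h, w = frame.shape
    cand = cand[
        (cand[:, 0] >= 3) & (cand[:, 0] < h - 3) & (cand[:, 1] >= 3) & (cand[:, 1] < w - 3)
    ]
    # lexicographic tie-break: suppress equal-valued maxima within 5x5 of a
    # smaller-index candidate
    cand = cand[np.lexsort((cand[:, 1], cand[:, 0]))]
    kept: list[tuple[int, int]] = []
    for r, c in cand:
        dup = any(
            abs(r - kr) <= 2 and abs(c - kc) <= 2 and frame[r, c] == frame[kr, kc]
            for kr, kc in kept
        )
        if not dup:
            kept.append((int(r), int(c)))
    return kept


def _gauss2d(params, yy, xx):
    amp, y0, x0, sigma, offset = params
    return amp * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma**2)) + offset


def fit_gaussian2d(
    frame: np.ndarray, candidate: tuple[int, int], pixel_size: float = 0.173
) -> dict:
    """Least-squares fit of a symmetric 2D Gaussian to the 7×7 window.

    Returns a localization record dict with sub-pixel position (px and µm),
    integrated photon count (2π·amp·σ²), fitted background, and ``fit_ok``.
    The fit counts as failed — never an exception — when the optimizer does
    not converge, the amplitude is non-positive, σ leaves
    ``SIGMA_BOUNDS_PX``, or the centre leaves the window.
    """
    r, c = candidate
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    if r < 3 or c < 3 or r >= h - 3 or c >= w - 3:
        raise ValueError("candidate must be at least 3 px from the border")
    win = frame[r - 3 : r + 4, c - 3 : c + 4]
    yy, xx = np.mgrid[r - 3 : r + 4, c - 3 : c + 4].astype(float)
    offset0 = win.min()
    amp0 = max(win.max() - offset0, 1e-6)
    p0 = np.array([amp0, float(r), float(c), 1.3, offset0])

    fit_ok = True
    try:
        res = optimize.least_squares(
            lambda p: (_gauss2d(p, yy, xx) - win).ravel(),
            p0,
            method="lm",
            max_nfev=400,
        )
        amp, y0, x0, sigma, offset = res.x
        sigma = abs(sigma)
        if not res.success:
            fit_ok = False
    except Exception:
        amp, y0, x0, sigma, offset = p0
        fit_ok = False
    if (
        amp <= 0
        or not (SIGMA_BOUNDS_PX[0] <= sigma <= SIGMA_BOUNDS_PX[1])
        or abs(y0 - r) > 3.5
        or abs(x0 - c) > 3.5
        or not np.isfinite([amp, y0, x0, sigma, offset]).all()
    ):
        fit_ok = False
    return {
        "x_px": float(x0),
        "y_px": float(y0),
        "x_um": float(x0) * pixel_size,
        "y_um": float(y0) * pixel_size,
        "photons": float(2 * np.pi * amp * sigma**2),
        "sigma_um": float(sigma) * pixel_size,
        "background": float(offset),
        "fit_ok": bool(fit_ok),
    }


@dataclass
class DriftTrace:
    """Per-block lateral drift (pixels) and its per-frame interpolation."""

    block_centers: np.ndarray  # frame index of each block centre
    dx_px: np.ndarray  # drift of each block relative to block 0
    dy_px: np.ndarray
    block_size: int

    def __post_init__(self) -> None:
        if self.dx_px[0] != 0 or self.dy_px[0] != 0:
            raise ValueError("first block drift must be (0, 0)")

    def at_frames(self, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of (dx, dy) between block centres."""
        f = np.asarray(frames, dtype=float)
        return (
            np.interp(f, self.block_centers, self.dx_px),
            np.interp(f, self.block_centers, self.dy_px),
        )


def _render_block(
    locs: pd.DataFrame, shape: tuple[int, int], upsample: int
) -> np.ndarray:
    h, w = shape
    img, _, _ = np.histogram2d(
        locs["y_px"],
        locs["x_px"],
        bins=(h * upsample, w * upsample),
        range=((0, h), (0, w)),
    )
    return ndimage.gaussian_filter(img, sigma=upsample)


def estimate_drift_fft(
    locs: pd.DataFrame,
    shape: tuple[int, int],
    block_size: int = 1000,
    upsample: int = 2,
) -> DriftTrace:
    """Estimate lateral drift from blocked localization reconstructions.

    Localizations are grouped into consecutive blocks of ``block_size``
    frames, each block rendered at ``upsample``× on the camera grid, and
    shifted against the first block via the FFT cross-correlation peak with
    sub-pixel interpolation.  An empty block inherits the previous block's
    shift with a warning.
    """
    if len(locs) == 0:
        raise ValueError("no localizations")
    frames = locs["frame"].to_numpy()
    n_blocks = int(frames.max() // block_size) + 1
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks to estimate drift")
    centers, dxs, dys = [], [], []
    ref = None
    prev = (0.0, 0.0)
    for b in range(n_blocks):
        sel = locs[(frames >= b * block_size) & (frames < (b + 1) * block_size)]
        centers.append(b * block_size + block_size / 2)
        if len(sel) == 0:
            warnings.warn(f"empty drift block {b}; carrying previous shift")
            dxs.append(prev[0])
            dys.append(prev[1])
            continue
        img = _render_block(sel, shape, upsample)
        if ref is None:
            ref = img
            dxs.append(0.0)
            dys.append(0.0)
            continue
        shift, _, _ = phase_cross_correlation(ref, img, upsample_factor=50)
        # shift = displacement of img needed to match ref, in upsampled px;
        # drift of the block relative to block 0 is the negative
        dy, dx = -shift[0] / upsample, -shift[1] / upsample
        dxs.append(float(dx))
        dys.append(float(dy))
        prev = (float(dx), float(dy))
    return DriftTrace(
        block_centers=np.array(centers),
        dx_px=np.array(dxs),
        dy_px=np.array(dys),
        block_size=block_size,
    )


def apply_drift_correction(locs: pd.DataFrame, trace: DriftTrace, pixel_size: float):
    """Subtract interpolated drift; returns a corrected copy of the table."""
    out = locs.copy()
    dx, dy = trace.at_frames(out["frame"].to_numpy())
    out["x_px"] = out["x_px"] - dx
    out["y_px"] = out["y_px"] - dy
    out["x_um"] = out["x_px"] * pixel_size
    out["y_um"] = out["y_px"] * pixel_size
    return out


def render_image(
    locs: pd.DataFrame, shape: tuple[int, int], upsample: int = 8
) -> np.ndarray:
    """Sum-of-unit-Gaussians rendering of localizations on an upsampled grid."""
    img = _render_block(locs, shape, upsample)
    return img


def localize_stack(
    stack,
    n_sigma: float = 3.0,
    drift_block_size: int = 1000,
    correct_drift: bool = True,
    upsample: int = 8,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Full reconstruction of an :class:`~sptq.simulate.ImageStack`.

    Runs detect → fit on every imaging frame (activation frames are
    skipped), discards failed fits, applies FFT drift correction when the
    movie spans at least two blocks, and renders a super-resolution image
    from the corrected positions.  Returns ``(table, rendered_image)``.
    """
    frames = stack.frames
    is_act = np.asarray(stack.is_activation, dtype=bool)
    if len(is_act) != len(frames):
        raise ValueError("acquisition descriptor does not match stack frame count")
    px = stack.pixel_size
    rows = []
    for f in range(len(frames)):
        if is_act[f]:
            continue
        for cand in detect_candidates(frames[f], n_sigma=n_sigma):
            rec = fit_gaussian2d(frames[f], cand, pixel_size=px)
            if rec["fit_ok"]:
                rec["frame"] = f
                rows.append(rec)
    table = pd.DataFrame(rows, columns=LOC_COLUMNS) if rows else pd.DataFrame(
        columns=LOC_COLUMNS
    )
    shape = frames.shape[1:]
    if correct_drift and len(table) and table["frame"].max() >= drift_block_size:
        trace = estimate_drift_fft(table, shape, block_size=drift_block_size)
        table = apply_drift_correction(table, trace, px)
    image = render_image(table, shape, upsample=upsample) if len(table) else np.zeros(
        (shape[0] * upsample, shape[1] * upsample)
    )
    return table, image
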