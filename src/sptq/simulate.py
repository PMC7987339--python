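"""Ground-truthed synthetic data for every pipeline stage.

Emulates sparse photoactivated-localization movies of a protein diffusing in
a bacterial cell: emitters are activated in pulses (one 405 nm activation
frame followed by ``activation_period`` imaging frames), perform 2D Brownian
motion drawn from a static mixture of diffusive states, bleach with a
geometric lifetime, and are imaged as integrated Gaussian spots with Poisson
photon statistics on a uniform Poisson background.  Decay time courses and
region-mask fixtures are generated from the same seeds.

Every generator is a pure function of its seed: identical configs produce
bit-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import erf

from .geometry import CellGeometry
from .decay import DecaySeries
from .spatial import RegionMasks

#: default imaging interval between consecutive frames (s); 174 frames/s
FRAME_INTERVAL_S = 0.00576


@dataclass
class SimulationConfig:
    """Acquisition and motion parameters for the synthetic movie generator.

    ``states`` lists the diffusive mixture as (fraction, D_conv) pairs where
    D_conv is the conventional 2D diffusion coefficient in µm²/s (per-axis
    step variance 2·D_conv·Δt).  The default mixture is a slow
    (RNA-associated) majority at 0.05 µm²/s and a fast (RNA-free) state at
    2.0 µm²/s.
    """

    states: tuple[tuple[float, float], ...] = ((0.4, 2.0), (0.6, 0.05))
    loc_sigma: float = 0.03  # µm, per-axis localization error
    frame_interval: float = FRAME_INTERVAL_S  # s
    exposure: float = 0.0024  # s
    n_frames: int = 13000
    activation_period: int = 10  # imaging frames per activation frame
    mean_activations_per_pulse: float = 2.0
    bleach_mean_frames: float = 20.0
    photons_per_frame: float = 300.0
    background_photons_per_pixel: float = 10.0
    pixel_size: float = 0.173  # µm
    psf_sigma: float = 0.13  # µm
    seed: int = 0
    confined: bool = True
    switching_rate: float = 0.0  # 1/s; 0 = static state membership

    def __post_init__(self) -> None:
        fracs = np.array([f for f, _ in self.states], dtype=float)
        if abs(fracs.sum() - 1.0) > 1e-12:
            raise ValueError("state fractions must sum to 1")
        if np.any(fracs < 0) or any(d < 0 for _, d in self.states):
            raise ValueError("fractions and diffusion coefficients must be >= 0")
        for name in (
            "frame_interval",
            "exposure",
            "pixel_size",
            "psf_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "n_frames",
            "activation_period",
            "mean_activations_per_pulse",
            "bleach_mean_frames",
            "photons_per_frame",
            "background_photons_per_pixel",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.loc_sigma < 0 or self.switching_rate < 0:
            raise ValueError("loc_sigma and switching_rate must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        d["states"] = tuple(tuple(s) for s in d["states"])
        return cls(**d)

    def frame_kind(self) -> np.ndarray:
        """Boolean array over frames; True where the frame is a 405 nm
        activation frame (one per ``activation_period`` imaging frames)."""
        idx = np.arange(self.n_frames)
        return idx % (self.activation_period + 1) == 0


@dataclass
class Emitter:
    """Ground-truth record of one emitter: state, lifetime and positions."""

    emitter_id: int
    state: int
    activation_frame: int
    bleach_frame: int  # first frame at which the emitter is dark again
    frames: np.ndarray  # frame indices while fluorescent
    xy: np.ndarray  # (len(frames), 2) true positions, µm


@dataclass
class GroundTruth:
    """Truth channel for recovery tests: every emitter's path and state."""

    emitters: list[Emitter]
    config: SimulationConfig
    geometry: CellGeometry

    def to_table(self, observed: bool = False) -> pd.DataFrame:
        """Long-format table (emitter_id, frame, x_um, y_um, state).

        With ``observed=True`` positions carry i.i.d. Gaussian localization
        error of s.d. ``config.loc_sigma`` per axis (seeded independently of
        the motion noise).
        """
        rows = []
        for e in self.emitters:
            rows.append(
                pd.DataFrame(
                    {
                        "emitter_id": e.emitter_id,
                        "frame": e.frames,
                        "x_um": e.xy[:, 0],
                        "y_um": e.xy[:, 1],
                        "state": e.state,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["emitter_id", "frame", "x_um", "y_um", "state"]
            )
        table = pd.concat(rows, ignore_index=True)
        if observed and self.config.loc_sigma > 0:
            rng = np.random.default_rng((self.config.seed, 0xB10B))
            table[["x_um", "y_um"]] += rng.normal(
                0.0, self.config.loc_sigma, size=(len(table), 2)
            )
        return table.sort_values(["frame", "emitter_id"], ignore_index=True)


@dataclass
class ImageStack:
    """Rendered movie plus its acquisition descriptor."""

    frames: np.ndarray  # (n_frames, H, W) photon counts
    pixel_size: float  # µm
    frame_interval: float  # s
    is_activation: np.ndarray  # bool per frame

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def descriptor(self) -> dict:
        return {
            "n_frames": int(self.n_frames),
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "activation_frames": np.flatnonzero(self.is_activation).tolist(),
        }


def simulate_trajectories(
    config: SimulationConfig, geometry: CellGeometry | None = None
) -> GroundTruth:
    """Simulate photoactivated emitters diffusing in (or out of) a cell.

    Motion is 2D Brownian with per-axis step variance 2·D_conv·Δt, confined
    by specular reflection at the spherocylinder boundary (``confined=True``)
    or free (unconfined variant for closed-form checks).  State membership
    is static per emitter unless ``switching_rate`` > 0, in which case
    states are redrawn from the mixture at exponential waiting times.
    """
    geometry = geometry or CellGeometry()
    dt = config.frame_interval
    if config.confined:
        max_sigma = max(np.sqrt(2 * d * dt) for _, d in config.states)
        if max_sigma > geometry.width / 4:
            raise ValueError("temporal resolution too coarse for confinement")

    rng = np.random.default_rng(config.seed)
    fracs = np.array([f for f, _ in config.states])
    dvals = np.array([d for _, d in config.states])
    is_act = config.frame_kind()
    act_frames = np.flatnonzero(is_act)

    emitters: list[Emitter] = []
    eid = 0
    p_switch = (
        1.0 - np.exp(-config.switching_rate * dt) if config.switching_rate > 0 else 0.0
    )
    for af in act_frames:
        n_new = rng.poisson(config.mean_activations_per_pulse)
        for _ in range(n_new):
            state = int(rng.choice(len(fracs), p=fracs))
            lifetime = rng.geometric(1.0 / config.bleach_mean_frames)
            first = af + 1
            last = min(first + lifetime, config.n_frames)  # exclusive
            if first >= config.n_frames:
                continue
            frames = np.arange(first, last)
            pos = np.empty((len(frames), 2))
            if config.confined:
                pos[0] = geometry.sample_uniform(1, rng)[0]
            else:
                pos[0] = rng.normal(0.0, geometry.width, size=2)
            states = np.full(len(frames), state)
            for i in range(1, len(frames)):
                if p_switch and rng.random() < p_switch:
                    states[i:] = int(rng.choice(len(fracs), p=fracs))
                d = dvals[states[i]]
                step = rng.normal(0.0, np.sqrt(2 * d * dt), size=2)
                nxt = pos[i - 1] + step
                pos[i] = geometry.reflect(nxt[None, :])[0] if config.confined else nxt
            emitters.append(
                Emitter(
                    emitter_id=eid,
                    state=state,
                    activation_frame=int(af),
                    bleach_frame=int(last),
                    frames=frames,
                    xy=pos,
                )
            )
            eid += 1
    return GroundTruth(emitters=emitters, config=config, geometry=geometry)


def _integrated_gaussian(
    xy_px: np.ndarray, photons: float, sigma_px: float, shape: tuple[int, int]
) -> np.ndarray:
    """Photon counts of one emitter integrated over each pixel (erf model)."""
    h, w = shape
    img = np.zeros(shape)
    cx, cy = xy_px  # column (x), row (y)
    # render a local window only, ±6 sigma
    r = int(np.ceil(6 * sigma_px)) + 1
    r0, r1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    c0, c1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    if r0 >= r1 or c0 >= c1:
        return img
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    s = sigma_px * np.sqrt(2.0)
    fy = 0.5 * (erf((rows + 1 - cy) / s) - erf((rows - cy) / s))
    fx = 0.5 * (erf((cols + 1 - cx) / s) - erf((cols - cx) / s))
    img[r0:r1, c0:c1] = photons * np.outer(fy, fx)
    return img


def render_movie(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    shape: tuple[int, int] | None = None,
    origin_um: tuple[float, float] | None = None,
    drift_px_per_frame: tuple[float, float] = (0.0, 0.0),
) -> ImageStack:
    """Render ground-truth emitters into a noisy photon-count movie.

    Each fluorescent emitter contributes an integrated symmetric Gaussian
    (``psf_sigma``) of ``photons_per_frame`` expected photons; pixel values
    are Poisson draws of signal plus ``background_photons_per_pixel``.
    Activation frames contain background only (the camera records no useful
    signal during the 405 nm pulse).  ``drift_px_per_frame`` applies a
    linear stage drift (x, y) to every emitter, for drift-correction tests.
    """
    config = config or truth.config
    geom = truth.geometry
    px = config.pixel_size
    if origin_um is None:
        # place the cell with a 4-pixel margin
        origin_um = (-geom.length / 2 - 4 * px, -geom.width / 2 - 4 * px)
    if shape is None:
        h = int(np.ceil(geom.width / px)) + 8
        w = int(np.ceil(geom.length / px)) + 8
        shape = (h, w)

    by_frame: dict[int, list[np.ndarray]] = {}
    for e in truth.emitters:
        for f, xy in zip(e.frames, e.xy):
            by_frame.setdefault(int(f), []).append(xy)

    # overlap diagnostic: warn when emitters crowd within the PSF footprint
    dens_warned = False
    for f, pts in by_frame.items():
        if len(pts) >= 2 and not dens_warned:
            arr = np.array(pts)
            dmat = np.linalg.norm(arr[:, None] - arr[None, :], axis=-1)
            np.fill_diagonal(dmat, np.inf)
            if dmat.min(axis=1).mean() < 4 * config.psf_sigma:
                warnings.warn("overlapping emitters; localization accuracy not guaranteed")
                dens_warned = True

    rng = np.random.default_rng((config.seed, 0x1A6E))
    is_act = config.frame_kind()[: config.n_frames]
    sigma_px = config.psf_sigma / px
    frames = np.empty((config.n_frames, *shape), dtype=np.uint16)
    bg = config.background_photons_per_pixel
    for f in range(config.n_frames):
        expected = np.full(shape, bg, dtype=float)
        if not is_act[f]:
            for xy in by_frame.get(f, []):
                cx = (xy[0] - origin_um[0]) / px + drift_px_per_frame[0] * f
                cy = (xy[1] - origin_um[1]) / px + drift_px_per_frame[1] * f
                expected += _integrated_gaussian(
                    (cx, cy), config.photons_per_frame, sigma_px, shape
                )
        frames[f] = rng.poisson(expected).astype(np.uint16)
    return ImageStack(
        frames=frames,
        pixel_size=px,
        frame_interval=config.frame_interval,
        is_activation=is_act,
    )


def simulate_decay_series(
    i0: float,
    alpha: float,
    k: float,
    timepoints,
    noise_cv: float = 0.0,
    seed: int = 0,
    replicate: str = "r1",
    condition: str = "",
) -> DecaySeries:
    """Generate a delayed-exponential intensity time course.

    I(t) = i0 for t <= alpha and i0·exp(-k(t-alpha)) beyond, multiplied by
    mean-one lognormal noise of coefficient of variation ``noise_cv``.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0:
        raise ValueError("empty timepoints")
    if k < 0 or alpha < 0:
        raise ValueError("k and alpha must be non-negative")
    ideal = np.where(t <= alpha, i0, i0 * np.exp(-k * np.maximum(t - alpha, 0.0)))
    if noise_cv > 0:
        rng = np.random.default_rng((seed, 0xDECA))
        s2 = np.log(1.0 + noise_cv**2)
        noise = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=t.shape)
        ideal = ideal * noise
    return DecaySeries(t_min=t, intensity=ideal, replicate=replicate, condition=condition)


def make_region_masks(
    geometry: CellGeometry, pixel_size: float, shape: tuple[int, int]
) -> RegionMasks:
    """Rasterize the geometry into a membrane/nucleoid/cytoplasm partition.

    The cell is centred in the field; the membrane band is the outer ring of
    ``round(membrane_band / pixel_size)`` pixels (at least one, with a
    warning if the requested band is thinner).  Masks index as (row, col)
    with x mapping to columns: a point (x, y) µm lies in pixel
    (floor(y/px), floor(x/px)) after shifting the cell centre to the field
    centre — use :func:`cell_frame_to_mask_frame` for that shift.
    """
    h, w = shape
    if geometry.length > w * pixel_size or geometry.width > h * pixel_size:
        raise ValueError("geometry does not fit in the requested mask shape")
    # pixel centres in cell coordinates (cell centred in the field)
    xs = (np.arange(w) + 0.5) * pixel_size - w * pixel_size / 2
    ys = (np.arange(h) + 0.5) * pixel_size - h * pixel_size / 2
    xx, yy = np.meshgrid(xs, ys)
    pts = np.stack([xx, yy], axis=-1)
    cell = geometry.contains(pts)

    band_px = int(round(geometry.membrane_band / pixel_size))
    if band_px < 1:
        warnings.warn("membrane band thinner than one pixel; widened to 1 px")
        band_px = 1
    from scipy import ndimage

    interior = ndimage.binary_erosion(
        cell, structure=np.ones((3, 3), bool), iterations=band_px
    )
    membrane = cell & ~interior
    nucleoid = geometry.in_nucleoid(pts) & interior
    cytoplasm = cell & ~membrane & ~nucleoid
    return RegionMasks(
        cell=cell,
        nucleoid=nucleoid,
        membrane=membrane,
        cytoplasm=cytoplasm,
        pixel_size=pixel_size,
    )


def cell_frame_to_mask_frame(
    xy_um: np.ndarray, pixel_size: float, shape: tuple[int, int]
) -> np.ndarray:
    """Shift cell-centred coordinates (µm) into the mask's corner-origin frame."""
    xy = np.asarray(xy_um, dtype=float).copy()
    h, w = shape
    xy[..., 0] += w * pixel_size / 2
    xy[..., 1] += h * pixel_size / 2
    return xy
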