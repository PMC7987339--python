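"""Frame-to-frame linking of localizations into diffusion trajectories.

Linking is greedy mutual-nearest-neighbour between consecutive frames with a
hard one-step displacement cutoff (default 0.400 µm at the ~5.76 ms frame
interval) that suppresses artificial links between different molecules.
Trajectories never span an activation-frame gap: only localizations in
frames differing by exactly one are ever linked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: empirical one-step displacement cutoff (µm)
DEFAULT_MAX_DISP = 0.400


@dataclass
class Trajectory:
    """Time-ordered path of one linked emitter."""

    traj_id: int
    frames: np.ndarray  # strictly increasing by 1
    xy: np.ndarray  # (n, 2) in µm
    cell_id: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and positions length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("trajectory frames must increase by exactly 1")

    @property
    def n_steps(self) -> int:
        return len(self.frames) - 1

    @property
    def displacements(self) -> np.ndarray:
        """One-step displacement lengths (µm)."""
        return np.linalg.norm(np.diff(self.xy, axis=0), axis=1)


def _mutual_nn_links(a: np.ndarray, b: np.ndarray, max_disp: float):
    """Indices (i, j) of mutual nearest neighbours with distance <= max_disp."""
    if len(a) == 0 or len(b) == 0:
        return []
    tb = cKDTree(b)
    d_ab, j_ab = tb.query(a)
    ta = cKDTree(a)
    _, i_ba = ta.query(b)
    links = []
    for i, (d, j) in enumerate(zip(d_ab, j_ab)):
        if d <= max_disp and i_ba[j] == i:
            links.append((i, int(j)))
    return links


def link_localizations(
    table: pd.DataFrame, max_disp: float = DEFAULT_MAX_DISP
) -> list[Trajectory]:
    """Link a localization table into trajectories.

    Mutual nearest neighbours between consecutive frames are linked when
    their distance does not exceed ``max_disp``; everything else starts a
    new trajectory.  Warns when the within-frame density makes ambiguous
    links likely (mean nearest-neighbour spacing below ``max_disp``).
    """
    if len(table) == 0:
        return []
    if "fit_ok" in table.columns:
        table = table[table["fit_ok"]]
    table = table.sort_values("frame")
    frames = sorted(table["frame"].unique())
    by_frame = {
        f: g[["x_um", "y_um"]].to_numpy() for f, g in table.groupby("frame")
    }

    nn_dists = [
        np.min(np.linalg.norm(p[:, None] - p[None, :], axis=-1) + np.eye(len(p)) * 1e9)
        for p in by_frame.values()
        if len(p) > 1
    ]
    if nn_dists and np.mean(nn_dists) < max_disp:
        warnings.warn("linking ambiguity likely: emitter density high for max_disp")

    # active trajectories in the previous frame: localization index -> record
    trajs: list[dict] = []
    active: dict[int, int] = {}
    prev_frame = None
    for f in frames:
        pts = by_frame[f]
        new_active: dict[int, int] = {}
        if prev_frame is not None and f == prev_frame + 1:
            links = _mutual_nn_links(by_frame[prev_frame], pts, max_disp)
            for i, j in links:
                if i in active:
                    t = trajs[active[i]]
                    t["frames"].append(f)
                    t["xy"].append(pts[j])
                    new_active[j] = active[i]
        for j in range(len(pts)):
            if j not in new_active:
                trajs.append({"frames": [f], "xy": [pts[j]]})
                new_active[j] = len(trajs) - 1
        active = new_active
        prev_frame = f
    return [
        Trajectory(traj_id=i, frames=np.array(t["frames"]), xy=np.array(t["xy"]))
        for i, t in enumerate(trajs)
    ]


def filter_trajectories(trajs: list[Trajectory], min_steps: int = 5) -> list[Trajectory]:
    """Keep trajectories strictly longer than ``min_steps`` steps.

    "Longer than N time steps" is read strictly: a trajectory with exactly
    ``min_steps`` steps is removed.  Defaults: 5 for MSD-based diffusion
    estimates, 3 for one-step-displacement analyses.
    """
    if min_steps < 1:
        raise ValueError("min_steps must be >= 1")
    return [t for t in trajs if t.n_steps > min_steps]


def steps_table(trajs: list[Trajectory], frame_interval: float) -> pd.DataFrame:
    """One-step displacement table (osd, osd², midpoint) for all trajectories."""
    rows = []
    for t in trajs:
        if t.n_steps == 0:
            continue
        d = t.displacements
        mid = 0.5 * (t.xy[1:] + t.xy[:-1])
        rows.append(
            pd.DataFrame(
                {
                    "traj_id": t.traj_id,
                    "frame": t.frames[:-1],
                    "osd_um": d,
                    "osd2_um2": d**2,
                    "x_mid": mid[:, 0],
                    "y_mid": mid[:, 1],
                    "dt_s": frame_interval,
                }
            )
        )
    cols = ["traj_id", "frame", "osd_um", "osd2_um2", "x_mid", "y_mid", "dt_s"]
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)


def calibrate_linking_radius(
    fixed_table: pd.DataFrame, quantile: float = 0.999
) -> dict:
    """Recommend a linking radius from a fixed (immobilized) sample.

    Apparent one-step displacements of immobile emitters are pure
    localization noise (Rayleigh with scale σ√2 for per-axis error σ); the
    recommended ``max_disp`` is a high quantile of that distribution.
    Returns the recommendation alongside the 0.400 µm field default.
    """
    trajs = link_localizations(fixed_table, max_disp=np.inf)
    disps = np.concatenate([t.displacements for t in trajs if t.n_steps > 0] or [[]])
    if len(disps) < 100:
        raise ValueError("insufficient calibration data: need >= 100 steps")
    return {
        "recommended_max_disp_um": float(np.quantile(disps, quantile)),
        "default_max_disp_um": DEFAULT_MAX_DISP,
        "n_steps": int(len(disps)),
        "quantile": quantile,
    }
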