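"""End-to-end orchestration: simulate → localize → track → diffuse → enrich.

A :class:`PipelineConfig` (strict: unknown keys are rejected) drives the full
chain; all randomness flows from the single top-level seed and the report
embeds the fully resolved configuration, so a rerun with the same config is
numerically identical.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .geometry import CellGeometry
from .simulate import SimulationConfig, simulate_trajectories, render_movie, make_region_masks, cell_frame_to_mask_frame
from .reconstruction import localize_stack
from .tracking import link_localizations, filter_trajectories, steps_table
from .diffusion import (
    compute_msd_ensemble,
    fit_msd_linear,
    compute_osd_speed,
    fit_cdf_mixture,
    select_state_number,
)
from .spatial import compute_enrichment


class GeometrySettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    length_um: float = 3.0
    width_um: float = 1.0
    membrane_band_um: float = 0.173
    nucleoid_semi_axes_um: tuple[float, float] = (1.0, 0.3)

    def build(self) -> CellGeometry:
        return CellGeometry(
            length=self.length_um,
            width=self.width_um,
            membrane_band=self.membrane_band_um,
            nucleoid_axes=self.nucleoid_semi_axes_um,
        )


class SimulationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_frames: int = 2200
    states: tuple[tuple[float, float], ...] = ((0.4, 2.0), (0.6, 0.05))
    loc_sigma_um: float = 0.03
    frame_interval_s: float = 0.00576
    photons_per_frame: float = 300.0
    background_photons_per_pixel: float = 10.0
    mean_activations_per_pulse: float = 2.0
    bleach_mean_frames: float = 20.0
    pixel_size_um: float = 0.173
    psf_sigma_um: float = 0.13

    def build(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            states=self.states,
            loc_sigma=self.loc_sigma_um,
            frame_interval=self.frame_interval_s,
            n_frames=self.n_frames,
            photons_per_frame=self.photons_per_frame,
            background_photons_per_pixel=self.background_photons_per_pixel,
            mean_activations_per_pulse=self.mean_activations_per_pulse,
            bleach_mean_frames=self.bleach_mean_frames,
            pixel_size=self.pixel_size_um,
            psf_sigma=self.psf_sigma_um,
            seed=seed,
        )


class AnalysisSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_disp_um: float = 0.400
    min_steps_msd: int = 5
    min_steps_osd: int = 3
    msd_max_lag: int = 10
    msd_fit_lags: int = 4
    n_states: int | None = None  # None → automatic selection


class PipelineConfig(BaseModel):
    """Resolved configuration of one pipeline run (strict keys)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    render_movie: bool = False
    output_dir: str | None = None
    geometry: GeometrySettings = GeometrySettings()
    simulation: SimulationSettings = SimulationSettings()
    analysis: AnalysisSettings = AnalysisSettings()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured chain and return a machine-readable report.

    Stages: simulate ground-truth motion; either use ground-truth-with-noise
    localizations directly or render + re-localize a movie
    (``render_movie=True``); link and filter; MSD fit; osd² mixture fit;
    region enrichment against the rasterized geometry.  Any stage failure
    raises with the stage name in the message.
    """
    report: dict = {
        "config": json.loads(config.model_dump_json()),
        "versions": {"sptq": __version__, "python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    geometry = config.geometry.build()
    sim = config.simulation.build(config.seed)

    def stage(name, fn, *a, **k):
        try:
            return fn(*a, **k)
        except Exception as e:  # re-raise with stage label
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    truth = stage("simulate", simulate_trajectories, sim, geometry)
    if config.render_movie:
        stack = stage("render", render_movie, truth, sim)
        locs, _ = stage("localize", localize_stack, stack)
        # localized coordinates live in the movie's corner-origin frame
        origin_shift = None
    else:
        locs = truth.to_table(observed=True).rename(columns={"emitter_id": "loc_id"})
        origin_shift = "cell"
    report["n_localizations"] = int(len(locs))

    trajs = stage("track", link_localizations, locs, config.analysis.max_disp_um)
    trajs_msd = filter_trajectories(trajs, config.analysis.min_steps_msd)
    trajs_osd = filter_trajectories(trajs, config.analysis.min_steps_osd)
    report["n_trajectories"] = len(trajs)
    report["n_trajectories_msd"] = len(trajs_msd)

    curve = stage(
        "msd",
        compute_msd_ensemble,
        trajs_msd,
        config.analysis.msd_max_lag,
        sim.frame_interval,
    )
    msd_fit = fit_msd_linear(curve, config.analysis.msd_fit_lags)
    report["msd"] = {
        "d_paper_um2_s": msd_fit.d_paper,
        "d_conv_um2_s": msd_fit.d_conv,
        "n_lags": msd_fit.n_lags,
    }

    steps = compute_osd_speed(steps_table(trajs_osd, sim.frame_interval))
    osd2 = steps["osd2_um2"].to_numpy()
    if len(osd2) >= 500:
        if config.analysis.n_states is None:
            n_sel, fits = stage("mixture", select_state_number, osd2, sim.frame_interval)
            fit = fits[n_sel]
        else:
            fit = stage(
                "mixture", fit_cdf_mixture, osd2, config.analysis.n_states, sim.frame_interval
            )
            n_sel = fit.n
        report["mixture"] = {
            "n_states": n_sel,
            "fractions": fit.fractions.tolist(),
            "d_prime_um2_s": fit.d_primes.tolist(),
            "d_states_um2_s": fit.d_states.tolist(),
            "rss": fit.rss,
        }
    else:
        report["mixture"] = None

    if origin_shift == "cell":
        px = sim.pixel_size
        h = int(np.ceil(geometry.width / px)) + 8
        w = int(np.ceil(geometry.length / px)) + 8
        masks = stage("masks", make_region_masks, geometry, px, (h, w))
        pts = cell_frame_to_mask_frame(
            locs[["x_um", "y_um"]].to_numpy(), px, (h, w)
        )
        steps_shift = steps.copy()
        shifted = cell_frame_to_mask_frame(
            steps[["x_mid", "y_mid"]].to_numpy(), px, (h, w)
        )
        steps_shift[["x_mid", "y_mid"]] = shifted
        enr = stage("enrich", compute_enrichment, pts, masks, steps_shift)
        report["enrichment"] = {
            "enrichment": enr.enrichment,
            "counts": enr.counts,
            "mean_osd_speed_um_s": enr.mean_osd_speed,
        }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
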