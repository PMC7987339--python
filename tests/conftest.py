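import numpy as np
import pytest

from sptq import CellGeometry, SimulationConfig, simulate_trajectories


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry()


@pytest.fixture(scope="session")
def two_state_truth():
    """Confined two-state simulation reused across tracking/diffusion tests."""
    cfg = SimulationConfig(n_frames=2200, seed=101)
    return simulate_trajectories(cfg, CellGeometry())


def unconfined_config(d_conv: float, seed: int, n_frames: int = 40000, loc_sigma: float = 0.0):
    """Single-state free-diffusion config for closed-form checks."""
    return SimulationConfig(
        states=((1.0, d_conv),),
        n_frames=n_frames,
        seed=seed,
        confined=False,
        loc_sigma=loc_sigma,
        mean_activations_per_pulse=3.0,
        bleach_mean_frames=30.0,
    )


def all_steps_sq(truth) -> np.ndarray:
    """Squared one-step displacements of every ground-truth emitter."""
    out = [
        np.sum(np.diff(e.xy, axis=0) ** 2, axis=1)
        for e in truth.emitters
        if len(e.xy) > 1
    ]
    return np.concatenate(out) if out else np.array([])
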