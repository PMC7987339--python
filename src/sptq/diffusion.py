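"""Diffusion coefficients and diffusive-state populations.

Two complementary estimators are provided:

* an ensemble mean-squared-displacement (MSD) curve fitted with the
  zero-intercept line MSD = D·Δt, reporting both that slope (``d_paper``)
  and the conventional 2D coefficient D_conv = D/4;

* an n-state mixture fit of the one-step squared displacement (osd²)
  distribution through its cumulative distribution function

      CDF(osd²) = 1 − Σᵢ Pᵢ · exp(−osd² / (4 D′ᵢ t)),

  where t is the interval between consecutive frames.  Each state i is an
  exponential component with mean 4·D′ᵢ·t; the per-state one-step
  coefficients are reported as Dᵢ ≡ 4·D′ᵢ.  States are sorted descending in
  D′ so state 1 is the fast (e.g. RNA-free) population, which can be
  box-constrained from reference fits (mean ± 2·s.d. across replicates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .tracking import Trajectory


@dataclass
class MSDCurve:
    """Ensemble MSD versus time lag."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD must be non-negative")


@dataclass
class DiffusionFit:
    """Zero-intercept linear MSD fit.

    ``d_paper`` is the raw slope of MSD vs Δt; the conventional 2D
    diffusion coefficient is ``d_conv = d_paper / 4`` exactly.
    """

    d_paper: float  # µm²/s, slope of MSD = D·Δt
    n_lags: int
    residual_norm: float
    clamped: bool = False

    @property
    def d_conv(self) -> float:
        return self.d_paper / 4.0


@dataclass
class MixtureFit:
    """Fitted n-state osd² mixture (fractions and one-step coefficients)."""

    n: int
    fractions: np.ndarray  # P_i, descending-D' order, sums to 1
    d_primes: np.ndarray  # D'_i, µm²/s, descending
    t: float  # s
    rss: float
    d1_constraint: tuple[float, float] | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.d_primes = np.asarray(self.d_primes, dtype=float)
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if np.any(self.d_primes <= 0):
            raise ValueError("D' must be positive")
        if np.any(np.diff(self.d_primes) > 0):
            raise ValueError("states must be sorted descending by D'")

    @property
    def d_states(self) -> np.ndarray:
        """One-step diffusion coefficients D_i = 4·D'_i."""
        return 4.0 * self.d_primes

    def cdf(self, osd2: np.ndarray) -> np.ndarray:
        x = np.asarray(osd2, dtype=float)
        return 1.0 - np.sum(
            self.fractions[:, None] * np.exp(-x[None, :] / (4 * self.d_primes[:, None] * self.t)),
            axis=0,
        )


def compute_msd_ensemble(
    trajs: list[Trajectory], max_lag: int = 10, frame_interval: float = 1.0
) -> MSDCurve:
    """Ensemble/time-averaged MSD over all trajectories and start points.

    MSD(m·Δt₀) averages |r(t + m·Δt₀) − r(t)|² over every valid start point
    of every trajectory, for lags m = 1…max_lag (in seconds when
    ``frame_interval`` is given, otherwise in frames).  Lags with no pairs
    are truncated with a warning.
    """
    if not trajs:
        raise ValueError("no trajectories")
    dt = None
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for t in trajs:
        n = len(t.xy)
        for m in range(1, min(max_lag, n - 1) + 1):
            d = t.xy[m:] - t.xy[:-m]
            sums[m - 1] += np.sum(d[:, 0] ** 2 + d[:, 1] ** 2)
            counts[m - 1] += len(d)
    valid = counts > 0
    if not valid.all():
        warnings.warn("some lags had no displacement pairs; curve truncated")
    last = int(np.max(np.flatnonzero(valid))) + 1 if valid.any() else 0
    if last == 0:
        raise ValueError("no displacement pairs at any lag")
    return MSDCurve(
        lags_s=np.arange(1, last + 1) * frame_interval,
        msd_um2=sums[:last] / np.maximum(counts[:last], 1),
        n_pairs=counts[:last],
    )


def fit_msd_linear(curve: MSDCurve, n_lags: int = 4) -> DiffusionFit:
    """Zero-intercept least-squares line MSD = D·Δt over the first lags.

    A numerically negative slope is clamped to 0 and flagged.
    """
    if n_lags < 2:
        raise ValueError("need at least 2 lags")
    n = min(n_lags, len(curve.lags_s))
    t = curve.lags_s[:n]
    y = curve.msd_um2[:n]
    slope = float(t @ y / (t @ t))
    clamped = slope < 0
    if clamped:
        slope = 0.0
    resid = y - slope * t
    return DiffusionFit(
        d_paper=slope,
        n_lags=n,
        residual_norm=float(np.linalg.norm(resid)),
        clamped=clamped,
    )


def compute_osd_speed(steps) -> "pd.DataFrame":
    """Attach osd speed = osd/Δt₀ (µm/s) to each step record.

    Requires a uniform frame interval across steps; the speed sits at the
    step's midpoint, which is what region-resolved speed maps use.
    """
    import pandas as pd

    steps = steps.copy()
    dt = steps["dt_s"].to_numpy()
    if len(steps) == 0:
        steps["speed_um_s"] = pd.Series(dtype=float)
        return steps
    if not np.allclose(dt, dt[0]):
        raise ValueError("mixed frame intervals; osd speed requires uniform dt")
    steps["speed_um_s"] = steps["osd_um"] / dt
    return steps


# ---------------------------------------------------------------------------
# osd² mixture fitting


def _unpack(theta: np.ndarray, n: int):
    """Map free parameters to (fractions, d_primes) with Σ P = 1.

    Fractions use a stick-breaking parametrization (each v_i in [0, 1]) so
    the simplex constraint holds for any box-bounded theta; D' are fitted in
    log space.
    """
    log_d = theta[:n]
    v = theta[n : 2 * n - 1]
    fracs = np.empty(n)
    rest = 1.0
    for i in range(n - 1):
        fracs[i] = rest * v[i]
        rest -= fracs[i]
    fracs[n - 1] = rest
    return fracs, np.exp(log_d)


def _mixture_cdf(x, fracs, d_primes, t):
    return 1.0 - np.sum(
        fracs[:, None] * np.exp(-x[None, :] / (4 * d_primes[:, None] * t)), axis=0
    )


def empirical_cdf_grid(osd2: np.ndarray, n_grid: int = 200):
    """Quantile-spaced evaluation grid for the empirical CDF.

    Evaluating on quantiles rather than a uniform x grid keeps the dense
    small-osd² region from dominating the least-squares objective.
    """
    q = (np.arange(1, n_grid + 1) - 0.5) / n_grid
    x = np.quantile(osd2, q)
    return x, q


def fit_cdf_mixture(
    osd2: np.ndarray,
    n: int,
    t: float,
    d1_constraint: tuple[float, float] | None = None,
    n_grid: int = 200,
    n_starts: int = 5,
) -> MixtureFit:
    """Fit the n-state mixture CDF to osd² samples.

    Nonlinear least squares of the model CDF against the empirical CDF on a
    quantile-spaced grid, with multi-start initialization seeded from sample
    quantiles (the objective has local minima when states are close).  With
    ``d1_constraint`` the fast-state D′₁ is box-bounded inside the interval.
    """
    osd2 = np.asarray(osd2, dtype=float)
    if len(osd2) < 500:
        raise ValueError("need at least 500 osd² samples")
    if n not in (1, 2, 3):
        raise ValueError("n must be 1, 2 or 3")
    if t <= 0:
        raise ValueError("t must be positive")
    x, q = empirical_cdf_grid(osd2, n_grid=n_grid)

    mean_d = max(float(osd2.mean()) / (4 * t), 1e-12)

    def residuals(theta):
        fracs, dp = _unpack(theta, n)
        return _mixture_cdf(x, fracs, dp, t) - q

    lo = np.full(2 * n - 1, -np.inf)
    hi = np.full(2 * n - 1, np.inf)
    lo[:n], hi[:n] = np.log(mean_d * 1e-5), np.log(mean_d * 1e5)
    lo[n:], hi[n:] = 1e-6, 1 - 1e-6
    if d1_constraint is not None:
        a, b = d1_constraint
        if not (0 < a <= b):
            raise ValueError("constraint interval must be positive and ordered")
        lo[0], hi[0] = np.log(a), np.log(b) if b > a else np.log(b) + 1e-12
        # keep the remaining states below the constrained fast state so the
        # descending order (and hence which state the box applies to) is fixed
        if n > 1:
            hi[1:n] = np.minimum(hi[1:n], np.log(a))

    rng = np.random.default_rng(12345)  # fixed: starts are deterministic
    starts = []
    # geometric spread of D' guesses around quantile-implied scales
    probe = np.quantile(osd2, np.linspace(0.15, 0.95, n)) / (4 * t)
    probe = np.maximum(probe, mean_d * 1e-4)
    for s in range(n_starts):
        jitter = rng.uniform(-0.5, 0.5, size=n) if s else np.zeros(n)
        log_d = np.log(probe[::-1]) + jitter  # descending D' first
        v = np.full(n - 1, 0.5) + (rng.uniform(-0.2, 0.2, n - 1) if s else 0.0)
        eps = np.minimum(1e-9, (hi - lo) / 4)
        theta0 = np.clip(np.concatenate([log_d, v]), lo + eps, hi - eps)
        starts.append(theta0)

    best = None
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            f"mixture fit failed to converge for n={n} after {n_starts} starts"
        )
    fracs, dp = _unpack(best.x, n)
    order = np.argsort(dp)[::-1]
    fracs, dp = fracs[order], dp[order]
    degenerate = bool(
        n > 1 and np.any(np.abs(np.diff(dp)) / dp[:-1] < 0.10)
    )
    if degenerate:
        warnings.warn("degenerate states: fitted D' values within 10% of each other")
    return MixtureFit(
        n=n,
        fractions=fracs,
        d_primes=dp,
        t=t,
        rss=float(2 * best.cost),
        d1_constraint=d1_constraint,
        degenerate=degenerate,
    )


def select_state_number(
    osd2: np.ndarray,
    t: float,
    improvement_factor: float = 2.0,
    d1_constraint: tuple[float, float] | None = None,
    **kwargs,
) -> tuple[int, dict[int, MixtureFit]]:
    """Choose the number of diffusive states by residual improvement.

    Fits n = 1, 2, 3 and returns the smallest n whose successor fails to
    reduce the residual sum of squares by at least ``improvement_factor``×.
    """
    fits = {m: fit_cdf_mixture(osd2, m, t, d1_constraint=d1_constraint, **kwargs) for m in (1, 2, 3)}
    chosen = 3
    for m in (1, 2):
        if fits[m].rss < improvement_factor * fits[m + 1].rss:
            chosen = m
            break
    return chosen, fits


def constrain_from_reference(reference_fits: list[MixtureFit]) -> tuple[float, float]:
    """Fast-state D′₁ interval from replicate reference fits.

    Returns mean(D′₁) ± 2·sample s.d. across replicates, for use as the
    box constraint in subsequent fits.  A single replicate yields the
    degenerate interval [d, d] with a warning.
    """
    if not reference_fits:
        raise ValueError("no reference fits")
    d1 = np.array([f.d_primes[0] for f in reference_fits])
    if len(d1) == 1:
        warnings.warn("single reference replicate; degenerate constraint interval")
        return (float(d1[0]), float(d1[0]))
    m, s = float(d1.mean()), float(d1.std(ddof=1))
    return (m - 2 * s, m + 2 * s)
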