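"""Piecewise delayed-exponential fitting of mRNA decay time courses.

After transcription is shut off (rifampicin chase), normalized band
intensities typically stay flat for a short delay and then decay
exponentially.  In log space the model is piecewise linear:

    ln I(t) = ln I(0)                 for t <= alpha
    ln I(t) = ln I(0) - k (t - alpha) for t >  alpha

with decay rate k (1/min), delay alpha (min), and half-life
tau = ln(2) / k.  The fit is performed on ln I, which weights late,
low-intensity points as heavily as early ones.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

LN2 = float(np.log(2.0))


@dataclass
class DecaySeries:
    """One normalized intensity time course (single replicate)."""

    t_min: np.ndarray
    intensity: np.ndarray
    replicate: str = "r1"
    condition: str = ""

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t_min.size == 0:
            raise ValueError("empty timepoints")
        if self.t_min.size != self.intensity.size:
            raise ValueError("t and intensity length mismatch")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("timepoints must be strictly ascending")
        if self.t_min[0] != 0:
            raise ValueError("first timepoint must be 0 (normalization anchor)")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")


@dataclass
class DecayFit:
    """Fitted piecewise decay parameters and the derived half-life."""

    k: float  # 1/min
    alpha: float  # min
    ln_i0: float
    residual_norm: float
    replicate: str = "r1"
    condition: str = ""
    no_decay: bool = False

    @property
    def tau(self) -> float:
        """Half-life tau = ln(2)/k (min); inf when no decay was detected."""
        return np.inf if self.k == 0 else LN2 / self.k


def _profile_sse(alpha: float, t: np.ndarray, y: np.ndarray, fix_i0: bool):
    """Best (ln I0, k >= 0) for a given delay alpha, by linear least squares."""
    s = np.maximum(t - alpha, 0.0)
    if fix_i0:
        ss = float(s @ s)
        k = 0.0 if ss == 0 else max(-float(s @ y) / ss, 0.0)
        c = 0.0
    else:
        A = np.column_stack([np.ones_like(t), -s])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        c, k = float(coef[0]), float(coef[1])
        if k < 0:
            k = 0.0
            c = float(y.mean())
    r = y - (c - k * s)
    return float(r @ r), c, k


def fit_piecewise_decay(
    series: DecaySeries,
    alpha_max: float | None = None,
    fix_i0: bool = False,
) -> DecayFit:
    """Fit the delayed-exponential model to one time course.

    The delay alpha is profiled: for each candidate alpha the remaining
    parameters have a closed-form least-squares solution, so the search
    reduces to a 1D minimization (coarse grid + local polish).  alpha is
    bounded by ``alpha_max`` (default: second-to-last timepoint) and k >= 0.

    With ``fix_i0=True`` the plateau is pinned at ln I(0) = 0 after internal
    normalization to the first point; by default ln I(0) is fitted.
    """
    t = series.t_min
    y = np.log(series.intensity)
    if fix_i0:
        y = y - y[0]
    if t.size < 4:
        raise ValueError("need at least 4 timepoints")
    if alpha_max is None:
        alpha_max = float(t[-2])
    if not alpha_max < t[-1]:
        raise ValueError("alpha_max must be below the last timepoint")

    # coarse grid over alpha, then Brent polish on the bracketing interval
    grid = np.linspace(0.0, alpha_max, 513)
    sse = np.array([_profile_sse(a, t, y, fix_i0)[0] for a in grid])
    i = int(np.argmin(sse))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda a: _profile_sse(a, t, y, fix_i0)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        alpha = float(res.x) if res.fun <= sse[i] else float(grid[i])
    else:
        alpha = float(grid[i])
    best_sse, c, k = _profile_sse(alpha, t, y, fix_i0)
    no_decay = k <= 0.0
    if no_decay:
        warnings.warn("no decay detected; k = 0, half-life infinite")
        k, alpha = 0.0, 0.0
    return DecayFit(
        k=k,
        alpha=alpha,
        ln_i0=c if not fix_i0 else float(np.log(series.intensity[0])),
        residual_norm=float(np.sqrt(best_sse)),
        replicate=series.replicate,
        condition=series.condition,
        no_decay=no_decay,
    )


def compare_half_lives(fits_by_condition: dict[str, list[DecayFit]]):
    """Summarize half-lives per condition and compare conditions pairwise.

    Returns ``(summary, pairwise)`` DataFrames.  Per condition: mean and
    sample s.d. of tau over replicates (infinite half-lives are excluded
    from the moments and counted separately).  Pairwise: fold change of
    mean half-lives and two-sample t-test p-value.
    """
    if any(len(v) < 2 for v in fits_by_condition.values()):
        raise ValueError("need at least 2 replicates per condition")
    rows, taus = [], {}
    for cond, fits in fits_by_condition.items():
        finite = np.array([f.tau for f in fits if np.isfinite(f.tau)])
        taus[cond] = finite
        rows.append(
            {
                "condition": cond,
                "n": len(finite),
                "n_no_decay": len(fits) - len(finite),
                "mean_tau_min": float(finite.mean()) if len(finite) else np.nan,
                "sd_tau_min": float(finite.std(ddof=1)) if len(finite) > 1 else np.nan,
            }
        )
    summary = pd.DataFrame(rows)

    pair_rows = []
    for a, b in itertools.combinations(fits_by_condition, 2):
        ta, tb = taus[a], taus[b]
        mean_a = ta.mean() if len(ta) else np.nan
        mean_b = tb.mean() if len(tb) else np.nan
        if len(ta) > 1 and len(tb) > 1:
            p = float(stats.ttest_ind(ta, tb).pvalue)
        else:
            p = np.nan
        pair_rows.append(
            {
                "condition_a": a,
                "condition_b": b,
                "fold_change_b_over_a": float(mean_b / mean_a),
                "p_value": p,
            }
        )
    return summary, pd.DataFrame(pair_rows)


def fits_from_table(table: pd.DataFrame, alpha_max: float | None = None, fix_i0: bool = False):
    """Fit every (condition, replicate) series in a tidy intensity table.

    Expects columns ``condition, replicate, t_min, intensity``.
    """
    out: dict[str, list[DecayFit]] = {}
    for (cond, rep), grp in table.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("t_min")
        series = DecaySeries(
            t_min=grp["t_min"].to_numpy(),
            intensity=grp["intensity"].to_numpy(),
            replicate=str(rep),
            condition=str(cond),
        )
        out.setdefault(str(cond), []).append(fit_piecewise_decay(series, alpha_max, fix_i0))
    return out
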