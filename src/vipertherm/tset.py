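"""Preferred temperature and set-point range from thermal-gradient trials.

The estimator follows the normalized-density workflow: fit a Gaussian kernel
density to an individual's gradient readings, rescale it to a 0-1 range,
evaluate it on a fixed grid from 15 to 45 °C in 0.05 °C steps, and read the
preferred temperature T_p at the peak and the set-point bounds T_set at the
outermost half-maximum crossings.  The half-maximum rule is the primary
method; a central-50% (interquartile) alternative is available via
``method="iqr"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "GRID",
    "DensityCurve",
    "TsetEstimate",
    "normalized_density",
    "extract_tset",
    "estimate_individual",
    "population_tset",
    "estimate_all",
]

#: fixed evaluation grid, 15-45 °C in 0.05 °C steps (601 points)
GRID = np.round(np.linspace(15.0, 45.0, 601), 2)

_MIN_READINGS = 5


@dataclass(frozen=True)
class DensityCurve:
    """Kernel density on the fixed grid, rescaled so max(prob) = 1."""

    grid: np.ndarray
    prob: np.ndarray

    def __post_init__(self):
        if self.grid.shape != self.prob.shape:
            raise ValueError("grid and prob must have equal length")


@dataclass(frozen=True)
class TsetEstimate:
    """Peak temperature and set-point bounds, individual or population level."""

    t_p: float
    t_set_lower: float
    t_set_upper: float
    level: str = "individual"
    n_obs: int = 0
    clipped: bool = False

    def __post_init__(self):
        if not self.t_set_lower <= self.t_p <= self.t_set_upper:
            raise ValueError("requires t_set_lower <= t_p <= t_set_upper")


def _nrd0_bandwidth(x: np.ndarray) -> float:
    """Silverman-type rule of thumb: 0.9 * min(SD, IQR/1.34) * n^(-1/5)."""
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    lo = min(sd, iqr / 1.34) if iqr > 0 else sd
    if lo == 0:
        raise DegenerateInputError("zero-variance series: bandwidth undefined")
    return 0.9 * lo * len(x) ** (-0.2)


def normalized_density(temps) -> DensityCurve:
    """Gaussian-kernel density of gradient readings, rescaled to [0, 1].

    Readings outside the 15-45 °C grid are clipped onto it with a warning.
    Raises ``InsufficientDataError`` below 5 readings and
    ``DegenerateInputError`` for zero-variance input.
    """
    x = np.asarray(temps, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < _MIN_READINGS:
        raise InsufficientDataError(f"need >= {_MIN_READINGS} readings, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("all readings identical")
    if (x < GRID[0]).any() or (x > GRID[-1]).any():
        warnings.warn("readings outside [15, 45] °C clipped to the grid", stacklevel=2)
        x = np.clip(x, GRID[0], GRID[-1])
        if np.ptp(x) == 0:
            raise DegenerateInputError("all readings identical after clipping")
    h = _nrd0_bandwidth(x)
    z = (GRID[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1)  # unnormalized Gaussian KDE
    return DensityCurve(grid=GRID.copy(), prob=dens / dens.max())


def extract_tset(
    curve: DensityCurve, level: str = "individual", n_obs: int = 0
) -> TsetEstimate:
    """Read T_p and the set-point bounds off a normalized density curve.

    T_p is the grid temperature at the (first) maximum; the bounds are the
    smallest and largest grid temperatures with prob >= 0.5.  A curve whose
    half-maximum region touches the grid edge is flagged ``clipped``.
    """
    prob = np.asarray(curve.prob, dtype=float)
    if prob.max() <= 0:
        raise DegenerateInputError("curve has no positive mass")
    peak = int(np.argmax(prob))
    above = np.flatnonzero(prob >= 0.5 * prob.max())
    if above.size == 0:  # unreachable for a valid normalized curve
        raise DegenerateInputError("curve never reaches half maximum")
    lo, hi = int(above[0]), int(above[-1])
    clipped = lo == 0 or hi == len(prob) - 1
    return TsetEstimate(
        t_p=float(curve.grid[peak]),
        t_set_lower=float(curve.grid[lo]),
        t_set_upper=float(curve.grid[hi]),
        level=level,
        n_obs=n_obs,
        clipped=clipped,
    )


def estimate_individual(temps, method: str = "halfmax") -> TsetEstimate:
    """Full individual-level estimate from raw gradient readings."""
    x = np.asarray(temps, dtype=float)
    curve = normalized_density(x)
    est = extract_tset(curve, level="individual", n_obs=x.size)
    if method == "iqr":
        q25, q75 = np.percentile(np.clip(x, GRID[0], GRID[-1]), [25, 75])
        lo = min(float(q25), est.t_p)
        hi = max(float(q75), est.t_p)
        est = TsetEstimate(est.t_p, lo, hi, "individual", x.size, est.clipped)
    elif method != "halfmax":
        raise ValueError(f"unknown method {method!r}")
    return est


def population_tset(trials: pd.DataFrame, method: str = "halfmax") -> TsetEstimate:
    """Pool all gradient readings of one population into a single estimate."""
    temps = trials["temp_c"].to_numpy(dtype=float)
    est = estimate_individual(temps, method=method)
    return TsetEstimate(
        est.t_p, est.t_set_lower, est.t_set_upper, "population", temps.size, est.clipped
    )


def estimate_all(trials: pd.DataFrame, method: str = "halfmax") -> pd.DataFrame:
    """One estimate row per individual plus one per population.

    Input columns: individual_id, population, temp_c.  Output columns:
    unit_id, population, level, t_p, t_set_lower, t_set_upper, n_obs, clipped.
    """
    rows = []
    for ind, grp in trials.groupby("individual_id", sort=True):
        est = estimate_individual(grp["temp_c"].to_numpy(dtype=float), method=method)
        rows.append(
            {
                "unit_id": ind,
                "population": grp["population"].iloc[0],
                "level": "individual",
                "t_p": est.t_p,
                "t_set_lower": est.t_set_lower,
                "t_set_upper": est.t_set_upper,
                "n_obs": est.n_obs,
                "clipped": est.clipped,
            }
        )
    for pop, grp in trials.groupby("population", sort=True):
        est = population_tset(grp, method=method)
        rows.append(
            {
                "unit_id": pop,
                "population": pop,
                "level": "population",
                "t_p": est.t_p,
                "t_set_lower": est.t_set_lower,
                "t_set_upper": est.t_set_upper,
                "n_obs": est.n_obs,
                "clipped": est.clipped,
            }
        )
    return pd.DataFrame(rows)
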