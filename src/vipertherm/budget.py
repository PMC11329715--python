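"""Annual operative-temperature budget and activity-restriction time h_r.

A full biophysical microclimate + ectotherm model is out of scope here;
instead, hourly operative temperature over a 365-day year is synthesized
from the 12 monthly mean air temperatures of an occurrence cell: daily means
are linearly interpolated between month midpoints (wrapping December to
January), a sinusoidal diurnal cycle peaking at 14:00 is superimposed, and a
radiative gain is added to the exposed model during daylight (06:00-20:00).
The restriction time h_r is the number of hours per year the synthesized
operative temperature strictly exceeds the upper set-point bound; warming
offsets enter additively through the monthly means, so h_r responds
monotonically to any uniform warming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import popstats
from .errors import InvalidConfigError, MalformedSeriesError, MissingScenarioError

__all__ = [
    "EctothermParams",
    "HOURS_PER_YEAR",
    "synthesize_hourly_te",
    "restriction_hours",
    "scenario_change_summary",
    "compare_scenarios",
    "latitude_trend",
]

HOURS_PER_YEAR = 8760
DAYS = 365
_MONTH_LEN = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
# mid-month day-of-year (0-based, fractional)
_MONTH_MID = np.cumsum(_MONTH_LEN) - _MONTH_LEN / 2.0 - 0.5

DAYLIGHT_START_H = 6
DAYLIGHT_END_H = 20


@dataclass(frozen=True)
class EctothermParams:
    """Physical stand-in for the operative model animal.

    ``radiative_gain`` is the extra °C the exposed model attains during
    daylight hours; ``diurnal_amplitude`` is the half-range of the daily
    cycle.  Mass and shape document the modelled animal (a 33.5 g cylinder)
    but do not enter the simplified synthesizer.
    """

    mass_g: float = 33.5
    shape: str = "cylinder"
    diurnal: bool = True
    radiative_gain: float = 6.0
    diurnal_amplitude: float = 8.0

    def __post_init__(self):
        if self.mass_g <= 0:
            raise InvalidConfigError("mass_g must be positive")
        if self.radiative_gain < 0 or self.diurnal_amplitude < 0:
            raise InvalidConfigError("amplitudes must be >= 0")


def _daily_means(monthly: np.ndarray) -> np.ndarray:
    """Linear interpolation of 12 monthly means onto 365 days, wrapping the year."""
    doy = np.arange(DAYS, dtype=float)
    # periodic extension for interpolation across the new year
    mids = np.concatenate([[_MONTH_MID[-1] - DAYS], _MONTH_MID, [_MONTH_MID[0] + DAYS]])
    vals = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
    return np.interp(doy, mids, vals)


def synthesize_hourly_te(
    monthly_means, params: EctothermParams = EctothermParams()
) -> np.ndarray:
    """Hourly operative temperature for one cell over a 365-day year (8760 values)."""
    monthly = np.asarray(monthly_means, dtype=float)
    if monthly.shape != (12,):
        raise MissingScenarioError(f"need 12 monthly means, got shape {monthly.shape}")
    daily = _daily_means(monthly)
    hour = np.arange(24, dtype=float)
    cycle = params.diurnal_amplitude * np.sin(2 * np.pi * (hour - 8.0) / 24.0)
    gain = np.where(
        (hour >= DAYLIGHT_START_H) & (hour < DAYLIGHT_END_H), params.radiative_gain, 0.0
    )
    te = daily[:, None] + cycle[None, :] + gain[None, :]
    return te.ravel()


def restriction_hours(hourly_te, t_set_upper: float) -> int:
    """Hours per year the operative temperature strictly exceeds the upper bound."""
    te = np.asarray(hourly_te, dtype=float)
    if te.shape != (HOURS_PER_YEAR,):
        raise MalformedSeriesError(
            f"expected {HOURS_PER_YEAR} hourly values, got {te.size}"
        )
    return int((te > t_set_upper).sum())


def _monthly_cols(df: pd.DataFrame) -> list:
    return [f"m{i:02d}" for i in range(1, 13)]


def scenario_change_summary(
    climate: pd.DataFrame,
    t_set_upper,
    params: EctothermParams = EctothermParams(),
):
    """Per-cell h_r for every scenario plus cross-cell means ± SE and deltas.

    ``climate`` is the long-format grid (cell_id, latitude, scenario, gcm,
    m01..m12); ``t_set_upper`` is a scalar threshold or a mapping
    cell_id -> threshold.  Future SSP values are averaged over their GCMs per
    cell before differencing against the current scenario.

    Returns ``(per_cell, summary)`` DataFrames: per_cell has one row per
    cell x scenario (GCM-averaged) with columns cell_id, latitude, scenario,
    h_r, delta_vs_current; summary has per-scenario mean, se, mean_delta.
    """
    if "current" not in set(climate["scenario"]):
        raise MissingScenarioError("climate table lacks the current scenario")
    cols = _monthly_cols(climate)

    def threshold(cell_id):
        if np.isscalar(t_set_upper) or isinstance(t_set_upper, float):
            return float(t_set_upper)
        return float(t_set_upper[cell_id])

    rows = []
    for (cell, scen, gcm), grp in climate.groupby(
        ["cell_id", "scenario", "gcm"], sort=True
    ):
        monthly = grp[cols].iloc[0].to_numpy(dtype=float)
        te = synthesize_hourly_te(monthly, params)
        rows.append(
            {
                "cell_id": cell,
                "latitude": float(grp["latitude"].iloc[0]),
                "scenario": scen,
                "gcm": gcm,
                "h_r": restriction_hours(te, threshold(cell)),
            }
        )
    raw = pd.DataFrame(rows)
    # equal-weight mean over GCMs within each scenario
    per_cell = (
        raw.groupby(["cell_id", "latitude", "scenario"], sort=True, as_index=False)
        .agg(h_r=("h_r", "mean"))
    )
    current = per_cell[per_cell["scenario"] == "current"].set_index("cell_id")["h_r"]
    per_cell["delta_vs_current"] = (
        per_cell["h_r"] - per_cell["cell_id"].map(current).astype(float)
    )
    summary = (
        per_cell.groupby("scenario", sort=True)
        .agg(
            mean_h_r=("h_r", "mean"),
            se_h_r=("h_r", lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0),
            mean_delta=("delta_vs_current", "mean"),
            n_cells=("h_r", "size"),
        )
        .reset_index()
    )
    return per_cell, summary


def compare_scenarios(h_r_a, h_r_b):
    """Two-sample Wilcoxon rank-sum between per-cell h_r of two scenarios."""
    return popstats.wilcoxon_ranksum(h_r_a, h_r_b)


def latitude_trend(h_r, latitude):
    """OLS fit of per-cell h_r on latitude; returns the popstats FitResult."""
    return popstats.ols_fit(latitude, h_r)
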