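"""Thermoregulation index suite: accuracy d_b, habitat quality d_e, E, I, E_x.

Conventions follow the standard Hertz formulation: a temperature inside the
set-point range deviates by 0; above it by (t - upper); below by (lower - t).
d_b averages those deviations over field body temperatures, d_e over
operative temperatures within the diurnal window (06:00 inclusive to 20:00
exclusive).  E = 1 - d_b/d_e, I = d_e - d_b, and the exploitation index E_x
is the count of body temperatures inside the set-point range divided by the
count of records whose time-matched operative temperature overlaps it (the
ratio is not clamped and may exceed 1).  Percentile-bootstrap confidence
intervals are reported for d_b and d_e and are deliberately not clipped at
zero, so near-zero means can show negative lower bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    InvalidBoundsError,
    MatchingError,
    UndefinedIndexError,
)
from .tset import TsetEstimate

__all__ = [
    "BootstrapSpec",
    "IndexReport",
    "deviation",
    "accuracy_db",
    "habitat_quality_de",
    "effectiveness_hertz",
    "effectiveness_bdw",
    "exploitation_ex",
    "build_index_report",
    "report_frame",
]

DIURNAL_START_H = 6
DIURNAL_END_H = 20


@dataclass(frozen=True)
class BootstrapSpec:
    n_resamples: int = 10_000
    seed: int = 0
    alpha: float = 0.05


@dataclass
class IndexReport:
    """One Table-row of population-level indices; None marks a missing value."""

    population: str
    t_p: Optional[float] = None
    t_set_lower: Optional[float] = None
    t_set_upper: Optional[float] = None
    d_b: Optional[float] = None
    d_b_lo: Optional[float] = None
    d_b_hi: Optional[float] = None
    d_e: Optional[float] = None
    d_e_lo: Optional[float] = None
    d_e_hi: Optional[float] = None
    e_hertz: Optional[float] = None
    i_bdw: Optional[float] = None
    e_x: Optional[float] = None
    n_tb: int = 0
    n_te: int = 0


def deviation(t, lower: float, upper: float):
    """Non-negative deviation of a temperature from the set-point range."""
    if lower > upper:
        raise InvalidBoundsError(f"lower {lower} > upper {upper}")
    t = np.asarray(t, dtype=float)
    out = np.where(t > upper, t - upper, np.where(t < lower, lower - t, 0.0))
    return float(out) if out.ndim == 0 else out


def _percentile_ci(values: np.ndarray, spec: BootstrapSpec):
    rng = np.random.default_rng(spec.seed)
    n = values.size
    idx = rng.integers(0, n, size=(spec.n_resamples, n))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * spec.alpha / 2, 100 * (1 - spec.alpha / 2)])
    return float(lo), float(hi)


def accuracy_db(
    spots: pd.DataFrame,
    tset: TsetEstimate,
    ci: BootstrapSpec = None,
    per_individual: bool = False,
):
    """Mean deviation of field body temperatures from the set-point range.

    Returns (mean, ci_low, ci_high, n) with a percentile-bootstrap CI over
    records; with ``per_individual`` deviations are averaged within each
    individual first and the bootstrap resamples individuals.
    """
    if len(spots) == 0:
        raise InsufficientDataError("no spot records")
    ci = ci or BootstrapSpec()
    dev = deviation(spots["t_b"].to_numpy(dtype=float), tset.t_set_lower, tset.t_set_upper)
    if per_individual:
        dev = (
            pd.Series(dev, index=spots["individual_id"].to_numpy())
            .groupby(level=0)
            .mean()
            .to_numpy()
        )
    lo, hi = _percentile_ci(dev, ci)
    return float(dev.mean()), lo, hi, int(dev.size)


def _diurnal_mask(dt: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(dt)
    frac = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    return ((frac >= DIURNAL_START_H) & (frac < DIURNAL_END_H)).to_numpy()


def habitat_quality_de(otm: pd.DataFrame, tset: TsetEstimate, ci: BootstrapSpec = None):
    """Mean deviation of diurnal operative temperatures from the set-point range.

    All series of the population are pooled; only readings in [06:00, 20:00)
    count.  Returns (mean, ci_low, ci_high, n).
    """
    ci = ci or BootstrapSpec()
    mask = _diurnal_mask(otm["datetime"])
    day = otm.loc[mask]
    if len(day) == 0:
        raise InsufficientDataError("no OTM readings inside the diurnal window")
    dev = deviation(day["t_e"].to_numpy(dtype=float), tset.t_set_lower, tset.t_set_upper)
    lo, hi = _percentile_ci(dev, ci)
    return float(dev.mean()), lo, hi, int(dev.size)


def effectiveness_hertz(d_b: float, d_e: float) -> float:
    """Hertz effectiveness E = 1 - d_b/d_e; undefined in a thermally ideal habitat."""
    if d_e == 0:
        raise UndefinedIndexError("d_e = 0: habitat thermally ideal, E undefined")
    return 1.0 - d_b / d_e


def effectiveness_bdw(d_b: float, d_e: float) -> float:
    """Blouin-Demers & Weatherhead effectiveness I = d_e - d_b (°C)."""
    return d_e - d_b


def exploitation_ex(
    spots: pd.DataFrame,
    otm: pd.DataFrame,
    tset: TsetEstimate,
    match_tolerance_min: float = 2.5,
) -> float:
    """Thermal exploitation: time at preferred temperature over time it was available.

    Numerator: spot records with t_b inside the set-point range.  Denominator:
    spot records whose nearest-in-time operative reading (either microhabitat;
    within ``match_tolerance_min`` minutes) lies inside the range.  The ratio
    is returned unclamped.
    """
    if len(spots) == 0:
        raise InsufficientDataError("no spot records")
    lower, upper = tset.t_set_lower, tset.t_set_upper
    spot_t = pd.to_datetime(spots["datetime"]).to_numpy()
    otm_t = pd.to_datetime(otm["datetime"]).to_numpy()
    tol = np.timedelta64(int(round(match_tolerance_min * 60)), "s")

    numer = int(((spots["t_b"] >= lower) & (spots["t_b"] <= upper)).sum())
    series = []
    for _, grp in otm.groupby("microhabitat"):
        grp = grp.sort_values("datetime")
        series.append(
            (pd.to_datetime(grp["datetime"]).to_numpy(), grp["t_e"].to_numpy(float))
        )
    denom = 0
    for st in range(len(spots)):
        overlap = False
        matched = False
        for gt, gv in series:
            j = int(np.searchsorted(gt, spot_t[st]))
            for k in (j - 1, j):
                if 0 <= k < gt.size and abs(gt[k] - spot_t[st]) <= tol:
                    matched = True
                    if lower <= gv[k] <= upper:
                        overlap = True
        if not matched:
            raise MatchingError(
                f"spot at {spots['datetime'].iloc[st]} has no operative reading "
                f"within {match_tolerance_min} min"
            )
        if overlap:
            denom += 1
    if denom == 0:
        raise UndefinedIndexError("no matched operative temperature overlaps T_set")
    return numer / denom


def build_index_report(
    population: str,
    tset: TsetEstimate,
    spots: Optional[pd.DataFrame],
    otm: Optional[pd.DataFrame],
    ci: BootstrapSpec = None,
    ex_tolerance_min: float = 2.5,
) -> IndexReport:
    """Assemble the per-population index row; absent inputs leave fields None.

    A population with operative series but no body-temperature records (the
    VA case) reports d_e only, with d_b, E, I and E_x flagged missing.
    """
    ci = ci or BootstrapSpec()
    rep = IndexReport(
        population=population,
        t_p=tset.t_p,
        t_set_lower=tset.t_set_lower,
        t_set_upper=tset.t_set_upper,
    )
    if otm is not None and len(otm):
        rep.d_e, rep.d_e_lo, rep.d_e_hi, rep.n_te = habitat_quality_de(otm, tset, ci)
    if spots is not None and len(spots):
        rep.d_b, rep.d_b_lo, rep.d_b_hi, rep.n_tb = accuracy_db(spots, tset, ci)
        if rep.d_e is not None:
            rep.e_hertz = effectiveness_hertz(rep.d_b, rep.d_e) if rep.d_e > 0 else None
            rep.i_bdw = effectiveness_bdw(rep.d_b, rep.d_e)
            try:
                rep.e_x = exploitation_ex(spots, otm, tset, ex_tolerance_min)
            except UndefinedIndexError:
                rep.e_x = None
    return rep


def report_frame(reports) -> pd.DataFrame:
    """Stack IndexReport rows into the fixed-column output table."""
    cols = [
        "population", "t_p", "t_set_lower", "t_set_upper",
        "d_b", "d_b_lo", "d_b_hi", "d_e", "d_e_lo", "d_e_hi",
        "e_hertz", "i_bdw", "e_x", "n_tb", "n_te",
    ]
    frame = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in reports])
    for c in cols[1:13]:  # missing values become NaN in float columns
        frame[c] = frame[c].astype(float)
    return frame
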