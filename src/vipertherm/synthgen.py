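"""Seeded synthetic data with the statistical structure the analysis assumes.

The generators emulate the five inputs of the study design: thermal-gradient
trials, field spot body temperatures, operative-temperature (OTM) logger
series, monthly climate per occurrence cell under current and future
scenarios, and a small population-level phylogeny.  Every generator is a pure
function of (config, seed) so that downstream stages are testable without any
field data.

Structural defaults are anchored to the study system: five populations on a
latitudinal gradient with an overall preferred temperature near 28.8 °C, a
female size effect of 0.02 °C/mm on preferred temperature, a cross-population
latitude trend of roughly 1.56 °C/degree, gradient trials read hourly from
06:00 to 18:00, OTM loggers on a 5-min cadence in paired sun/shade
microhabitats, and 12 monthly means per climate cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

__all__ = [
    "PopulationConfig",
    "ScenarioOffsets",
    "default_population_configs",
    "default_scenarios",
    "generate_roster",
    "generate_gradient_trials",
    "generate_field_campaign",
    "generate_climate_grid",
    "generate_phylogeny",
]

#: slope of preferred temperature on female snout-vent length, °C per mm
FEMALE_SVL_TP_SLOPE = 0.02
#: cross-population trend of preferred temperature on latitude, °C per degree
LATITUDE_TP_SLOPE = 1.557
#: grand mean preferred temperature anchoring the population defaults, °C
OVERALL_TP = 28.77
#: adult body mass used by the operative-model stand-in, grams
ANIMAL_MASS_G = 33.5

_TRIAL_DATE = "2019-08-01"
_CAMPAIGN_DATE = "2019-08-01"

# per-stage children of the root seed, so stages draw from independent streams
_STREAM = {"roster": 11, "trials": 12, "field": 13, "climate": 14}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAM[stage])))


@dataclass(frozen=True)
class PopulationConfig:
    """Generating parameters for one population.

    ``base_tp`` is the population-mean preferred temperature; individuals
    scatter around it with SD ``tp_sd_between`` and their gradient readings
    scatter around the individual value with SD ``tp_sd_within``.
    """

    name: str
    latitude: float
    base_tp: float
    tp_sd_between: float = 1.2
    tp_sd_within: float = 2.0
    n_individuals: int = 10
    n_otm_days: int = 3
    svl_mean_mm: float = 270.0
    svl_sd_mm: float = 35.0

    def __post_init__(self) -> None:
        if not 35.0 <= self.latitude <= 45.0:
            raise InvalidConfigError(f"latitude {self.latitude} outside [35, 45]")
        if not 15.0 < self.base_tp < 45.0:
            raise InvalidConfigError(f"base_tp {self.base_tp} outside (15, 45)")
        if self.tp_sd_between <= 0 or self.tp_sd_within < 0:
            raise InvalidConfigError("SDs must be positive")
        if self.n_individuals < 1:
            raise InvalidConfigError("n_individuals must be >= 1")
        if self.n_otm_days < 1:
            raise InvalidConfigError("n_otm_days must be >= 1")


@dataclass(frozen=True)
class ScenarioOffsets:
    """Monthly warming offsets (°C) for one scenario x climate-model pair."""

    scenario_id: str
    gcm_id: str
    monthly_offset: tuple = field(default=(0.0,) * 12)

    def __post_init__(self) -> None:
        if len(self.monthly_offset) != 12:
            raise InvalidConfigError("exactly 12 monthly offsets required")
        if self.scenario_id == "current" and any(o != 0.0 for o in self.monthly_offset):
            raise InvalidConfigError("current scenario must have zero offsets")


def default_population_configs() -> list:
    """Five populations on a north-to-south latitudinal gradient.

    Counts and body sizes follow the study's sampling design (19/5/31/3/15
    individuals); base preferred temperatures reproduce the observed spread
    around the 28.77 °C grand mean and its positive latitude trend.
    """
    return [
        PopulationConfig("TO", 40.70, 30.09, n_individuals=19, svl_mean_mm=293.2),
        PopulationConfig("KU", 40.50, 28.95, n_individuals=5, svl_mean_mm=234.3),
        PopulationConfig("TY", 39.98, 28.74, n_individuals=31, svl_mean_mm=257.7),
        PopulationConfig("LA", 39.60, 30.26, n_individuals=3, svl_mean_mm=317.7),
        PopulationConfig("VA", 38.66, 26.77, n_individuals=15, svl_mean_mm=262.6),
    ]


def default_scenarios() -> list:
    """Current climate plus three GCMs under an optimistic and a pessimistic SSP.

    Offsets approximate end-of-century Mediterranean-mountain warming:
    ~+1.8 °C under SSP1-2.6 and ~+4.5 °C under SSP5-8.5, slightly larger in
    summer months, with small between-GCM spread.
    """
    month = np.arange(12)
    summer_bump = 0.4 * np.sin((month - 3) / 12.0 * 2 * np.pi)  # peaks mid-year
    out = [ScenarioOffsets("current", "none")]
    for i, gcm in enumerate(["GCM-A", "GCM-B", "GCM-C"]):
        for ssp, base in (("SSP1-2.6", 1.8), ("SSP5-8.5", 4.5)):
            offs = base + 0.2 * (i - 1) + summer_bump
            out.append(ScenarioOffsets(ssp, gcm, tuple(np.round(offs, 3))))
    return out


def generate_roster(configs, seed: int) -> pd.DataFrame:
    """Draw individuals with sex, size, gravidity and a latent preferred temperature.

    Female latent preferred temperature includes the size effect
    ``FEMALE_SVL_TP_SLOPE * (svl - population mean svl)``; males are
    size-independent.  Deterministic under (configs, seed).
    """
    if not configs:
        raise InvalidConfigError("need at least one PopulationConfig")
    rng = _rng(seed, "roster")
    rows = []
    for cfg in configs:
        sex = rng.choice(["male", "female"], size=cfg.n_individuals)
        svl = rng.normal(cfg.svl_mean_mm, cfg.svl_sd_mm, size=cfg.n_individuals)
        svl = np.clip(svl, 150.0, 450.0)
        gravid = (sex == "female") & (rng.random(cfg.n_individuals) < 0.3)
        noise = rng.normal(0.0, cfg.tp_sd_between, size=cfg.n_individuals)
        tp = cfg.base_tp + noise
        tp = np.where(
            sex == "female",
            tp + FEMALE_SVL_TP_SLOPE * (svl - cfg.svl_mean_mm),
            tp,
        )
        tp = np.clip(tp, 15.01, 44.99)
        for i in range(cfg.n_individuals):
            rows.append(
                {
                    "individual_id": f"{cfg.name}-{i + 1:03d}",
                    "population": cfg.name,
                    "latitude": cfg.latitude,
                    "sex": sex[i],
                    "svl_mm": round(float(svl[i]), 1),
                    "gravid": bool(gravid[i]),
                    "true_tp": round(float(tp[i]), 4),
                    "tp_sd_within": cfg.tp_sd_within,
                }
            )
    return pd.DataFrame(rows)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled normal restricted to (lo, hi); exact for sd = 0."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    if sd == 0:
        return np.clip(mean, lo + 1e-9, hi - 1e-9)
    out = rng.normal(mean, sd)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd)
        bad = (out <= lo) | (out >= hi)
    return out


def generate_gradient_trials(
    roster: pd.DataFrame, seed: int, hours=None, sd_within=None
) -> pd.DataFrame:
    """Hourly cloacal temperatures in the laboratory thermal gradient.

    One reading per clock hour (default 06:00-18:00 inclusive, 13 readings)
    per individual, drawn from a normal around the individual's latent
    preferred temperature truncated to (15, 45) °C.
    """
    if hours is None:
        hours = list(range(6, 19))
    hours = list(hours)
    if not hours:
        raise InvalidConfigError("hours must be non-empty")
    if any(h < 0 or h > 23 for h in hours):
        raise InvalidConfigError("hours must lie in 0-23")
    rng = _rng(seed, "trials")
    n = len(roster)
    k = len(hours)
    sd = roster.get("tp_sd_within")
    if sd_within is not None:
        sd_arr = np.full(n, float(sd_within))
    elif sd is not None:
        sd_arr = sd.to_numpy(dtype=float)
    else:
        sd_arr = np.full(n, 2.0)
    rows = []
    for idx, rec in enumerate(roster.itertuples(index=False)):
        s = float(sd_arr[idx])
        if s == 0:
            temps = np.full(k, rec.true_tp)
        else:
            temps = _truncated_normal(rng, rec.true_tp, s, 15.0, 45.0, (k,))
        for h, t in zip(hours, temps):
            rows.append(
                {
                    "individual_id": rec.individual_id,
                    "population": rec.population,
                    "timestamp": f"{_TRIAL_DATE} {h:02d}:00:00",
                    "temp_c": round(float(t), 2),
                }
            )
    return pd.DataFrame(rows)


def _diurnal_te(rng, n_days, base, amplitude, noise_sd, ar):
    """5-min operative series: sinusoid peaking at 14:00 plus AR(1) noise."""
    steps_per_day = 24 * 12
    t = np.arange(n_days * steps_per_day)
    hour = (t % steps_per_day) / 12.0
    clean = base + amplitude * np.sin(2 * np.pi * (hour - 8.0) / 24.0)
    eps = rng.normal(0.0, noise_sd, size=t.size)
    noise = np.empty(t.size)
    acc = 0.0
    for i in range(t.size):
        acc = ar * acc + eps[i]
        noise[i] = acc
    return clean + noise


def generate_field_campaign(
    roster: pd.DataFrame,
    seed: int,
    n_days: int = 3,
    cold_fraction: float = 0.05,
    sun_amplitude: float = 12.0,
    shade_amplitude: float = 6.0,
    te_base: float = 18.0,
    noise_sd: float = 0.5,
    ar_coef: float = 0.8,
    spots_per_individual: int = 3,
    populations_without_tb=("VA",),
):
    """Spot body temperatures plus paired sun/shade OTM logger series.

    Returns ``(spots, otm)`` DataFrames.  Spot temperatures sit near the
    individual's latent preferred value; a ``cold_fraction`` of records is
    replaced by early-morning sub-preferred observations, mimicking animals
    caught at the start of morning basking.  Populations listed in
    ``populations_without_tb`` get OTM series but no spot records.
    """
    if n_days < 1:
        raise InvalidConfigError("n_days must be >= 1")
    if not 0.0 <= cold_fraction < 1.0:
        raise InvalidConfigError("cold_fraction must lie in [0, 1)")
    rng = _rng(seed, "field")
    steps_per_day = 24 * 12
    otm_rows = []
    for pop in roster["population"].unique():
        for micro, amp, off in (
            ("sun", sun_amplitude, 2.0),
            ("shade", shade_amplitude, 0.0),
        ):
            series = _diurnal_te(rng, n_days, te_base + off, amp, noise_sd, ar_coef)
            stamps = pd.date_range(
                _CAMPAIGN_DATE, periods=n_days * steps_per_day, freq="5min"
            )
            otm_rows.append(
                pd.DataFrame(
                    {
                        "population": pop,
                        "microhabitat": micro,
                        "datetime": stamps.strftime("%Y-%m-%d %H:%M:%S"),
                        "t_e": np.round(series, 2),
                    }
                )
            )
    otm = pd.concat(otm_rows, ignore_index=True)

    spot_rows = []
    for rec in roster.itertuples(index=False):
        if rec.population in populations_without_tb:
            continue
        for j in range(spots_per_individual):
            cold = rng.random() < cold_fraction
            if cold:
                minute = int(rng.integers(6 * 60, 8 * 60))
                t_b = rec.true_tp - float(rng.uniform(6.0, 10.0))
            else:
                minute = int(rng.integers(8 * 60, 20 * 60))
                # warm records stay within +/- 1.5 °C of the latent preferred
                # value, i.e. well inside a typical set-point range
                t_b = float(
                    _truncated_normal(
                        rng, rec.true_tp, 0.8, rec.true_tp - 1.5, rec.true_tp + 1.5, (1,)
                    )[0]
                )
            day = int(rng.integers(0, n_days))
            stamp = pd.Timestamp(_CAMPAIGN_DATE) + pd.Timedelta(
                days=day, minutes=minute
            )
            spot_rows.append(
                {
                    "individual_id": rec.individual_id,
                    "population": rec.population,
                    "datetime": stamp.strftime("%Y-%m-%d %H:%M:%S"),
                    "t_b": round(max(t_b, 5.0), 1),
                    "microhabitat": "sun" if rng.random() < 0.6 else "shade",
                    "latitude": rec.latitude,
                    "svl_mm": rec.svl_mm,
                    "sex": rec.sex,
                    "gravid": rec.gravid,
                }
            )
    spots = pd.DataFrame(spot_rows)
    return spots, otm


def generate_climate_grid(
    seed: int,
    n_cells: int = 102,
    lat_range=(38.5, 40.8),
    scenarios=None,
    mean_annual_at_lat0: float = 9.0,
    lat0: float = 39.5,
    lat_slope: float = -1.2,
    seasonal_amplitude: float = 9.0,
    cell_noise_sd: float = 0.7,
) -> pd.DataFrame:
    """Monthly mean air temperature per occurrence cell and scenario.

    Each cell gets 12 monthly means built from a sinusoidal seasonal cycle
    (peak in July), a negative latitude trend (°C per degree), and cell-level
    noise; scenario offsets are added on top.  Long format with columns
    cell_id, latitude, scenario, gcm, m01..m12.
    """
    if n_cells < 1:
        raise InvalidConfigError("n_cells must be >= 1")
    if scenarios is None:
        scenarios = default_scenarios()
    if not any(s.scenario_id == "current" for s in scenarios):
        raise InvalidConfigError("scenario list must include 'current'")
    rng = _rng(seed, "climate")
    lats = rng.uniform(lat_range[0], lat_range[1], size=n_cells)
    month = np.arange(12)
    season = seasonal_amplitude * np.cos(2 * np.pi * (month - 6.5) / 12.0)
    noise = rng.normal(0.0, cell_noise_sd, size=(n_cells, 12))
    base = (
        mean_annual_at_lat0
        + lat_slope * (lats[:, None] - lat0)
        + season[None, :]
        + noise
    )
    rows = []
    for sc in scenarios:
        monthly = base + np.asarray(sc.monthly_offset)[None, :]
        for c in range(n_cells):
            row = {
                "cell_id": f"cell-{c + 1:03d}",
                "latitude": round(float(lats[c]), 4),
                "scenario": sc.scenario_id,
                "gcm": sc.gcm_id,
            }
            for m in range(12):
                row[f"m{m + 1:02d}"] = round(float(monthly[c, m]), 3)
            rows.append(row)
    return pd.DataFrame(rows)


def generate_phylogeny(populations, southern: str | None = None) -> str:
    """Newick topology with the southern population sister to the rest.

    With the default five populations this yields the two-lineage structure
    of the study system (one southern tip against a northern clade).  Pass
    ``southern=None`` with two tips for a plain cherry.
    """
    populations = list(populations)
    if len(populations) < 2:
        raise InvalidConfigError("need at least 2 populations")
    if len(set(populations)) != len(populations):
        raise InvalidConfigError("duplicate population labels")
    if len(populations) == 2:
        return f"({populations[0]},{populations[1]});"
    if southern is None:
        southern = "VA" if "VA" in populations else populations[-1]
    if southern not in populations:
        raise InvalidConfigError(f"southern label {southern!r} not among populations")
    rest = [p for p in populations if p != southern]
    # pectinate northern clade keeps the topology deterministic
    clade = rest[0]
    for p in rest[1:]:
        clade = f"({clade},{p})"
    return f"({southern},{clade});"
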