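"""Observed growth rate, areal productivity and the culture Health Index.

The Health Index (HI) compares the growth rate a culture actually achieved
between the morning and evening AFDW samples with the rate a healthy-growth
simulator predicts for the same interval and environment:

    mu_obs = ln(AFDWe / AFDWm) / (te - tm)
    HI_raw = -(mu_obs - mu_model) / mu_obs

HI_raw is zero when observation matches the model.  Because the model only
describes healthy growth, stressed cultures have mu_obs < mu_model and
positive HI_raw; the negated value (``hi_plot``) is the canonical score used
for plotting and correlation so that larger means healthier.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from datetime import datetime, time

import numpy as np
import pandas as pd

from .growth_model import EnvironmentSeries, GrowthModelParams, simulate_day
from .io_tables import CultureSeries, logger

#: |mu_obs| below this threshold makes the HI denominator unusable.
DEFAULT_MU_TOL = 1e-3  # day^-1


@dataclass
class HealthRecord:
    run_id: str
    date: object
    mu_obs: float
    mu_model: float
    hi_raw: float | None
    hi_plot: float | None
    valid: bool
    reason: str = ""


@dataclass
class ProductivityRecord:
    run_id: str
    t_prev: object
    t_now: object
    delta_conc: float   # g l^-1
    volume: float       # l
    surface_area: float  # m^2
    days: float
    productivity: float  # g m^-2 day^-1


def observed_growth_rate(afdw_m: float, afdw_e: float, t_m, t_e) -> float:
    """ln(AFDWe/AFDWm) / (te - tm) with the interval in days.

    ``t_m``/``t_e`` may be floats (days) or datetimes.
    """
    if afdw_m <= 0 or afdw_e <= 0:
        raise ValueError("AFDW values must be positive")
    dt_days = _interval_days(t_m, t_e)
    if dt_days <= 0:
        raise ValueError("evening time must follow morning time")
    return float(np.log(afdw_e / afdw_m) / dt_days)


def _interval_days(t_m, t_e) -> float:
    if isinstance(t_m, (datetime, pd.Timestamp)) or isinstance(t_e, (datetime, pd.Timestamp)):
        return (pd.Timestamp(t_e) - pd.Timestamp(t_m)).total_seconds() / 86400.0
    return float(t_e) - float(t_m)


def areal_productivity(conc_prev: float, conc_now: float, volume: float,
                       area: float, days: float) -> float:
    """(conc_now - conc_prev) * volume / (area * days), g m^-2 day^-1.

    Negative during culture decline; that is informative, not an error.
    """
    if volume <= 0 or area <= 0 or days <= 0:
        raise ValueError("volume, area and days must be positive")
    return (conc_now - conc_prev) * volume / (area * days)


def health_index(mu_obs: float, mu_model: float, tol: float = DEFAULT_MU_TOL,
                 bounded: bool = False) -> tuple[float | None, float | None, bool, str]:
    """Return (hi_raw, hi_plot, valid, reason).

    With ``bounded=True`` the alternative score
    (mu_obs - mu_model)/max(|mu_obs|, |mu_model|) is returned in ``hi_plot``
    (and its negation in ``hi_raw``), which stays finite near mu_obs = 0.
    """
    if bounded:
        denom = max(abs(mu_obs), abs(mu_model))
        if denom <= tol:
            return None, None, False, "both rates near zero"
        score = (mu_obs - mu_model) / denom
        return -score, score, True, ""
    if abs(mu_obs) <= tol:
        return None, None, False, "observed rate near zero"
    hi_raw = -(mu_obs - mu_model) / mu_obs
    return hi_raw, -hi_raw, True, ""


def run_health_series(series: CultureSeries, params: GrowthModelParams,
                      env: EnvironmentSeries | None = None,
                      solar_noon: time = time(12, 0),
                      tol: float = DEFAULT_MU_TOL,
                      bounded: bool = False) -> list[HealthRecord]:
    """One HealthRecord per day with a paired morning/evening AFDW sample.

    Pairing rule: within each calendar day of the run, "morning" is the first
    sample strictly before ``solar_noon`` local time and "evening" the last
    one at or after it; days without both are skipped with a logged reason.
    mu_model comes from the growth simulator run over the same interval,
    driven by ``env`` (or ``series.env``) or, as a fallback, by linear
    interpolation of the irradiance/temperature recorded at sample times.
    """
    records: list[HealthRecord] = []
    rec = series.records.copy()
    if rec.empty:
        return records
    rec["datetime"] = pd.to_datetime(rec["datetime"])
    t0 = rec["datetime"].min().normalize()
    rec["_t_day"] = (rec["datetime"] - t0).dt.total_seconds() / 86400.0

    env_series = env if env is not None else _environment_from(series, rec, t0)
    if env is None and series.env is None:
        # coarse fallback profile interpolated from sample-time readings:
        # relax the dense-coverage guard to the sampling interval
        params = replace(params, max_env_gap=1.0)

    for date, day in rec.groupby(rec["datetime"].dt.date):
        morning = day[day["datetime"].dt.time < solar_noon]
        evening = day[day["datetime"].dt.time >= solar_noon]
        if morning.empty or evening.empty:
            logger.info("run %s day %s: unpaired day skipped", series.run_id, date)
            continue
        m = morning.iloc[0]
        e = evening.iloc[-1]
        t_m, t_e = float(m["_t_day"]), float(e["_t_day"])
        try:
            mu_obs = observed_growth_rate(m["afdw_g_per_l"], e["afdw_g_per_l"], t_m, t_e)
            _, mu_model = simulate_day(float(m["afdw_g_per_l"]), env_series, params,
                                       t_m=t_m, t_e=t_e)
        except ValueError as exc:
            logger.info("run %s day %s: skipped (%s)", series.run_id, date, exc)
            continue
        hi_raw, hi_plot, valid, reason = health_index(mu_obs, mu_model, tol=tol,
                                                      bounded=bounded)
        records.append(HealthRecord(series.run_id, date, mu_obs, mu_model,
                                    hi_raw, hi_plot, valid, reason))
    return records


def _environment_from(series: CultureSeries, rec: pd.DataFrame,
                      t0: pd.Timestamp) -> EnvironmentSeries:
    """Environment for the simulator, preferring the attached dense profile."""
    if series.env is not None:
        env = series.env
        return EnvironmentSeries(env["time_day"].to_numpy(),
                                 env["solar_w_per_m2"].to_numpy(),
                                 env["water_temp_c"].to_numpy())
    return EnvironmentSeries(rec["_t_day"].to_numpy(),
                             rec["solar_w_per_m2"].to_numpy(),
                             rec["water_temp_c"].to_numpy())


def run_productivity_series(series: CultureSeries, volume: float, area: float,
                            use: str = "morning",
                            solar_noon: time = time(12, 0)) -> list[ProductivityRecord]:
    """Areal productivity between consecutive AFDW measurements of a run.

    ``use`` selects which daily samples anchor the differences: "morning"
    (default, one interval per day pair), "evening", or "all" samples.
    """
    rec = series.records.copy()
    rec["datetime"] = pd.to_datetime(rec["datetime"])
    if use == "morning":
        rec = rec[rec["datetime"].dt.time < solar_noon]
        rec = rec.groupby(rec["datetime"].dt.date).first()
    elif use == "evening":
        rec = rec[rec["datetime"].dt.time >= solar_noon]
        rec = rec.groupby(rec["datetime"].dt.date).last()
    elif use != "all":
        raise ValueError(f"unknown sample selector {use!r}")
    out: list[ProductivityRecord] = []
    rows = rec.reset_index(drop=True)
    for i in range(1, len(rows)):
        prev, now = rows.iloc[i - 1], rows.iloc[i]
        days = _interval_days(prev["datetime"], now["datetime"])
        if days <= 0:
            continue
        delta = float(now["afdw_g_per_l"] - prev["afdw_g_per_l"])
        out.append(ProductivityRecord(
            series.run_id, prev["datetime"], now["datetime"], delta,
            volume, area, days, areal_productivity(
                float(prev["afdw_g_per_l"]), float(now["afdw_g_per_l"]),
                volume, area, days)))
    return out


def attach_biomass_productivity(metadata: pd.DataFrame, volume: float,
                                area: float) -> pd.DataFrame:
    """Add a ``biomass_prod`` column (g m^-2 day^-1) to sample metadata.

    Productivity is computed per run between consecutive morning AFDW
    measurements and assigned to every sample of the interval's ending day;
    first sampled days have no previous point and get NaN.
    """
    md = metadata.copy()
    md["datetime"] = pd.to_datetime(md["datetime"])
    md["biomass_prod"] = np.nan
    for run_id, grp in md.groupby("run_id"):
        mornings = grp[grp["datetime"].dt.time < time(12, 0)]
        mornings = mornings.sort_values("datetime")
        prev = None
        for _, row in mornings.iterrows():
            if prev is not None:
                days = _interval_days(prev["datetime"], row["datetime"])
                if days > 0:
                    prod = areal_productivity(prev["afdw_g_per_l"],
                                              row["afdw_g_per_l"],
                                              volume, area, days)
                    day = row["datetime"].date()
                    sel = (md["run_id"] == run_id) & (md["datetime"].dt.date == day)
                    md.loc[sel, "biomass_prod"] = prod
            prev = row
    return md


def health_records_frame(records: list[HealthRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(HealthRecord)]
    return pd.DataFrame([r.__dict__ for r in records], columns=cols)


def productivity_records_frame(records: list[ProductivityRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(ProductivityRecord)]
    return pd.DataFrame([r.__dict__ for r in records], columns=cols)
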