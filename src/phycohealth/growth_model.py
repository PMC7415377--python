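"""Healthy-growth simulator for dense outdoor algal cultures.

Predicts the daytime biomass trajectory of an uncontaminated culture from
surface irradiance and water temperature.  The model is multiplicative:

    mu(I, T) = mu_max * f_T(T) * f_I(I)

with ``f_T`` the cardinal-temperature model with inflexion (zero outside
[t_min, t_max], one at t_opt) and ``f_I(I) = tanh(I / i_sat)``.  Self-shading
is Beer-Lambert: irradiance decays with depth at rate ``k_w + sigma_a * X``
(X in g m^-3), and the realised growth rate is the average of mu over depth
layers.  Integrating dX/dt = mu_bar(X, t) * X from the morning sampling time
to the evening one yields the simulated evening biomass AFDWe' and hence the
model growth rate mu_model = ln(AFDWe'/AFDWm) / (te - tm).

Both response functions are pluggable; the defaults define the package's
canonical healthy-growth reference used by the Health Index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import yaml


@dataclass
class GrowthModelParams:
    """Parameters of the light/temperature growth model.

    mu_max is the maximum specific growth rate (day^-1) reached at optimal
    temperature under saturating light; 5.9/day at t_opt=36 C matches lab
    characterisation of the high-temperature *Chlorella sorokiniana* strain
    the pipeline targets.  The remaining defaults describe a 25 cm deep
    raceway scenario and are freely overridable.
    """

    mu_max: float = 5.9          # day^-1
    t_min: float = 5.0           # deg C, no growth at or below
    t_opt: float = 36.0          # deg C
    t_max: float = 45.0          # deg C, no growth at or above
    i_sat: float = 100.0         # W m^-2 (PAR scale of tanh light response)
    k_w: float = 0.2             # m^-1 background water attenuation
    sigma_a: float = 0.1         # m^2 g^-1 biomass-specific attenuation
    depth: float = 0.25          # m
    n_layers: int = 50
    dt: float = 1e-3             # day, integration step
    par_fraction: float = 0.45   # fraction of total solar that is PAR
    night_loss_rate: float = 0.0  # day^-1 optional linear biomass loss
    integrator: str = "rk4"      # "rk4" | "euler"
    max_env_gap: float = 0.05    # day, largest tolerated gap in env coverage

    def __post_init__(self):
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError("require t_min < t_opt < t_max")
        if self.mu_max <= 0 or self.depth <= 0 or self.dt <= 0 or self.i_sat <= 0:
            raise ValueError("mu_max, depth, dt and i_sat must be positive")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.integrator not in ("euler", "rk4"):
            raise ValueError(f"unknown integrator {self.integrator!r}")

    @classmethod
    def from_yaml(cls, path) -> "GrowthModelParams":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class EnvironmentSeries:
    """Irradiance and water temperature sampled over a simulation interval.

    Times are in days (fraction-of-day resolution); irradiance is total
    solar in W m^-2 (the PAR fraction is applied inside the model).
    """

    times: np.ndarray
    irradiance: np.ndarray
    water_temp: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        self.water_temp = np.asarray(self.water_temp, dtype=float)
        if not (len(self.times) == len(self.irradiance) == len(self.water_temp)):
            raise ValueError("times, irradiance and water_temp must align")
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.irradiance < 0).any():
            raise ValueError("irradiance must be nonnegative")

    def interp(self, t: float) -> tuple[float, float]:
        i0 = float(np.interp(t, self.times, self.irradiance))
        temp = float(np.interp(t, self.times, self.water_temp))
        return i0, temp


# ---------------------------------------------------------------------------
# Response functions
# ---------------------------------------------------------------------------

def cardinal_temperature_response(temp, params: GrowthModelParams):
    """Cardinal temperature model with inflexion (CTMI); in [0, 1].

    Zero at and outside the cardinal limits, one exactly at t_opt.
    """
    t = np.asarray(temp, dtype=float)
    tmin, topt, tmax = params.t_min, params.t_opt, params.t_max
    num = (t - tmax) * (t - tmin) ** 2
    den = (topt - tmin) * ((topt - tmin) * (t - topt)
                           - (topt - tmax) * (topt + tmin - 2.0 * t))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den != 0, num / den, 0.0)
    f = np.where((t <= tmin) | (t >= tmax), 0.0, f)
    return np.clip(f, 0.0, 1.0)


def tanh_light_response(irradiance, params: GrowthModelParams):
    """Saturating light response tanh(I/i_sat) on PAR irradiance."""
    return np.tanh(np.asarray(irradiance, dtype=float) / params.i_sat)


def light_profile(i0: float, biomass: float, params: GrowthModelParams) -> np.ndarray:
    """Irradiance at each depth-layer midpoint under Beer-Lambert decay.

    ``biomass`` is culture density in g l^-1 (converted to g m^-3 for the
    attenuation coefficient).  Monotone non-increasing with depth.
    """
    if i0 < 0 or biomass < 0:
        raise ValueError("irradiance and biomass must be nonnegative")
    k = params.k_w + params.sigma_a * biomass * 1000.0  # g l^-1 -> g m^-3
    z = (np.arange(params.n_layers) + 0.5) * (params.depth / params.n_layers)
    return i0 * np.exp(-k * z)


def specific_growth_rate(irradiance, temp, params: GrowthModelParams,
                         f_T: Callable = cardinal_temperature_response,
                         f_I: Callable = tanh_light_response):
    """mu(I, T) = mu_max * f_T(T) * f_I(I) in day^-1.

    ``irradiance`` is taken as effective (PAR) irradiance; the PAR fraction
    is applied by :func:`depth_averaged_growth_rate` before descending the
    water column.
    """
    return params.mu_max * f_T(temp, params) * f_I(irradiance, params)


def depth_averaged_growth_rate(i0: float, temp: float, biomass: float,
                               params: GrowthModelParams,
                               f_T: Callable = cardinal_temperature_response,
                               f_I: Callable = tanh_light_response) -> float:
    """Average of mu over depth layers for surface (total solar) irradiance i0."""
    layers = light_profile(params.par_fraction * i0, biomass, params)
    mu = specific_growth_rate(layers, temp, params, f_T=f_T, f_I=f_I)
    return float(np.mean(mu))


# ---------------------------------------------------------------------------
# Day simulation
# ---------------------------------------------------------------------------

class EnvironmentCoverageError(ValueError):
    """The environment series does not cover the simulation interval."""


def _check_coverage(env: EnvironmentSeries, t_m: float, t_e: float,
                    params: GrowthModelParams) -> None:
    if len(env.times) < 2 or env.times[0] > t_m + 1e-12 or env.times[-1] < t_e - 1e-12:
        raise EnvironmentCoverageError(
            f"environment series does not cover [{t_m}, {t_e}]")
    inside = env.times[(env.times >= t_m) & (env.times <= t_e)]
    grid = np.concatenate(([t_m], inside, [t_e]))
    gap = float(np.max(np.diff(grid))) if len(grid) > 1 else t_e - t_m
    if gap > max(params.max_env_gap, 5.0 * params.dt):
        raise EnvironmentCoverageError(
            f"environment gap of {gap:.4f} day exceeds tolerated maximum")


def simulate_day(afdw_m: float, env: EnvironmentSeries, params: GrowthModelParams,
                 t_m: float | None = None, t_e: float | None = None,
                 f_T: Callable = cardinal_temperature_response,
                 f_I: Callable = tanh_light_response) -> tuple[float, float]:
    """Integrate daytime growth from AFDWm; return (AFDWe', mu_model).

    The interval defaults to the span of ``env``.  mu_model is the observed
    growth-rate formula applied to the simulated endpoints.
    """
    if afdw_m <= 0:
        raise ValueError("morning AFDW must be positive")
    t_m = float(env.times[0]) if t_m is None else float(t_m)
    t_e = float(env.times[-1]) if t_e is None else float(t_e)
    if t_e <= t_m:
        raise ValueError("evening time must follow morning time")
    _check_coverage(env, t_m, t_e, params)

    def rate(x: float, t: float) -> float:
        i0, temp = env.interp(t)
        return depth_averaged_growth_rate(i0, temp, x, params, f_T=f_T, f_I=f_I) * x

    x, t = afdw_m, t_m
    dt = params.dt
    while t < t_e - 1e-12:
        h = min(dt, t_e - t)
        if params.integrator == "rk4":
            k1 = rate(x, t)
            k2 = rate(x + 0.5 * h * k1, t + 0.5 * h)
            k3 = rate(x + 0.5 * h * k2, t + 0.5 * h)
            k4 = rate(x + h * k3, t + h)
            x = x + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        else:
            x = x + h * rate(x, t)
        t += h
    if params.night_loss_rate:
        # optional linear loss applied over the same interval
        x *= np.exp(-params.night_loss_rate * (t_e - t_m))
    mu_model = float(np.log(x / afdw_m) / (t_e - t_m))
    return float(x), mu_model
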