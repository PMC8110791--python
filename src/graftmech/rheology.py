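"""Rheology of the culture medium: viscosity curves, fits, and the
shear-stress bookkeeping used to report applied loads.

Viscosity η(γ̇) is measured on a cone-plate rheometer between 10 and
1500 s⁻¹; curves are linearly interpolated (after averaging replicate
measurements per shear-rate level) to evaluate viscosity at the applied
shear rate, and the wall shear stress follows τ(γ̇) = γ̇·η(γ̇).  Daily
reported stresses are the product of the daily mean shear rate and the
daily mean viscosity, with a first-order independent-variable error
propagation for the standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synth import carreau_viscosity, power_law_viscosity

__all__ = [
    "RheologyCurve",
    "ShearCondition",
    "interpolate_viscosity",
    "shear_stress",
    "daily_stress_with_error",
    "fit_power_law",
    "fit_carreau",
    "read_rheology_csv",
]


@dataclass(frozen=True)
class ShearCondition:
    """Applied shear condition: mean ± sd of rate, viscosity and stress.

    ``mode`` is 'steady' or 'oscillatory' (1 Hz complete flow reversal,
    reported as a symmetric ± stress).
    """

    mode: str
    shear_rate_mean: float
    shear_rate_sd: float
    viscosity_mean: float
    viscosity_sd: float
    stress_mean: float
    stress_sd: float

    def __post_init__(self) -> None:
        if self.mode not in ("steady", "oscillatory"):
            raise ValueError("mode must be 'steady' or 'oscillatory'")
        if min(self.shear_rate_sd, self.viscosity_sd, self.stress_sd) < 0:
            raise ValueError("standard deviations must be >= 0")

    def __str__(self) -> str:
        pm = "(±) " if self.mode == "oscillatory" else ""
        return (
            f"{self.mode}: γ̇ = {self.shear_rate_mean:.4g} ± {self.shear_rate_sd:.2g} 1/s, "
            f"η = {self.viscosity_mean:.4g} ± {self.viscosity_sd:.2g} Pa·s, "
            f"τ = {pm}{self.stress_mean:.4g} ± {self.stress_sd:.2g} Pa"
        )


class RheologyCurve:
    """Viscosity–shear-rate measurements with an interpolant and fits.

    Parameters
    ----------
    measurements : DataFrame with columns
        ``sample_id, replicate, shear_rate_1_per_s, viscosity_pa_s``.
    log_space : interpolate in log10(shear rate) instead of linear
        shear rate (the measured grid is log-spaced; default is linear).
    """

    def __init__(self, measurements: pd.DataFrame, *, log_space: bool = False):
        need = {"shear_rate_1_per_s", "viscosity_pa_s"}
        if not need.issubset(measurements.columns):
            raise ValueError(f"measurements need columns {sorted(need)}")
        if (measurements["viscosity_pa_s"] <= 0).any():
            raise ValueError("viscosities must be positive")
        if (measurements["shear_rate_1_per_s"] <= 0).any():
            raise ValueError("shear rates must be positive")
        self.measurements = measurements.copy()
        # average all measurements at each shear-rate level first
        level = (
            measurements.groupby("shear_rate_1_per_s")["viscosity_pa_s"]
            .mean()
            .sort_index()
        )
        self._rates = level.index.to_numpy(dtype=float)
        self._visc = level.to_numpy(dtype=float)
        if self._rates.size < 2:
            raise ValueError("need at least 2 distinct shear-rate levels")
        self.log_space = log_space
        self._fit: dict | None = None

    @property
    def span(self) -> tuple[float, float]:
        return float(self._rates[0]), float(self._rates[-1])

    def viscosity(self, shear_rate: float, *, strict: bool = True) -> float:
        """Piecewise-linear interpolated viscosity at ``shear_rate`` (Pa·s).

        Outside the measured span, strict mode raises; otherwise the
        nearest endpoint viscosity is returned with a warning.
        """
        lo, hi = self.span
        if not lo <= shear_rate <= hi:
            if strict:
                raise ValueError(
                    f"shear rate {shear_rate:g} outside measured span [{lo:g}, {hi:g}]"
                )
            warnings.warn(
                f"extrapolating viscosity at {shear_rate:g} 1/s by nearest point",
                RuntimeWarning,
                stacklevel=2,
            )
        x, xs = (np.log10(shear_rate), np.log10(self._rates)) if self.log_space else (
            shear_rate,
            self._rates,
        )
        return float(np.interp(x, xs, self._visc))

    def fit(self, model: str = "power_law") -> dict:
        """Fit a constitutive model to the level-averaged curve.

        'power_law' fits η = K·γ̇ⁿ⁻¹ by log–log least squares; 'carreau'
        fits the 4(+1)-parameter Carreau law by nonlinear least squares.
        Returns the parameter dict and caches it for the annulus solvers.
        """
        if model == "power_law":
            slope, intercept = np.polyfit(np.log(self._rates), np.log(self._visc), 1)
            params = {"model": "power_law", "K": float(np.exp(intercept)), "n": float(slope + 1.0)}
        elif model == "carreau":
            p0 = [self._visc[0] * 2, self._visc[-1] * 0.9, 0.1, 0.5]
            popt, _ = curve_fit(
                lambda g, eta0, eta_inf, lam, n: carreau_viscosity(g, eta0, eta_inf, lam, 2.0, n),
                self._rates,
                self._visc,
                p0=p0,
                maxfev=20000,
            )
            params = {
                "model": "carreau",
                "eta0": float(popt[0]),
                "eta_inf": float(popt[1]),
                "lam": float(popt[2]),
                "a": 2.0,
                "n": float(popt[3]),
            }
        else:
            raise ValueError(f"unknown model {model!r}")
        self._fit = params
        return params

    def model_viscosity(self, shear_rate):
        """Viscosity from the cached fitted model (fits power law if absent)."""
        if self._fit is None:
            self.fit("power_law")
        p = self._fit
        if p["model"] == "power_law":
            return power_law_viscosity(shear_rate, p["K"], p["n"])
        return carreau_viscosity(shear_rate, p["eta0"], p["eta_inf"], p["lam"], p["a"], p["n"])


def interpolate_viscosity(curve: RheologyCurve, shear_rate: float, *, strict: bool = True) -> float:
    """Linearly interpolated viscosity at ``shear_rate`` (Pa·s)."""
    return curve.viscosity(shear_rate, strict=strict)


def shear_stress(shear_rate: float, curve: RheologyCurve, *, strict: bool = True) -> float:
    """Wall shear stress τ(γ̇) = γ̇ · η(γ̇) in Pa."""
    if shear_rate < 0:
        raise ValueError("shear rate must be >= 0")
    if shear_rate == 0.0:
        return 0.0
    return shear_rate * curve.viscosity(shear_rate, strict=strict)


def daily_stress_with_error(
    shear_rates, viscosities, *, mode: str = "steady"
) -> ShearCondition:
    """Daily shear-stress summary with propagated uncertainty.

    The reported stress is the product of the sample means,
    ``τ = mean(γ̇)·mean(η)``, and its standard deviation follows the
    first-order propagation for independent factors,
    ``σ_τ = sqrt((mean(η)·σ_γ̇)² + (mean(γ̇)·σ_η)²)``.
    """
    g = np.asarray(shear_rates, dtype=float).ravel()
    e = np.asarray(viscosities, dtype=float).ravel()
    if g.size == 0 or e.size == 0:
        raise ValueError("need at least one sample of each quantity")
    g_m, e_m = g.mean(), e.mean()
    g_s = g.std(ddof=1) if g.size > 1 else 0.0
    e_s = e.std(ddof=1) if e.size > 1 else 0.0
    tau = g_m * e_m
    tau_s = float(np.hypot(e_m * g_s, g_m * e_s))
    return ShearCondition(mode, g_m, g_s, e_m, e_s, tau, tau_s)


def fit_power_law(measurements: pd.DataFrame) -> dict:
    """Convenience: power-law (K, n) fit from a raw measurement table."""
    return RheologyCurve(measurements).fit("power_law")


def fit_carreau(measurements: pd.DataFrame) -> dict:
    return RheologyCurve(measurements).fit("carreau")


def read_rheology_csv(path, **kwargs) -> RheologyCurve:
    return RheologyCurve(pd.read_csv(path), **kwargs)
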