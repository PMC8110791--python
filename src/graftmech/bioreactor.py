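"""Annular-flow bioreactor design: forward wall-shear solves and the
inverse problem of choosing a pressure gradient for a target stress.

The culture chamber is a concentric annulus: the construct's outer
surface (radius R1) faces the gap to the glass tube's inner wall
(radius R2), and a constant axial pressure gradient drives laminar
flow.  For a Newtonian medium the classical annular Poiseuille solution
applies; for the shear-thinning X-gum-enriched medium a generalized-
Newtonian solve inverts the fitted flow curve τ(γ̇) = γ̇·η(γ̇) point by
point along the stress profile τ(r) = (G/2)(r_m² − r²)/r, with the
zero-stress radius r_m fixed by no-slip at both walls.

Oscillatory conditions (complete flow reversal at 1 Hz) are designed
quasi-statically: the gradient alternates sign as a square wave and the
instantaneous profile is assumed fully developed.  The Womersley number
of the gap is reported as a validity diagnostic for that assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import brentq

from .metrics import WssSeries
from .rheology import RheologyCurve, ShearCondition

__all__ = [
    "AnnulusGeometry",
    "DesignResult",
    "annulus_velocity_newtonian",
    "annulus_wall_shear_generalized",
    "design_for_target",
]

#: Default construct outer radius: 3 mm inner-diameter scaffold with a
#: 200 µm wall, mounted on silicone tubing.
DEFAULT_R1 = 1.7e-3
#: Default radial gap to the glass tube wall (config, not a measured value).
DEFAULT_GAP = 2.0e-3

MEDIUM_DENSITY = 1000.0  # kg/m^3


@dataclass(frozen=True)
class AnnulusGeometry:
    """Concentric annulus: construct surface R1 < glass wall R2 (m)."""

    inner_radius: float = DEFAULT_R1
    outer_radius: float = DEFAULT_R1 + DEFAULT_GAP
    length: float = 15.0e-3

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < R1 < R2")
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def gap(self) -> float:
        return self.outer_radius - self.inner_radius


def annulus_velocity_newtonian(
    geometry: AnnulusGeometry,
    pressure_gradient: float,
    viscosity: float,
    *,
    n_radial: int = 201,
    density: float = MEDIUM_DENSITY,
):
    """Analytic Newtonian annular Poiseuille solution.

    ``pressure_gradient`` G = −dp/dz (Pa/m, positive drives +z flow).
    Returns a dict with the radial grid, axial velocity profile,
    volumetric flow rate and the wall shear rates |du/dr| at R1 and R2.
    Emits a warning when the gap Reynolds number exceeds 2000 (laminar
    assumption questionable).
    """
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    R1, R2 = geometry.inner_radius, geometry.outer_radius
    G = pressure_gradient
    r = np.linspace(R1, R2, n_radial)
    log_ratio = np.log(R2 / R1)
    u = (G / (4.0 * viscosity)) * (R2**2 - r**2 + (R2**2 - R1**2) * np.log(r / R2) / log_ratio)

    def dudr(rr):
        return (G / (4.0 * viscosity)) * (-2.0 * rr + (R2**2 - R1**2) / (rr * log_ratio))

    Q = (np.pi * G / (8.0 * viscosity)) * (
        R2**4 - R1**4 - (R2**2 - R1**2) ** 2 / log_ratio
    )
    gamma1, gamma2 = abs(dudr(R1)), abs(dudr(R2))
    area = np.pi * (R2**2 - R1**2)
    if area > 0 and Q != 0:
        u_mean = abs(Q) / area
        reynolds = density * u_mean * 2.0 * geometry.gap / viscosity
        if reynolds > 2000:
            warnings.warn(
                f"gap Reynolds number {reynolds:.0f} > 2000: laminar assumption questionable",
                RuntimeWarning,
                stacklevel=2,
            )
    return {
        "r": r,
        "u": u,
        "flow_rate": float(Q),
        "wall_shear_rate_inner": float(gamma1),
        "wall_shear_rate_outer": float(gamma2),
        "wall_shear_stress_inner": float(viscosity * gamma1),
        "wall_shear_stress_outer": float(viscosity * gamma2),
    }


# ---------------------------------------------------------------------------
# Generalized-Newtonian annulus


def _invert_flow_curve(curve: RheologyCurve, tau: np.ndarray) -> np.ndarray:
    """Solve γ̇ from τ = γ̇·η(γ̇) element-wise for the fitted model."""
    tau = np.asarray(tau, dtype=float)
    if curve._fit is None:
        curve.fit("power_law")
    p = curve._fit
    if p["model"] == "power_law":
        return (tau / p["K"]) ** (1.0 / p["n"])
    # generic monotone flow curve: log-log table guess + Newton polish
    g_tab = np.logspace(-6, 7, 1301)
    t_tab = g_tab * np.asarray(curve.model_viscosity(g_tab))
    g = np.exp(np.interp(np.log(np.maximum(tau, 1e-300)), np.log(t_tab), np.log(g_tab)))
    for _ in range(40):
        f = g * curve.model_viscosity(g) - tau
        h = np.maximum(1e-8 * g, 1e-12)
        df = (
            (g + h) * curve.model_viscosity(g + h) - (g - h) * curve.model_viscosity(g - h)
        ) / (2 * h)
        step = f / df
        g_new = np.clip(g - step, g * 0.2, g * 5.0)
        if np.all(np.abs(g_new - g) <= 1e-14 * np.maximum(g, 1e-300)):
            g = g_new
            break
        g = g_new
    return np.where(tau == 0.0, 0.0, g)


def annulus_wall_shear_generalized(
    geometry: AnnulusGeometry,
    pressure_gradient: float,
    curve: RheologyCurve,
    *,
    n_radial: int = 801,
):
    """Generalized-Newtonian annular solve via the stress profile.

    Momentum balance gives τ(r) = (G/2)(r_m² − r²)/r with the zero-stress
    radius r_m the single unknown, fixed by requiring no slip at both
    walls: the velocity built up by integrating γ̇ from R1 must return to
    zero at R2.  γ̇ is obtained by inverting the fitted constitutive law
    at each radius.  Returns inner/outer wall shear rate and stress and
    the converged r_m.
    """
    if pressure_gradient <= 0:
        raise ValueError("pressure gradient must be positive")
    R1, R2 = geometry.inner_radius, geometry.outer_radius
    G = pressure_gradient

    def tau_at(r, rm):
        return 0.5 * G * (rm**2 - r**2) / r

    def residual(rm):
        r_lo = np.linspace(R1, rm, n_radial)
        r_hi = np.linspace(rm, R2, n_radial)
        g_lo = _invert_flow_curve(curve, tau_at(r_lo, rm))
        g_hi = _invert_flow_curve(curve, -tau_at(r_hi, rm))
        return simpson(g_lo, x=r_lo) - simpson(g_hi, x=r_hi)

    eps = 1e-9 * (R2 - R1)
    try:
        rm = brentq(residual, R1 + eps, R2 - eps, xtol=1e-15, rtol=1e-14)
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"no-slip shooting failed: residual({R1 + eps:g}) = {residual(R1 + eps):.3e}, "
            f"residual({R2 - eps:g}) = {residual(R2 - eps):.3e}"
        ) from exc
    tau1 = float(tau_at(R1, rm))
    tau2 = float(-tau_at(R2, rm))
    g1 = float(_invert_flow_curve(curve, np.array([tau1]))[0])
    g2 = float(_invert_flow_curve(curve, np.array([tau2]))[0])
    return {
        "zero_stress_radius": float(rm),
        "wall_shear_rate_inner": g1,
        "wall_shear_rate_outer": g2,
        "wall_shear_stress_inner": tau1,
        "wall_shear_stress_outer": tau2,
    }


# ---------------------------------------------------------------------------
# Inverse design


@dataclass(frozen=True)
class DesignResult:
    """Operating point meeting a target inner-wall shear stress."""

    pressure_gradient: float  # Pa/m
    geometry: AnnulusGeometry
    condition: ShearCondition
    womersley: float
    frequency_hz: float = 0.0

    def wss_series(self, n_samples: int = 401, period: float | None = None) -> WssSeries:
        """Axial WSS series at the construct surface for metric checks.

        Steady mode gives a constant series; oscillatory mode a 1 Hz
        square wave of complete flow reversal (zero crossings carry
        τ = 0 on the grid, so the signed cycle integral vanishes
        exactly).
        """
        if self.frequency_hz > 0:
            T = period if period is not None else 1.0 / self.frequency_hz
            t = np.linspace(0.0, T, n_samples)
            x = np.sin(2.0 * np.pi * t / T)
            sgn = np.where(np.abs(x) < 1e-12, 0.0, np.sign(x))
            tau = self.condition.stress_mean * sgn
        else:
            T = period if period is not None else 1.0
            t = np.linspace(0.0, T, n_samples)
            tau = np.full(n_samples, self.condition.stress_mean)
        vecs = np.zeros((n_samples, 1, 3))
        vecs[:, 0, 0] = tau
        return WssSeries(np.array(["construct_surface"]), t, vecs, period=T)


def design_for_target(
    target_stress: float,
    geometry: AnnulusGeometry,
    curve: RheologyCurve,
    mode: str = "steady",
    *,
    frequency_hz: float = 1.0,
    density: float = MEDIUM_DENSITY,
) -> DesignResult:
    """Find the pressure gradient producing ``target_stress`` at R1.

    ``mode='steady'`` solves for a constant gradient; ``'oscillatory'``
    returns the amplitude of a square-alternating gradient (complete
    flow reversal at ``frequency_hz``, quasi-static).  Raises a
    ``ValueError`` reporting the achievable bounds when the target is
    outside the bracketing range.
    """
    if mode not in ("steady", "oscillatory"):
        raise ValueError("mode must be 'steady' or 'oscillatory'")
    if target_stress <= 0:
        raise ValueError("target stress must be positive")

    def inner_tau(G):
        return annulus_wall_shear_generalized(geometry, G, curve)["wall_shear_stress_inner"]

    G_lo, G_hi = 1.0, 1.0e4
    while inner_tau(G_hi) < target_stress and G_hi < 1e12:
        G_hi *= 10.0
    while inner_tau(G_lo) > target_stress and G_lo > 1e-9:
        G_lo /= 10.0
    lo_tau, hi_tau = inner_tau(G_lo), inner_tau(G_hi)
    if not lo_tau <= target_stress <= hi_tau:
        raise ValueError(
            f"target {target_stress:g} Pa outside achievable range "
            f"[{lo_tau:.3g}, {hi_tau:.3g}] Pa for this geometry/rheology"
        )
    G = brentq(lambda g: inner_tau(g) - target_stress, G_lo, G_hi, rtol=1e-13)
    sol = annulus_wall_shear_generalized(geometry, G, curve)
    gamma = sol["wall_shear_rate_inner"]
    eta = sol["wall_shear_stress_inner"] / gamma if gamma > 0 else float("nan")
    osc = mode == "oscillatory"
    omega = 2.0 * np.pi * frequency_hz if osc else 0.0
    womersley = (
        0.5 * geometry.gap * np.sqrt(omega * density / eta) if osc else 0.0
    )
    condition = ShearCondition(
        "oscillatory" if osc else "steady",
        gamma,
        0.0,
        eta,
        0.0,
        sol["wall_shear_stress_inner"],
        0.0,
    )
    return DesignResult(
        pressure_gradient=float(G),
        geometry=geometry,
        condition=condition,
        womersley=float(womersley),
        frequency_hz=frequency_hz if osc else 0.0,
    )
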