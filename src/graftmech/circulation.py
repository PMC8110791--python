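"""0D lumped-parameter surrogate of an arteriovenous-graft (AVG) loop.

The network stands in for a full 3D CFD/FSI solve at desk scale.  A
prescribed pulsatile inlet flow enters through a proximal arterial
segment, reaches the arterial anastomosis node, passes through the graft
to the venous anastomosis node and leaves through the proximal venous
segment to a zero-pressure outlet.  Each anastomosis node additionally
feeds a three-element Windkessel (R-C-R) terminal representing the
distal arterial and distal venous beds — six lumped elements in total.
Segment resistances follow Poiseuille, ``R = 8 μ L / (π r⁴)``; segment
wall shear stress is recovered quasi-statically from the flow waveform
as ``τ(t) = 4 μ Q(t) / (π r³)``.

Default geometry uses the study vessel calibers (artery 6.6 mm, vein
7.7 mm, graft 6 mm diameter); terminal element values are plausible
defaults for an upper-limb access circulation, not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .metrics import WssSeries
from .synth import InletWaveform, gen_inlet_waveform

__all__ = [
    "LumpedElement",
    "VesselSegment",
    "WindkesselTerminal",
    "CirculationNetwork",
    "WaveformSet",
    "build_default_network",
    "simulate",
    "segment_wss",
    "ConvergenceError",
]

BLOOD_DENSITY = 1060.0  # kg/m^3
BLOOD_KINEMATIC_VISCOSITY = 3.3e-6  # m^2/s, Newtonian blood assumption


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class LumpedElement:
    """Single 0D circuit element.

    kind: 'resistance' (Pa·s·m⁻³), 'compliance' (m³·Pa⁻¹) or
    'inertance' (Pa·s²·m⁻³).
    """

    kind: str
    value: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("resistance", "compliance", "inertance"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "inertance":
            if self.value < 0:
                raise ValueError("inertance must be >= 0")
        elif self.value <= 0:
            raise ValueError(f"{self.kind} must be > 0")


@dataclass(frozen=True)
class VesselSegment:
    """Straight vessel segment with a Poiseuille lumped representation."""

    name: str
    radius: float  # m
    length: float  # m

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError(f"segment {self.name}: non-positive geometry")

    def resistance(self, mu: float) -> float:
        return 8.0 * mu * self.length / (np.pi * self.radius**4)


@dataclass(frozen=True)
class WindkesselTerminal:
    """Three-element R-C-R terminal: proximal R1, capacitor C to ground,
    distal R2 to ground.  ``compliance=0`` degenerates to a series
    resistor R1+R2."""

    name: str
    r_proximal: float
    compliance: float
    r_distal: float

    def __post_init__(self) -> None:
        if self.r_proximal <= 0 or self.r_distal <= 0 or self.compliance < 0:
            raise ValueError(f"terminal {self.name}: invalid element values")

    @property
    def elements(self) -> tuple[LumpedElement, ...]:
        return (
            LumpedElement("resistance", self.r_proximal, f"{self.name}.R1"),
            LumpedElement("compliance", self.compliance, f"{self.name}.C")
            if self.compliance > 0
            else LumpedElement("inertance", 0.0, f"{self.name}.C(zero)"),
            LumpedElement("resistance", self.r_distal, f"{self.name}.R2"),
        )


@dataclass(frozen=True)
class CirculationNetwork:
    """AVG loop: artery-in → node A → graft → node V → vein-out (P=0),
    with distal-arterial and distal-venous Windkessels on nodes A and V."""

    artery: VesselSegment
    graft: VesselSegment
    vein: VesselSegment
    arterial_terminal: WindkesselTerminal
    venous_terminal: WindkesselTerminal
    inlet: InletWaveform
    kinematic_viscosity: float = BLOOD_KINEMATIC_VISCOSITY
    density: float = BLOOD_DENSITY

    @property
    def viscosity(self) -> float:
        """Dynamic viscosity μ = ν·ρ (Pa·s)."""
        return self.kinematic_viscosity * self.density

    def segment(self, name: str) -> VesselSegment:
        for seg in (self.artery, self.graft, self.vein):
            if seg.name == name:
                return seg
        raise KeyError(name)


@dataclass(frozen=True)
class WaveformSet:
    """Converged last-cycle waveforms: node pressures (Pa) and segment
    flows (m³/s) on a common time grid."""

    times: np.ndarray
    pressures: dict  # node name -> array
    flows: dict  # segment/terminal name -> array
    n_cycles_run: int = 0

    def flow_balance_residual(self) -> float:
        """Max relative node flow-balance residual (storage included)."""
        qa = self.flows["artery"] - self.flows["graft"] - self.flows["arterial_terminal"]
        qv = self.flows["graft"] - self.flows["vein"] - self.flows["venous_terminal"]
        scale = max(np.abs(self.flows["artery"]).mean(), 1e-30)
        return float(max(np.abs(qa).max(), np.abs(qv).max()) / scale)

    def pressure_frame(self):
        import pandas as pd

        rows = []
        for node, p in self.pressures.items():
            rows.append(pd.DataFrame({"time_s": self.times, "node": node, "pressure_pa": p}))
        return pd.concat(rows, ignore_index=True)

    def flow_frame(self):
        import pandas as pd

        rows = []
        for seg, q in self.flows.items():
            rows.append(pd.DataFrame({"time_s": self.times, "segment": seg, "flow_m3s": q}))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    # study vessel calibers; lengths are nominal access-loop dimensions
    "geometry": {
        "artery": {"diameter_m": 6.6e-3, "length_m": 0.10},
        "graft": {"diameter_m": 6.0e-3, "length_m": 0.30},
        "vein": {"diameter_m": 7.7e-3, "length_m": 0.20},
    },
    # terminal element values: plausible upper-limb defaults, NOT measured
    "terminals": {
        "arterial": {"r_proximal": 4.0e7, "compliance": 1.0e-9, "r_distal": 3.3e8},
        "venous": {"r_proximal": 8.0e7, "compliance": 2.0e-9, "r_distal": 4.0e8},
    },
    "blood": {"kinematic_viscosity_m2s": BLOOD_KINEMATIC_VISCOSITY, "density_kgm3": BLOOD_DENSITY},
    "inlet": {"mean_flow_lmin": 1.5, "pulsatility": 0.8, "harmonics": 3, "period_s": 1.0},
}


def build_default_network(config: dict | None = None) -> CirculationNetwork:
    """Build the AVG loop network from a (possibly partial) config dict.

    Missing keys fall back to :data:`DEFAULT_CONFIG`.  Raises
    ``ValueError`` on non-positive geometry.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    geo = cfg["geometry"]

    def seg(name: str) -> VesselSegment:
        g = geo[name]
        return VesselSegment(name, g["diameter_m"] / 2.0, g["length_m"])

    term = cfg["terminals"]
    inlet_cfg = cfg["inlet"]
    inlet = gen_inlet_waveform(
        mean_flow=inlet_cfg["mean_flow_lmin"] / 6.0e4,
        pulsatility=inlet_cfg["pulsatility"],
        harmonics=inlet_cfg["harmonics"],
        period=inlet_cfg["period_s"],
    )
    return CirculationNetwork(
        artery=seg("artery"),
        graft=seg("graft"),
        vein=seg("vein"),
        arterial_terminal=WindkesselTerminal("arterial_terminal", **term["arterial"]),
        venous_terminal=WindkesselTerminal("venous_terminal", **term["venous"]),
        inlet=inlet,
        kinematic_viscosity=cfg["blood"]["kinematic_viscosity_m2s"],
        density=cfg["blood"]["density_kgm3"],
    )


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _node_pressures(net: CirculationNetwork, q_in: float, pc_a: float, pc_v: float):
    """Solve the algebraic node system for (P_A, P_V) given capacitor states.

    Node A:  q_in = (P_A - P_V)/R_g + q_term_a(P_A)
    Node V:  (P_A - P_V)/R_g = P_V/R_v + q_term_v(P_V)
    where q_term = (P - Pc)/R1 for a compliant terminal and P/(R1+R2) for a
    zero-compliance one.
    """
    mu = net.viscosity
    Rg = net.graft.resistance(mu)
    Rv = net.vein.resistance(mu)
    ta, tv = net.arterial_terminal, net.venous_terminal

    # terminal admittance and source terms: q_term = g*P - s
    if ta.compliance > 0:
        ga, sa = 1.0 / ta.r_proximal, pc_a / ta.r_proximal
    else:
        ga, sa = 1.0 / (ta.r_proximal + ta.r_distal), 0.0
    if tv.compliance > 0:
        gv, sv = 1.0 / tv.r_proximal, pc_v / tv.r_proximal
    else:
        gv, sv = 1.0 / (tv.r_proximal + tv.r_distal), 0.0

    A = np.array(
        [
            [1.0 / Rg + ga, -1.0 / Rg],
            [1.0 / Rg, -(1.0 / Rg + 1.0 / Rv + gv)],
        ]
    )
    b = np.array([q_in + sa, -sv])
    pa, pv = np.linalg.solve(A, b)
    q_term_a = ga * pa - sa
    q_term_v = gv * pv - sv
    q_graft = (pa - pv) / Rg
    q_vein = pv / Rv
    return pa, pv, q_graft, q_vein, q_term_a, q_term_v


def _rhs(t, y, net: CirculationNetwork):
    pc_a, pc_v = y
    q_in = net.inlet(t)
    pa, pv, _, _, qta, qtv = _node_pressures(net, q_in, pc_a, pc_v)
    ta, tv = net.arterial_terminal, net.venous_terminal
    dpa = (qta - pc_a / ta.r_distal) / ta.compliance if ta.compliance > 0 else 0.0
    dpv = (qtv - pc_v / tv.r_distal) / tv.compliance if tv.compliance > 0 else 0.0
    return [dpa, dpv]


def simulate(
    network: CirculationNetwork,
    n_cycles: int = 30,
    dt: float | None = None,
    *,
    tol: float = 1e-3,
    initial_state: tuple[float, float] | None = None,
    require_convergence: bool = True,
) -> WaveformSet:
    """Integrate the network to a periodic state and return the last cycle.

    Cycles are integrated one period at a time with an adaptive
    stiff-capable solver (LSODA); convergence is declared when the
    cycle-to-cycle maximum node-pressure change drops below ``tol``
    (relative, default 0.1%).  ``dt`` sets the output sampling interval
    (default T/400) and must not exceed T/200.  With
    ``require_convergence=False`` the waveforms of cycle ``n_cycles`` are
    returned without a periodicity check (useful for transients such as
    capacitor discharge).
    """
    T = network.inlet.period
    if dt is None:
        dt = T / 400.0
    if dt > T / 200.0 + 1e-15:
        raise ValueError("dt must be <= T/200 for adequate cycle resolution")
    n_out = int(round(T / dt))
    t_eval = np.linspace(0.0, T, n_out + 1)

    y = np.array(initial_state if initial_state is not None else [0.0, 0.0], float)
    prev = None
    for cyc in range(1, n_cycles + 1):
        sol = solve_ivp(
            _rhs,
            (0.0, T),
            y,
            t_eval=t_eval,
            args=(network,),
            method="LSODA",
            rtol=1e-9,
            atol=1e-12,
        )
        if not sol.success:
            raise ConvergenceError(f"ODE solve failed in cycle {cyc}: {sol.message}")
        y = sol.y[:, -1]
        pa = np.empty(t_eval.size)
        pv = np.empty(t_eval.size)
        qg = np.empty(t_eval.size)
        qv = np.empty(t_eval.size)
        qta = np.empty(t_eval.size)
        qtv = np.empty(t_eval.size)
        q_in = np.array([network.inlet(t) for t in t_eval])
        for i, t in enumerate(t_eval):
            pa[i], pv[i], qg[i], qv[i], qta[i], qtv[i] = _node_pressures(
                network, q_in[i], sol.y[0, i], sol.y[1, i]
            )
        cur = np.vstack([pa, pv])
        converged = False
        if prev is not None:
            scale = max(np.abs(cur).max(), 1e-30)
            converged = np.abs(cur - prev).max() / scale < tol
        if converged or (not require_convergence and cyc == n_cycles):
            mu = network.viscosity
            p_inlet = pa + q_in * network.artery.resistance(mu)
            return WaveformSet(
                times=t_eval,
                pressures={
                    "inlet": p_inlet,
                    "arterial_anastomosis": pa,
                    "venous_anastomosis": pv,
                    "arterial_terminal_capacitor": sol.y[0],
                    "venous_terminal_capacitor": sol.y[1],
                },
                flows={
                    "artery": q_in,
                    "graft": qg,
                    "vein": qv,
                    "arterial_terminal": qta,
                    "venous_terminal": qtv,
                },
                n_cycles_run=cyc,
            )
        prev = cur
    raise ConvergenceError(
        f"no periodic state within {n_cycles} cycles "
        f"(last cycle-to-cycle change {np.abs(cur - prev).max() / max(np.abs(cur).max(), 1e-30):.3e} "
        f"vs tol {tol:g})"
    )


def segment_wss(waveforms: WaveformSet, network: CirculationNetwork, segment: str) -> WssSeries:
    """Quasi-static Poiseuille WSS series for one segment.

    ``τ(t) = 4 μ Q(t) / (π r³)`` directed along the segment axis (x̂), on
    one nominal surface element, directly consumable by
    :mod:`graftmech.metrics`.
    """
    seg = network.segment(segment)
    q = waveforms.flows[segment]
    tau = 4.0 * network.viscosity * q / (np.pi * seg.radius**3)
    vecs = np.zeros((waveforms.times.size, 1, 3))
    vecs[:, 0, 0] = tau
    return WssSeries(np.array([segment]), waveforms.times, vecs)
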