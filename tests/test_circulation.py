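"""0D circulation surrogate: oracles and conservation properties."""

import numpy as np
import pytest

from graftmech.circulation import (
    VesselSegment,
    build_default_network,
    segment_wss,
    simulate,
)
from graftmech.metrics import compute_osi, compute_tawss
from graftmech.synth import InletWaveform


def steady_network(mean_lmin=1.5, compliant=True):
    cfg = {"inlet": {"pulsatility": 0.0, "mean_flow_lmin": mean_lmin}}
    if not compliant:
        cfg["terminals"] = {
            "arterial": {"r_proximal": 4.0e7, "compliance": 0.0, "r_distal": 3.3e8},
            "venous": {"r_proximal": 8.0e7, "compliance": 0.0, "r_distal": 4.0e8},
        }
    return build_default_network(cfg)


def resistor_oracle(net, q_in):
    """Direct linear solve of the pure-resistor network (no dynamics)."""
    mu = net.viscosity
    Rg, Rv = net.graft.resistance(mu), net.vein.resistance(mu)
    ta, tv = net.arterial_terminal, net.venous_terminal
    Ra_t = ta.r_proximal + ta.r_distal
    Rv_t = tv.r_proximal + tv.r_distal
    A = np.array(
        [[1 / Rg + 1 / Ra_t, -1 / Rg], [1 / Rg, -(1 / Rg + 1 / Rv + 1 / Rv_t)]]
    )
    return np.linalg.solve(A, np.array([q_in, 0.0]))


class TestNetworkConstruction:
    def test_default_graft_radius(self):
        net = build_default_network()
        assert net.graft.radius == pytest.approx(3.0e-3)
        assert net.artery.radius == pytest.approx(3.3e-3)
        assert net.vein.radius == pytest.approx(3.85e-3)

    def test_poiseuille_radius_scaling(self):
        mu = 3.5e-3
        seg = VesselSegment("s", 3e-3, 0.1)
        half = VesselSegment("s", 1.5e-3, 0.1)
        assert half.resistance(mu) / seg.resistance(mu) == pytest.approx(16.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_default_network({"geometry": {"graft": {"diameter_m": -1.0}}})


class TestSimulate:
    def test_zero_compliance_matches_resistor_algebra(self):
        net = steady_network(compliant=False)
        waves = simulate(net, n_cycles=5)
        q_in = net.inlet(0.0)
        pa, pv = resistor_oracle(net, q_in)
        assert np.allclose(waves.pressures["arterial_anastomosis"], pa, rtol=1e-10)
        assert np.allclose(waves.pressures["venous_anastomosis"], pv, rtol=1e-10)

    def test_rc_discharge_closed_form(self):
        """Capacitor discharge after flow shutoff follows exp(-t/(R_eff C))."""
        cfg = {
            "terminals": {
                "arterial": {"r_proximal": 4.0e7, "compliance": 1.0e-9, "r_distal": 3.3e8},
                "venous": {"r_proximal": 8.0e7, "compliance": 0.0, "r_distal": 4.0e8},
            }
        }
        from dataclasses import replace

        net = build_default_network(cfg)
        net = replace(net, inlet=InletWaveform(0.0, 1.0, np.zeros(0), np.zeros(0)))
        p0 = 1000.0
        waves = simulate(net, n_cycles=1, require_convergence=False, initial_state=(p0, 0.0))
        # discharge path: R2 in parallel with (R1 + network-to-ground resistance)
        mu = net.viscosity
        Rg, Rv = net.graft.resistance(mu), net.vein.resistance(mu)
        tv = net.venous_terminal
        r_net = Rg + 1.0 / (1.0 / Rv + 1.0 / (tv.r_proximal + tv.r_distal))
        ta = net.arterial_terminal
        r_eff = 1.0 / (1.0 / ta.r_distal + 1.0 / (ta.r_proximal + r_net))
        expected = p0 * np.exp(-waves.times / (r_eff * ta.compliance))
        got = waves.pressures["arterial_terminal_capacitor"]
        assert np.allclose(got, expected, rtol=1e-6)

    def test_flow_conservation_residual(self):
        net = build_default_network()
        waves = simulate(net)
        assert waves.flow_balance_residual() < 1e-8

    def test_dt_refinement_stability(self):
        net = build_default_network()
        w1 = simulate(net, dt=net.inlet.period / 400)
        w2 = simulate(net, dt=net.inlet.period / 800)
        p1 = w1.pressures["arterial_anastomosis"]
        p2 = w2.pressures["arterial_anastomosis"][::2]
        assert np.max(np.abs(p1 - p2)) / np.max(np.abs(p1)) < 1e-3

    def test_dt_too_coarse_rejected(self):
        net = build_default_network()
        with pytest.raises(ValueError):
            simulate(net, dt=net.inlet.period / 100)


class TestSegmentWss:
    def test_zero_flow_zero_stress(self):
        net = steady_network()
        waves = simulate(net, n_cycles=5)
        waves.flows["graft"] = np.zeros_like(waves.flows["graft"])
        s = segment_wss(waves, net, "graft")
        assert np.all(s.vectors == 0.0)

    def test_poiseuille_wall_stress_value(self):
        """1 L/min through a 6 mm tube at 3.5e-3 Pa.s gives ~2.75 Pa."""
        mu, q, r = 3.5e-3, 1.667e-5, 3.0e-3
        tau = 4 * mu * q / (np.pi * r**3)
        assert tau == pytest.approx(2.75, abs=0.01)
        net = build_default_network({"blood": {"kinematic_viscosity_m2s": mu / 1060.0}})
        waves = simulate(net, n_cycles=10)
        waves.flows["graft"] = np.full_like(waves.flows["graft"], q)
        s = segment_wss(waves, net, "graft")
        assert s.vectors[0, 0, 0] == pytest.approx(tau, rel=1e-12)

    def test_full_reversal_gives_max_osi(self):
        net = build_default_network()
        waves = simulate(net)
        t = waves.times
        T = net.inlet.period
        waves.flows["graft"] = 1e-5 * np.sin(2 * np.pi * t / T)
        s = segment_wss(waves, net, "graft")
        assert compute_osi(s)[0] == pytest.approx(0.5, abs=1e-9)

    def test_graft_tawss_physiological_range(self):
        """Pulsatile 1-2 L/min through the 6 mm graft: TAWSS of a few Pa."""
        for lmin in (1.0, 2.0):
            net = build_default_network({"inlet": {"mean_flow_lmin": lmin}})
            waves = simulate(net)
            tawss = compute_tawss(segment_wss(waves, net, "graft"))[0]
            assert 2.0 <= tawss <= 8.0
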