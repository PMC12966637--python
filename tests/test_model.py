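"""Circuit building blocks: activation, elastance, valve/shunt laws and
the ODE right-hand side, checked against closed forms, a hand-computed
balance evaluation and the exact conservation identity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shuntsim import (
    activation,
    chamber_pressure,
    circuit_rhs,
    conservation_residual,
    elastance,
    shunt_flow,
    valve_flow,
)
from shuntsim.model import NonFiniteStateError, make_rhs
from shuntsim.params import STATE_NAMES, ValveParams


@pytest.mark.parametrize("chamber", ["la", "lv", "ra", "rv"])
def test_activation_ramp_boundaries(chamber, presets):
    """0 at contraction onset, 1 at its end, 1/2 at the half-cosine
    midpoint, and 0 again after relaxation completes."""
    m = presets["vsd"]
    ch = getattr(m, chamber)
    assert activation(ch.t_contract, ch, m.thb) == pytest.approx(0.0, abs=1e-12)
    assert activation(ch.t_contract + ch.d_contract, ch, m.thb) == pytest.approx(1.0)
    assert activation(ch.t_contract + ch.d_contract / 2, ch, m.thb) == pytest.approx(0.5)
    assert activation(ch.t_relax + ch.d_relax, ch, m.thb) == pytest.approx(0.0, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(t=st.floats(-100.0, 100.0), k=st.integers(-5, 5))
def test_activation_periodic_and_bounded(t, k):
    """activation(t) = activation(t + k·THB) and stays within [0, 1],
    including for relaxation windows that wrap past the cycle end."""
    from shuntsim import load_preset

    m = load_preset("vsd").params
    for name in ("la", "lv", "ra", "rv"):
        ch = getattr(m, name)
        a = activation(t, ch, m.thb)
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(activation(t + k * m.thb, ch, m.thb), abs=1e-9)


def test_elastance_bounds_and_examples(presets):
    """Passive floor and active ceiling of the right ventricle."""
    rv = presets["vsd"].rv
    thb = presets["vsd"].thb
    t_quiet = 0.78  # after relaxation, before next contraction
    assert elastance(t_quiet, rv, thb) == pytest.approx(0.07)
    t_peak = rv.t_contract + rv.d_contract
    assert elastance(t_peak, rv, thb) == pytest.approx(0.6683 + 0.07)
    t = np.linspace(0, thb, 400)
    e = elastance(t, rv, thb)
    assert np.all(e >= rv.eb - 1e-12) and np.all(e <= rv.eb + rv.ea + 1e-12)


def test_constant_elastance_without_active_component(presets):
    ch = presets["vsd"].la.model_copy(update={"ea": 0.0})
    t = np.linspace(-1, 2, 50)
    assert np.allclose(elastance(t, ch, 0.8), ch.eb)


def test_chamber_pressure_linear_law():
    assert chamber_pressure(50.0, 1.0, 50.0) == 0.0
    assert chamber_pressure(60.0, 1.0, 50.0) == pytest.approx(10.0)
    assert chamber_pressure(100.0, 0.07, 0.0) == pytest.approx(7.0)
    assert chamber_pressure(40.0, 1.0, 50.0) < 0


def test_valve_flow_diode_law():
    v = ValveParams(rmin=0.0075, rmax=75006.2)
    assert valve_flow(11.0, 10.0, v) == pytest.approx(1 / 0.0075)  # 133.33 mL/s
    assert valve_flow(10.0, 10.0, v) == 0.0
    assert valve_flow(0.0, 10.0, v) == pytest.approx(-10 / 75006.2)  # leak


def test_valve_flow_continuity_and_rectification():
    """Both branches vanish at zero gradient; reverse flow is smaller by
    the rmax/rmin ratio (seven orders of magnitude)."""
    v = ValveParams(rmin=0.0075, rmax=75006.2)
    eps = 1e-9
    assert abs(valve_flow(eps, 0.0, v)) < 1e-6
    assert abs(valve_flow(-eps, 0.0, v)) < 1e-6
    dp = np.linspace(-20, 20, 81)
    q = valve_flow(dp, 0.0, v)
    assert np.all(np.sign(q) == np.sign(dp))
    ratio = valve_flow(1.0, 0.0, v) / -valve_flow(-1.0, 0.0, v)
    assert ratio == pytest.approx(75006.2 / 0.0075)


def test_shunt_flow_resistive_branch():
    assert shunt_flow(10.0, 10.0, 0.0031) == 0.0
    assert shunt_flow(11.0, 10.0, 0.0031) == pytest.approx(1 / 0.0031)  # 322.58 mL/s
    assert shunt_flow(3.0, 8.0, 0.0031) < 0  # right-to-left is negative
    assert shunt_flow(60.0, 10.0, None) == 0.0
    assert shunt_flow(60.0, 10.0, "closed") == 0.0


def test_rhs_hand_computed_fixture(presets):
    """The 12 balance equations at one fixed state, VSD scenario,
    t = 0.1 s, against an independent explicit evaluation."""
    m = presets["vsd"]
    y = np.array([60.0, 120.0, 70.0, 130.0, 85.0, 6.0, 20.0, 9.0,
                  10.0, 20.0, 30.0, 40.0])
    # --- independent evaluation, written out from the circuit ---------
    thb = 0.8
    a_la = 0.5 * (1 + math.cos(math.pi * (0.1 - 0.72 + thb) / (0.8 * thb)))  # falling
    a_lv = 0.5 * (1 - math.cos(math.pi * 0.1 / (0.35 * thb)))                # rising
    a_ra = 0.5 * (1 + math.cos(math.pi * (0.1 - 0.72 + thb) / (0.7 * thb)))  # falling
    a_rv = 0.5 * (1 - math.cos(math.pi * 0.1 / (0.3 * thb)))                 # rising
    p_la = (0.209 + 0.2273 * a_la) * 60.0
    p_lv = (0.10 + 3.0391 * a_lv) * 120.0
    p_ra = (0.0636 + 0.0429 * a_ra) * 70.0
    p_rv = (0.07 + 0.6683 * a_rv) * 130.0
    def diode(dp):
        return dp / 0.0075 if dp > 0 else dp / 75006.2
    q_mv = diode(p_la - p_lv)
    q_av = diode(p_lv - 85.0)
    q_tv = diode(p_ra - p_rv)
    q_pv = diode(p_rv - 20.0)
    q_vsd = (p_lv - p_rv) / 0.038
    expected = [
        40.0 - q_mv,                        # dV_LA (no ASD branch)
        q_mv - q_av - q_vsd,                # dV_LV
        20.0 - q_tv,                        # dV_RA
        q_tv - q_pv + q_vsd,                # dV_RV
        (q_av - 10.0) / 0.96,               # dp systemic arteries
        (10.0 - 20.0) / 60.0,               # dp systemic veins
        (q_pv - 30.0) / 5.0,                # dp pulmonary arteries
        (30.0 - 40.0) / 16.0,               # dp pulmonary veins
        (85.0 - 6.0 - 0.588 * 10.0) / 5e-3,  # dQ systemic arteries
        (6.0 - p_ra - 0.352 * 20.0) / 5e-4,  # dQ systemic veins
        (20.0 - 9.0 - 0.104 * 30.0) / 5e-4,  # dQ pulmonary arteries
        (9.0 - p_la - 0.0105 * 40.0) / 5e-4,  # dQ pulmonary veins
    ]
    # ------------------------------------------------------------------
    np.testing.assert_allclose(circuit_rhs(0.1, y, m), expected, rtol=1e-12)


def test_rhs_equilibrium_state_is_stationary(presets):
    """Uniform pressure, zero flows, volumes matching the passive
    pressure during the common quiescent phase: all derivatives vanish."""
    m = presets["asd_vsd"]
    t = 0.61  # every chamber is passive here
    p = 10.0
    y = np.array([p / m.la.eb, p / m.lv.eb, p / m.ra.eb, p / m.rv.eb,
                  p, p, p, p, 0.0, 0.0, 0.0, 0.0])
    np.testing.assert_allclose(circuit_rhs(t, y, m), np.zeros(12), atol=1e-12)


@pytest.mark.parametrize("scenario", ["vsd", "asd", "asd_vsd"])
def test_conservation_identity(scenario, presets):
    """Σ dV/dt + Σ C·dp/dt = 0 to 1e-10 of the largest term, for random
    physiological-magnitude states at random times."""
    m = presets[scenario]
    rng = np.random.default_rng(42)
    for _ in range(200):
        y = np.concatenate([
            rng.uniform(5, 250, 4),     # volumes
            rng.uniform(1, 130, 4),     # pressures
            rng.uniform(-200, 400, 4),  # flows
        ])
        t = rng.uniform(0, 10 * m.thb)
        dy = circuit_rhs(t, y, m)
        caps = [m.arsys.c, m.vensys.c, m.arpul.c, m.venpul.c]
        terms = np.concatenate([dy[:4], np.array(caps) * dy[4:8]])
        assert abs(conservation_residual(t, y, m)) <= 1e-10 * np.max(np.abs(terms))


def test_closed_shunt_equals_huge_resistance(presets):
    """A closed defect and a 1e6 mmHg·s/mL branch give the same RHS to
    1e-3 relative on every component."""
    m_closed = presets["vsd"].with_shunts(rasd=None)
    m_huge = presets["vsd"].with_shunts(rasd=1e6)
    rng = np.random.default_rng(7)
    for _ in range(20):
        y = np.concatenate([
            rng.uniform(20, 200, 4), rng.uniform(2, 120, 4), rng.uniform(-100, 300, 4)
        ])
        t = rng.uniform(0, 0.8)
        a = circuit_rhs(t, y, m_closed)
        b = circuit_rhs(t, y, m_huge)
        scale = np.max(np.abs(a))
        np.testing.assert_allclose(a, b, rtol=1e-3, atol=1e-3 * scale)


def test_rhs_rejects_non_finite_state(presets):
    m = presets["vsd"]
    y = np.ones(12)
    y[6] = np.nan
    with pytest.raises(NonFiniteStateError, match=STATE_NAMES[6]):
        circuit_rhs(0.2, y, m)


def test_fast_rhs_matches_public_rhs(presets):
    """The integrator closure and the public array API agree exactly."""
    m = presets["asd_vsd"]
    rhs = make_rhs(m)
    rng = np.random.default_rng(3)
    for _ in range(10):
        y = np.concatenate([
            rng.uniform(20, 200, 4), rng.uniform(2, 120, 4), rng.uniform(-100, 300, 4)
        ])
        t = rng.uniform(0, 0.8)
        np.testing.assert_array_equal(np.array(rhs(t, y)), circuit_rhs(t, y, m))
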