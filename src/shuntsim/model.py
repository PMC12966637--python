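"""Electric-analogue circuit: elastances, valve law, shunt branches and
the 12-equation ODE right-hand side.

State ordering follows :data:`shuntsim.params.STATE_NAMES`: four chamber
volumes, four compartment pressures, four compartment flows. The loop is
closed — total blood volume (chamber volumes plus C·p stored in each
compartment) is conserved exactly by construction, which the
``conservation_residual`` helper makes checkable.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Union

import numpy as np

from .params import (
    DERIVED_NAMES,
    STATE_NAMES,
    ChamberParams,
    ModelParams,
    ValveParams,
)


class NonFiniteStateError(RuntimeError):
    """Raised when the integrator hands the RHS a NaN/Inf state."""

    def __init__(self, name: str, value: float, t: float):
        self.state_name = name
        self.time = t
        super().__init__(f"non-finite state variable {name}={value} at t={t:.6f} s")


def activation(t, ch: ChamberParams, thb: float):
    """Dimensionless activation in [0, 1] of a chamber at time ``t``.

    Rises 0→1 over ``[t_contract, t_contract + d_contract]`` and falls
    1→0 over ``[t_relax, t_relax + d_relax]`` with half-cosine ramps;
    zero in the quiescent phase. All intervals are taken modulo ``thb``
    (relaxation windows may wrap past the cycle end). Accepts scalars or
    arrays.
    """
    t = np.asarray(t, dtype=float)
    tau_c = (t - ch.t_contract) % thb
    tau_r = (t - ch.t_relax) % thb
    rising = tau_c < ch.d_contract
    falling = ~rising & (tau_r < ch.d_relax)
    a = np.where(
        rising,
        0.5 * (1.0 - np.cos(np.pi * tau_c / ch.d_contract)),
        np.where(falling, 0.5 * (1.0 + np.cos(np.pi * tau_r / ch.d_relax)), 0.0),
    )
    return a if a.ndim else float(a)


def elastance(t, ch: ChamberParams, thb: float):
    """Instantaneous elastance E(t) = eb + ea·activation(t), mmHg/mL."""
    return ch.eb + ch.ea * activation(t, ch, thb)


def chamber_pressure(v, e, v0: float = 0.0):
    """Linear elastance pressure law p = E·(V − V0), mmHg."""
    return e * (v - v0)


def valve_flow(p_up, p_down, valve: ValveParams):
    """Diode-with-leak valve flow, mL/s.

    Forward gradient drains through ``rmin``, reverse through ``rmax``;
    both branches vanish at zero gradient, so the law is continuous.
    """
    dp = np.asarray(p_up, dtype=float) - np.asarray(p_down, dtype=float)
    q = np.where(dp > 0, dp / valve.rmin, dp / valve.rmax)
    return q if q.ndim else float(q)


def shunt_flow(p_left, p_right, r: Optional[Union[float, str]]):
    """Flow through a resistive septal defect, mL/s; positive is
    left-to-right. ``r`` of ``None``/'closed' means no defect (zero flow)."""
    if r is None or (isinstance(r, str) and r.lower() == "closed"):
        return 0.0 * (np.asarray(p_left, dtype=float) - np.asarray(p_right, dtype=float))
    dp = np.asarray(p_left, dtype=float) - np.asarray(p_right, dtype=float)
    q = dp / r
    return q if q.ndim else float(q)


def make_rhs(m: ModelParams, check_finite: bool = True):
    """Build a fast ``f(t, y) -> dy/dt`` closure for the integrator.

    All parameters are captured as plain floats; the returned function
    performs scalar arithmetic only, which keeps stiff integration of
    the discontinuous valve law affordable.
    """
    thb = m.thb
    chambers = []
    for name in ("la", "lv", "ra", "rv"):
        ch = getattr(m, name)
        chambers.append(
            (ch.ea, ch.eb, ch.v0, ch.t_contract, ch.d_contract, ch.t_relax, ch.d_relax)
        )
    (la, lv, ra, rv) = chambers
    rmin_mv, rmax_mv = m.mv.rmin, m.mv.rmax
    rmin_av, rmax_av = m.av.rmin, m.av.rmax
    rmin_tv, rmax_tv = m.tv.rmin, m.tv.rmax
    rmin_pv, rmax_pv = m.pv.rmin, m.pv.rmax
    rasd, rvsd = m.shunts.rasd, m.shunts.rvsd
    r_as, c_as, l_as = m.arsys.r, m.arsys.c, m.arsys.l
    r_vs, c_vs, l_vs = m.vensys.r, m.vensys.c, m.vensys.l
    r_ap, c_ap, l_ap = m.arpul.r, m.arpul.c, m.arpul.l
    r_vp, c_vp, l_vp = m.venpul.r, m.venpul.c, m.venpul.l
    cos, pi = math.cos, math.pi

    def act(t, ch):
        ea, eb, v0, tc, dc, tr, dr = ch
        tau = (t - tc) % thb
        if tau < dc:
            return 0.5 * (1.0 - cos(pi * tau / dc))
        tau = (t - tr) % thb
        if tau < dr:
            return 0.5 * (1.0 + cos(pi * tau / dr))
        return 0.0

    def rhs(t, y):
        if check_finite and not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise NonFiniteStateError(STATE_NAMES[bad], y[bad], t)
        (v_la, v_lv, v_ra, v_rv,
         p_as, p_vs, p_ap, p_vp,
         q_as, q_vs, q_ap, q_vp) = y
        p_la = (la[1] + la[0] * act(t, la)) * (v_la - la[2])
        p_lv = (lv[1] + lv[0] * act(t, lv)) * (v_lv - lv[2])
        p_ra = (ra[1] + ra[0] * act(t, ra)) * (v_ra - ra[2])
        p_rv = (rv[1] + rv[0] * act(t, rv)) * (v_rv - rv[2])
        dp = p_la - p_lv
        q_mv = dp / rmin_mv if dp > 0 else dp / rmax_mv
        dp = p_lv - p_as
        q_av = dp / rmin_av if dp > 0 else dp / rmax_av
        dp = p_ra - p_rv
        q_tv = dp / rmin_tv if dp > 0 else dp / rmax_tv
        dp = p_rv - p_ap
        q_pv = dp / rmin_pv if dp > 0 else dp / rmax_pv
        q_asd = (p_la - p_ra) / rasd if rasd is not None else 0.0
        q_vsd = (p_lv - p_rv) / rvsd if rvsd is not None else 0.0
        return (
            q_vp - q_mv - q_asd,
            q_mv - q_av - q_vsd,
            q_vs - q_tv + q_asd,
            q_tv - q_pv + q_vsd,
            (q_av - q_as) / c_as,
            (q_as - q_vs) / c_vs,
            (q_pv - q_ap) / c_ap,
            (q_ap - q_vp) / c_vp,
            (p_as - p_vs - r_as * q_as) / l_as,
            (p_vs - p_ra - r_vs * q_vs) / l_vs,
            (p_ap - p_vp - r_ap * q_ap) / l_ap,
            (p_vp - p_la - r_vp * q_vp) / l_vp,
        )

    return rhs


def circuit_rhs(t: float, y, m: ModelParams) -> np.ndarray:
    """Time derivative of the 12-component circuit state.

    Chamber volume balances (mitral/aortic/tricuspid/pulmonary valve
    flows plus the ASD and VSD branches), capacitor pressure balances
    C·dp/dt = inflow − outflow, and inductor flow balances
    L·dQ/dt = Δp − R·Q, with the systemic veins discharging into the
    right atrium and the pulmonary veins into the left atrium.

    Raises :class:`NonFiniteStateError` if any state component is
    NaN/Inf, identifying the offending variable and time.
    """
    y = np.asarray(y, dtype=float)
    return np.array(make_rhs(m)(t, y))


def derived_signals(
    t, y, m: ModelParams
) -> Dict[str, np.ndarray]:
    """Chamber pressures, valve flows and shunt flows for state samples.

    ``t`` is a scalar or (n,) array; ``y`` is (12,) or (12, n).
    Returns a dict keyed by :data:`shuntsim.params.DERIVED_NAMES`.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (12, n)
    p_la = chamber_pressure(y[0], elastance(t, m.la, m.thb), m.la.v0)
    p_lv = chamber_pressure(y[1], elastance(t, m.lv, m.thb), m.lv.v0)
    p_ra = chamber_pressure(y[2], elastance(t, m.ra, m.thb), m.ra.v0)
    p_rv = chamber_pressure(y[3], elastance(t, m.rv, m.thb), m.rv.v0)
    out = {
        "p_la": p_la,
        "p_lv": p_lv,
        "p_ra": p_ra,
        "p_rv": p_rv,
        "q_mv": valve_flow(p_la, p_lv, m.mv),
        "q_av": valve_flow(p_lv, y[4], m.av),
        "q_tv": valve_flow(p_ra, p_rv, m.tv),
        "q_pv": valve_flow(p_rv, y[6], m.pv),
        "q_asd": shunt_flow(p_la, p_ra, m.shunts.rasd),
        "q_vsd": shunt_flow(p_lv, p_rv, m.shunts.rvsd),
    }
    assert set(out) == set(DERIVED_NAMES)
    return {k: np.atleast_1d(v) for k, v in out.items()}


def conservation_residual(t: float, y, m: ModelParams) -> float:
    """Closed-loop volume balance Σ dV/dt + Σ C·dp/dt for one state.

    Zero (to rounding) for every state: the circuit neither creates nor
    destroys blood.
    """
    dy = circuit_rhs(t, y, m)
    caps = (m.arsys.c, m.vensys.c, m.arpul.c, m.venpul.c)
    return float(dy[:4].sum() + sum(c * dp for c, dp in zip(caps, dy[4:8])))
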