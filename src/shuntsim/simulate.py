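"""Periodic steady-state integration and cycle-averaged hemodynamics.

The forced, closed-loop circuit settles onto a limit cycle; all reported
quantities (Qp, Qs, Qp/Qs, mean shunt flows and pressures) are
trapezoidal averages over one converged cycle. Convergence is declared
when cycle-mean pulmonary and systemic valve flows and all four
end-diastolic chamber volumes change by less than ``convergence_tol``
(relative) between consecutive cycles.

With all rest volumes at zero the circuit is positively homogeneous:
scaling the initial state scales the whole limit cycle, so flow ratios
such as Qp/Qs are independent of total blood volume and of the initial
condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator
from scipy.integrate import solve_ivp

from .model import derived_signals, make_rhs
from .params import DERIVED_NAMES, STATE_NAMES, CircuitState, ModelParams

logger = logging.getLogger(__name__)

#: 1 Wood unit = 1 mmHg·min/L = 0.06 mmHg·s/mL
MMHG_S_PER_ML_PER_WU = 0.06


class SimConfig(BaseModel):
    """Integrator and convergence settings.

    Defaults resolve the two-resistance valve law (seven orders of
    magnitude between open and closed) without event detection: a
    stiff-capable method with the step bounded to 1 ms.
    """

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    max_step: float = 1e-3
    n_samples_per_cycle: int = 800
    max_cycles: int = 200
    convergence_tol: float = 1e-4
    method: str = "LSODA"
    initial_state: Optional[CircuitState] = None

    @field_validator("rel_tol", "abs_tol", "max_step", "convergence_tol")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @field_validator("n_samples_per_cycle")
    @classmethod
    def _min_samples(cls, v: int) -> int:
        if v < 200:
            raise ValueError("need at least 200 samples per cycle")
        return v

    @field_validator("max_cycles")
    @classmethod
    def _min_cycles(cls, v: int) -> int:
        if v < 2:
            raise ValueError("need at least 2 cycles")
        return v


@dataclass
class CycleTrajectory:
    """One cardiac cycle on a uniform time grid: the 12 state variables
    plus derived chamber pressures, valve flows and shunt flows."""

    time_s: np.ndarray
    signals: Dict[str, np.ndarray] = field(repr=False)
    thb: float = 0.0

    def signal(self, name: str) -> np.ndarray:
        try:
            return self.signals[name]
        except KeyError:
            raise KeyError(
                f"unknown signal {name!r}; available: {sorted(self.signals)}"
            ) from None

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.time_s}
        cols.update({n: self.signals[n] for n in STATE_NAMES + DERIVED_NAMES})
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class CycleMetrics:
    """Cycle-averaged steady-state outputs (units in field names)."""

    qp_ml_s: float
    qs_ml_s: float
    qp_qs: float
    mean_qasd_ml_s: float
    mean_qvsd_ml_s: float
    mean_p_arsys_mmhg: float
    mean_p_vensys_mmhg: float
    mean_p_arpul_mmhg: float
    mean_p_venpul_mmhg: float
    mean_p_la_mmhg: float
    mean_p_lv_mmhg: float
    mean_p_ra_mmhg: float
    mean_p_rv_mmhg: float
    svr_wu: float
    pvr_wu: float
    svr_dynamic_wu: float
    pvr_dynamic_wu: float
    cycles_to_converge: int
    converged: bool
    residual: float


def resistance_to_wood(r: float) -> float:
    """Convert mmHg·s/mL to Wood units (mmHg·min/L)."""
    if r < 0:
        raise ValueError("resistance must be non-negative")
    return r / MMHG_S_PER_ML_PER_WU


def wood_to_resistance(wu: float) -> float:
    """Convert Wood units to mmHg·s/mL."""
    return wu * MMHG_S_PER_ML_PER_WU


def static_pvr_wu(m: ModelParams) -> float:
    """Pulmonary resistive sum (arterial + venous) in Wood units."""
    return resistance_to_wood(m.arpul.r + m.venpul.r)


def static_svr_wu(m: ModelParams) -> float:
    """Systemic resistive sum (arterial + venous) in Wood units."""
    return resistance_to_wood(m.arsys.r + m.vensys.r)


def set_pvr(m: ModelParams, target_wu: float) -> ModelParams:
    """Copy of ``m`` with total pulmonary resistance set to ``target_wu``.

    The venous resistance is left untouched; the arterial resistance
    absorbs the change: ``r_arpul = 0.06·target − r_venpul``.
    """
    r_total = wood_to_resistance(target_wu)
    r_arpul = r_total - m.venpul.r
    if r_arpul <= 0:
        raise ValueError(
            f"target PVR {target_wu} WU leaves no positive arterial resistance "
            f"(venous resistance is {m.venpul.r} mmHg·s/mL)"
        )
    return m.model_copy(update={"arpul": m.arpul.model_copy(update={"r": r_arpul})})


DEFAULT_PRESSURES_MMHG = {
    "p_arsys": 80.0,
    "p_vensys": 5.0,
    "p_arpul": 15.0,
    "p_venpul": 8.0,
}


def default_initial_state(m: ModelParams, scale: float = 1.0) -> CircuitState:
    """Physiological diastolic starting point.

    Compartment pressures at typical diastolic values, compartment flows
    at zero, and each chamber filled so that its passive pressure
    matches the adjacent venous pressure. ``scale`` multiplies the whole
    state (a blood-volume rescaling); flow ratios at steady state are
    unaffected by it.
    """
    p = DEFAULT_PRESSURES_MMHG
    return CircuitState(
        v_la=scale * (m.la.v0 + p["p_venpul"] / m.la.eb),
        v_lv=scale * (m.lv.v0 + p["p_venpul"] / m.lv.eb),
        v_ra=scale * (m.ra.v0 + p["p_vensys"] / m.ra.eb),
        v_rv=scale * (m.rv.v0 + p["p_vensys"] / m.rv.eb),
        p_arsys=scale * p["p_arsys"],
        p_vensys=scale * p["p_vensys"],
        p_arpul=scale * p["p_arpul"],
        p_venpul=scale * p["p_venpul"],
    )


def cycle_average(traj: CycleTrajectory, signal_name: str) -> float:
    """Trapezoidal mean of a trajectory signal over the cycle."""
    y = traj.signal(signal_name)
    return float(np.trapezoid(y, traj.time_s) / (traj.time_s[-1] - traj.time_s[0]))


def _cycle_summary(t, y, m: ModelParams):
    """Cycle-mean valve flows and start-of-cycle (end-diastolic) volumes."""
    d = derived_signals(t, y, m)
    thb = t[-1] - t[0]
    qp = float(np.trapezoid(d["q_pv"], t) / thb)
    qs = float(np.trapezoid(d["q_av"], t) / thb)
    edv = y[:4, 0]
    return qp, qs, edv


def simulate_to_steady_state(
    m: ModelParams, cfg: Optional[SimConfig] = None
) -> Tuple[CycleTrajectory, CycleMetrics]:
    """Integrate cycle by cycle until the limit cycle is reached.

    Returns the last simulated cycle (time shifted to ``[0, thb]``) and
    its cycle-averaged metrics. If ``cfg.max_cycles`` is reached without
    convergence the metrics carry ``converged=False`` and a warning is
    logged; the trajectory is still returned.
    """
    cfg = cfg or SimConfig()
    rhs = make_rhs(m)
    state = cfg.initial_state or default_initial_state(m)
    y0 = state.as_array()
    thb = m.thb
    prev = None
    residual = np.inf
    n_cycles = 0
    for k in range(cfg.max_cycles):
        t_span = (k * thb, (k + 1) * thb)
        t_eval = np.linspace(*t_span, cfg.n_samples_per_cycle + 1)
        sol = solve_ivp(
            rhs,
            t_span,
            y0,
            method=cfg.method,
            t_eval=t_eval,
            rtol=cfg.rel_tol,
            atol=cfg.abs_tol,
            max_step=cfg.max_step,
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed in cycle {k + 1} at t={sol.t[-1]:.4f} s: {sol.message}"
            )
        if np.any(sol.y[:4] <= 0):
            idx = np.argwhere(sol.y[:4] <= 0)[0]
            logger.warning(
                "non-physical chamber volume: %s = %.3g mL at t = %.4f s (cycle %d)",
                STATE_NAMES[idx[0]], sol.y[idx[0], idx[1]], sol.t[idx[1]], k + 1,
            )
        y0 = sol.y[:, -1]
        qp, qs, edv = _cycle_summary(sol.t, sol.y, m)
        cur = np.concatenate([[qp, qs], edv])
        n_cycles = k + 1
        if prev is not None:
            scale = np.maximum(np.maximum(np.abs(cur), np.abs(prev)), 1e-6)
            residual = float(np.max(np.abs(cur - prev) / scale))
            if residual < cfg.convergence_tol:
                break
        prev = cur
    converged = residual < cfg.convergence_tol
    if not converged:
        logger.warning(
            "no periodic steady state after %d cycles (residual %.3g > %.3g)",
            n_cycles, residual, cfg.convergence_tol,
        )
    logger.info(
        "steady state in %d cycles (residual %.3g); Qp/Qs = %.4f",
        n_cycles, residual, qp / qs if qs else np.nan,
    )
    t_local = sol.t - sol.t[0]
    signals = {name: sol.y[i].copy() for i, name in enumerate(STATE_NAMES)}
    signals.update(derived_signals(sol.t, sol.y, m))
    traj = CycleTrajectory(time_s=t_local, signals=signals, thb=thb)
    metrics = compute_metrics(traj, m, n_cycles, converged, residual)
    return traj, metrics


def compute_metrics(
    traj: CycleTrajectory,
    m: ModelParams,
    cycles_to_converge: int = 0,
    converged: bool = True,
    residual: float = 0.0,
) -> CycleMetrics:
    """Cycle-averaged metrics of one (steady-state) cycle.

    The reported SVR/PVR in Wood units are the static resistor sums; the
    ``*_dynamic_wu`` fields are the mean-gradient/mean-flow estimates a
    catheterisation would give, for comparison.
    """
    qp = cycle_average(traj, "q_pv")
    qs = cycle_average(traj, "q_av")
    means = {n: cycle_average(traj, n) for n in (
        "q_asd", "q_vsd",
        "p_arsys", "p_vensys", "p_arpul", "p_venpul",
        "p_la", "p_lv", "p_ra", "p_rv",
    )}
    svr_dyn = (means["p_arsys"] - means["p_ra"]) / qs if qs else np.nan
    pvr_dyn = (means["p_arpul"] - means["p_la"]) / qp if qp else np.nan
    return CycleMetrics(
        qp_ml_s=qp,
        qs_ml_s=qs,
        qp_qs=qp / qs,
        mean_qasd_ml_s=means["q_asd"],
        mean_qvsd_ml_s=means["q_vsd"],
        mean_p_arsys_mmhg=means["p_arsys"],
        mean_p_vensys_mmhg=means["p_vensys"],
        mean_p_arpul_mmhg=means["p_arpul"],
        mean_p_venpul_mmhg=means["p_venpul"],
        mean_p_la_mmhg=means["p_la"],
        mean_p_lv_mmhg=means["p_lv"],
        mean_p_ra_mmhg=means["p_ra"],
        mean_p_rv_mmhg=means["p_rv"],
        svr_wu=static_svr_wu(m),
        pvr_wu=static_pvr_wu(m),
        svr_dynamic_wu=svr_dyn / MMHG_S_PER_ML_PER_WU,
        pvr_dynamic_wu=pvr_dyn / MMHG_S_PER_ML_PER_WU,
        cycles_to_converge=cycles_to_converge,
        converged=converged,
        residual=residual,
    )
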