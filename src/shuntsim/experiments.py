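"""Scenario sweeps and the standard Qp/Qs analyses.

A sweep varies exactly one quantity — total pulmonary vascular
resistance (Wood units), right-ventricular passive elastance EBRV,
right-ventricular relaxation duration as a fraction of the heartbeat
period, or a defect resistance — across a monotone grid, integrating
each point to periodic steady state. Percent reductions are computed
from the unrounded endpoint Qp/Qs values.

Sweep baselines normalize total PVR to the healthy reference of 1.9 WU
(unless PVR itself is swept, whose grid starts there): the isolated-ASD
preset's printed pulmonary arterial resistance encodes a remodelled
state with a static sum near 5 WU, and the sweep analyses are defined
relative to the healthy baseline. Pass ``normalize_pvr_wu=None`` to
sweep from the raw preset values instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .params import CircuitState, ModelParams
from .presets import load_preset
from .simulate import CycleMetrics, CycleTrajectory, SimConfig, set_pvr, simulate_to_steady_state

#: Published variability ranges of the swept quantities.
SWEEP_RANGES = {
    "pvr_wu": (1.9, 8.2),
    "ebrv": (0.0088, 0.28),
    "trrv_frac": (0.30, 0.70),
}

QUANTITIES = ("pvr_wu", "ebrv", "trrv_frac", "rasd", "rvsd")

BASELINE_PVR_WU = 1.9


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional parameter sweep over a scenario preset.

    ``overrides`` adjusts the baseline before sweeping: recognised keys
    are ``rasd``, ``rvsd`` (defect resistances, ``"closed"`` allowed),
    ``ebrv`` (absolute), ``ebrv_scale`` (multiple of the preset value)
    and ``pvr_wu``.
    """

    preset: str
    quantity: str
    grid: Tuple[float, ...]
    overrides: Dict[str, Union[float, str]] = field(default_factory=dict)
    normalize_pvr_wu: Optional[float] = BASELINE_PVR_WU
    enforce_range: bool = True

    def __post_init__(self):
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown sweep quantity {self.quantity!r}; one of {QUANTITIES}")
        grid = tuple(float(g) for g in self.grid)
        object.__setattr__(self, "grid", grid)
        if len(grid) == 0:
            raise ValueError("sweep grid is empty")
        diffs = np.diff(grid)
        if len(grid) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("sweep grid must be strictly monotone")
        if self.enforce_range and self.quantity in SWEEP_RANGES:
            lo, hi = SWEEP_RANGES[self.quantity]
            eps = 1e-12
            if min(grid) < lo - eps or max(grid) > hi + eps:
                raise ValueError(
                    f"{self.quantity} grid {min(grid)}..{max(grid)} outside the "
                    f"published range {lo}..{hi}; pass enforce_range=False to override"
                )


@dataclass
class SweepResult:
    spec: SweepSpec
    metrics: List[CycleMetrics]
    qp_qs_first: float
    qp_qs_last: float
    percent_reduction: float

    @property
    def qp_qs(self) -> np.ndarray:
        return np.array([m.qp_qs for m in self.metrics])

    @property
    def all_converged(self) -> bool:
        return all(m.converged for m in self.metrics)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.spec.quantity: list(self.spec.grid),
                "qp_qs": self.qp_qs,
                "qp_ml_s": [m.qp_ml_s for m in self.metrics],
                "qs_ml_s": [m.qs_ml_s for m in self.metrics],
                "converged": [m.converged for m in self.metrics],
            }
        )


def percent_reduction(first: float, last: float) -> float:
    """Relative drop 100·(first − last)/first, in percent."""
    if first <= 0:
        raise ValueError(f"initial value must be positive, got {first}")
    return 100.0 * (first - last) / first


def _apply_overrides(m: ModelParams, overrides: Dict[str, float]) -> ModelParams:
    for key, val in overrides.items():
        if key == "rasd":
            m = m.with_shunts(rasd=val)
        elif key == "rvsd":
            m = m.with_shunts(rvsd=val)
        elif key == "ebrv":
            m = m.with_chamber("rv", eb=float(val))
        elif key == "ebrv_scale":
            m = m.with_chamber("rv", eb=float(val) * m.rv.eb)
        elif key == "pvr_wu":
            m = set_pvr(m, float(val))
        else:
            raise ValueError(f"unknown override {key!r}")
    return m


def _apply_quantity(m: ModelParams, quantity: str, value: float) -> ModelParams:
    if quantity == "pvr_wu":
        return set_pvr(m, value)
    if quantity == "ebrv":
        return m.with_chamber("rv", eb=value)
    if quantity == "trrv_frac":
        return m.with_chamber("rv", d_relax=value * m.thb)
    if quantity == "rasd":
        return m.with_shunts(rasd=value)
    if quantity == "rvsd":
        return m.with_shunts(rvsd=value)
    raise ValueError(f"unknown sweep quantity {quantity!r}")


def sweep_baseline(spec: SweepSpec) -> ModelParams:
    """The fixed parameters every point of the sweep shares."""
    m = load_preset(spec.preset).params
    if spec.normalize_pvr_wu is not None and spec.quantity != "pvr_wu":
        m = set_pvr(m, spec.normalize_pvr_wu)
    return _apply_overrides(m, spec.overrides)


def run_sweep(spec: SweepSpec, cfg: Optional[SimConfig] = None, warm_start: bool = True) -> SweepResult:
    """Steady-state simulation at every grid point.

    With ``warm_start`` each point starts from the previous point's
    final state — a pure accelerant, since the limit cycle does not
    depend on the initial condition. Non-converged points are flagged in
    their metrics and the sweep continues.
    """
    cfg = cfg or SimConfig()
    base = sweep_baseline(spec)
    metrics: List[CycleMetrics] = []
    carry: Optional[CircuitState] = cfg.initial_state
    for value in spec.grid:
        m = _apply_quantity(base, spec.quantity, value)
        point_cfg = cfg.model_copy(update={"initial_state": carry})
        traj, mt = simulate_to_steady_state(m, point_cfg)
        metrics.append(mt)
        if warm_start:
            carry = CircuitState(**{n: traj.signals[n][-1] for n in CircuitState.__dataclass_fields__})
    first, last = metrics[0].qp_qs, metrics[-1].qp_qs
    return SweepResult(
        spec=spec,
        metrics=metrics,
        qp_qs_first=first,
        qp_qs_last=last,
        percent_reduction=percent_reduction(first, last),
    )


def default_grid(quantity: str, n: int = 9) -> Tuple[float, ...]:
    """Evenly spaced grid across the published range of a quantity."""
    lo, hi = SWEEP_RANGES[quantity]
    return tuple(np.linspace(lo, hi, n))


#: The five standard Qp/Qs curves: (panel, scenario, quantity, overrides).
FIG2_PANELS: Sequence[Tuple[str, str, str, Dict[str, float]]] = (
    *[("A", s, "pvr_wu", {}) for s in ("vsd", "asd", "asd_vsd")],
    *[("B", s, "ebrv", {}) for s in ("vsd", "asd", "asd_vsd")],
    *[("C", s, "trrv_frac", {}) for s in ("vsd", "asd", "asd_vsd")],
    ("D", "asd_vsd", "ebrv", {"rvsd": 0.0024}),
    ("E", "asd", "trrv_frac", {"ebrv_scale": 10.0}),
)


def reproduce_fig2(
    cfg: Optional[SimConfig] = None, n_points: int = 9, panels: Optional[str] = None
) -> pd.DataFrame:
    """Qp/Qs versus each swept quantity for every scenario.

    Panels: A — PVR sweeps; B — EBRV sweeps; C — relaxation-time sweeps
    (each for the three scenarios); D — EBRV sweep of the combined
    scenario with an enlarged VSD (resistance 0.0024 mmHg·s/mL); E —
    relaxation-time sweep of the isolated ASD with EBRV fixed at ten
    times its baseline. ``panels`` restricts the output to a subset,
    e.g. ``"ADE"``.
    """
    rows = []
    for panel, scenario, quantity, overrides in FIG2_PANELS:
        if panels is not None and panel not in panels.upper():
            continue
        spec = SweepSpec(
            preset=scenario, quantity=quantity,
            grid=default_grid(quantity, n_points), overrides=overrides,
        )
        res = run_sweep(spec, cfg)
        for value, mt in zip(spec.grid, res.metrics):
            rows.append(
                dict(panel=panel, scenario=scenario, grid_value=value,
                     qp_qs=mt.qp_qs, converged=mt.converged)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shunt-flow waveform morphology


def _in_window(t: float, start: float, end: float, thb: float) -> bool:
    """Is time ``t`` inside the cyclic window [start, end] (mod thb)?"""
    return (t - start) % thb <= (end - start) % thb + 1e-12


def periodic_local_maxima(traj: CycleTrajectory, name: str, prominence_frac: float = 0.05):
    """Times and values of local maxima of a periodic signal.

    The cycle is tiled three times so maxima at the wrap point are not
    missed; peaks need a prominence of ``prominence_frac`` of the
    signal's peak-to-peak amplitude.
    """
    t, y = traj.time_s, traj.signal(name)
    thb = t[-1] - t[0]
    n = len(y) - 1  # last sample repeats the first
    y3 = np.concatenate([y[:n], y[:n], y[:n]])
    prominence = prominence_frac * (y.max() - y.min())
    peaks, _ = find_peaks(y3, prominence=prominence)
    peaks = peaks[(peaks >= n) & (peaks < 2 * n)] - n
    return t[peaks], y[peaks]


def check_vsd_waveform(traj: CycleTrajectory, m: ModelParams) -> dict:
    """Is the ventricular shunt flow dominated by systole?

    The global maximum of the VSD flow must fall inside the ventricular
    contraction window (left-ventricular contraction onset through half
    the relaxation ramp).
    """
    t, y = traj.time_s, traj.signal("q_vsd")
    t_peak = float(t[int(np.argmax(y))])
    start = m.lv.t_contract
    end = m.lv.t_relax + 0.5 * m.lv.d_relax
    ok = _in_window(t_peak, start, end, m.thb)
    return dict(passed=ok, peak_time_s=t_peak, window_s=(start, end % m.thb))


def check_asd_waveform(traj: CycleTrajectory, m: ModelParams) -> dict:
    """Does the atrial shunt flow show its two diastolic peaks?

    Requires at least two local maxima, one inside the ventricular
    relaxation window and one inside the atrial contraction window.
    """
    t_peaks, _ = periodic_local_maxima(traj, "q_asd")
    relax_start = min(m.lv.t_relax, m.rv.t_relax)
    relax_end = max(m.lv.t_relax + m.lv.d_relax, m.rv.t_relax + m.rv.d_relax)
    atr_start = min(m.la.t_contract, m.ra.t_contract)
    atr_end = max(m.la.t_contract + m.la.d_contract, m.ra.t_contract + m.ra.d_contract)
    in_relax = [tp for tp in t_peaks if _in_window(tp, relax_start, relax_end, m.thb)]
    in_atrial = [tp for tp in t_peaks if _in_window(tp, atr_start, atr_end, m.thb)]
    ok = len(t_peaks) >= 2 and bool(in_relax) and bool(in_atrial)
    return dict(
        passed=ok,
        n_peaks=len(t_peaks),
        peak_times_s=list(map(float, t_peaks)),
        relaxation_window_s=(relax_start % m.thb, relax_end % m.thb),
        atrial_window_s=(atr_start % m.thb, atr_end % m.thb),
    )


def reproduce_fig3(cfg: Optional[SimConfig] = None) -> Dict[str, pd.DataFrame]:
    """One steady-state cycle of each shunt-flow waveform.

    Returns ``{"asd": DataFrame(time_s, q_asd), "vsd": DataFrame(time_s,
    q_vsd)}`` with the morphology-check outcome attached in
    ``DataFrame.attrs["check"]``.
    """
    out: Dict[str, pd.DataFrame] = {}
    for scenario, signal, checker in (
        ("asd", "q_asd", check_asd_waveform),
        ("vsd", "q_vsd", check_vsd_waveform),
    ):
        m = load_preset(scenario).params
        traj, mt = simulate_to_steady_state(m, cfg)
        df = pd.DataFrame({"time_s": traj.time_s, signal: traj.signal(signal)})
        df.attrs["check"] = dict(checker(traj, m), converged=mt.converged)
        out[scenario] = df
    return out
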