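# Methods

## Model structure

The circulation is closed-loop and zero-dimensional: four time-varying
elastance chambers, four diode valves, four RLC Windkessel compartments
and up to two resistive septal-defect branches. The 12 unknowns are the
chamber volumes (V_LA, V_LV, V_RA, V_RV), the compartment pressures
(p_ARSYS, p_VENSYS, p_ARPUL, p_VENPUL) and the compartment flows
(Q_ARSYS, Q_VENSYS, Q_ARPUL, Q_VENPUL). Chamber pressures and valve and
shunt flows are algebraic functions of the state, evaluated inside the
right-hand side:

- volume balances: dV_LA/dt = Q_VENPUL − Q_MV − Q_ASD, and analogously
  for the other chambers, with Q_ASD entering the right atrium and
  Q_VSD the right ventricle;
- capacitor balances: C·dp/dt = inflow − outflow per compartment;
- inductor balances: L·dQ/dt = upstream p − downstream p − R·Q, the
  systemic veins discharging into the right atrium and the pulmonary
  veins into the left atrium.

Summing the four volume balances and the four capacitor balances
multiplied by their compliances cancels every flow exactly, so total
blood volume (ΣV + ΣC·p) is a conserved quantity of the continuous
system. The test suite checks this identity to 1e−10 of the largest
term at random states.

## Activation waveform

The chamber activation rises 0→1 over [t_C, t_C + T_C] and falls 1→0
over [t_R, t_R + T_R] with half-cosine ramps, zero in between, all
windows taken modulo the heartbeat period; atrial relaxation windows
wrap past the cycle end (e.g. left-atrial relaxation spans 0.64 s
starting at 0.9·T_HB). This is the standard profile of the lumped
elastance model family; it satisfies a(t_C) = 0, a(t_C + T_C) = 1 and
the half-way symmetry a(t_C + T_C/2) = 1/2. As tabulated, the
relaxation onset always equals contraction onset plus contraction
duration, and the parameter container enforces that invariant on every
modification.

## Rest volumes and homogeneity

The published parameterisation omits unstressed chamber volumes, so the
package defaults to V₀ = 0 for all chambers (configurable per chamber in
preset files). This has a useful structural consequence: every
constitutive law (linear elastance, piecewise-linear valves, resistive
shunts, linear RLC) is then positively homogeneous of degree 1 in the
state, so rescaling the initial state rescales the whole limit cycle
and leaves every flow ratio — in particular Qp/Qs — exactly unchanged.
Absolute pressures and volumes *do* depend on the initial total blood
volume; only ratios are volume-free. The default initial state (80/5/
15/8 mmHg in the systemic-arterial/systemic-venous/pulmonary-arterial/
pulmonary-venous compartments, zero compartment flows, chambers filled
to passive equilibrium with their adjacent venous pressure) yields a
total stressed volume near 850 mL for the baseline column, which puts
the baseline pressures in the physiological range.

## Integration and steady state

The valve law jumps between resistances seven orders of magnitude
apart, making the system stiff at every valve opening and closure. The
engine integrates with LSODA (configurable), rel_tol 1e−6, abs_tol
1e−8, and a 1 ms step bound so no switching event is stepped over; no
event detection is used. Integration proceeds cycle by cycle with 800
output samples per cycle; convergence is declared when cycle-mean Qp,
cycle-mean Qs and all four start-of-cycle (end-diastolic) volumes
change by less than 1e−4 relative between consecutive cycles, with a
cap of 200 cycles (the slowest mode is blood redistribution through the
60 mL/mmHg systemic venous compliance, with a time constant of roughly
20 s ≈ 25 cycles; cold starts converge in 50–70 cycles). Halving the
tolerances moves Qp/Qs by well under 0.1 %, and the returned cycle is
periodic to about 1e−4 of each signal's amplitude; the tests assert
both. Non-positive chamber volumes trigger a warning diagnostic rather
than silent continuation, and non-finite states abort with the
offending variable named.

Metrics are trapezoidal cycle means. Qp and Qs are the pulmonary- and
aortic-valve flows (the clinical definition); at the limit cycle they
coincide with the compartment flows and obey Qp − Qs = mean Q_ASD +
mean Q_VSD to 0.1 %, which the suite asserts for every scenario. The
reported SVR/PVR in Wood units (WU = mmHg·min/L, 0.06 mmHg·s/mL) are
the static resistor sums; the mean-gradient/mean-flow estimates are
reported alongside as `*_dynamic_wu`.

## Scenarios and sweep baselines

The three presets store the published parameter columns verbatim
(timings as fractions of T_HB). The baseline (VSD) column's resistor
sums give PVR = 1.91 WU and SVR = 15.7 WU. The isolated-ASD column
encodes a remodelled circulation — dilated, compliant ventricles
(E_B,LV = 0.018, E_B,RV = 0.0088 mmHg/mL) and a pulmonary arterial
resistance whose static sum is about 5 WU.

Sweeps therefore fix their baseline as *the preset column with total
PVR retargeted to the healthy 1.9 WU reference* (arterial resistance
absorbs the change, venous is kept), unless PVR itself is the swept
quantity, whose grid starts at 1.9 WU anyway. This choice makes the
isolated-ASD sweep baselines land at Qp/Qs ≈ 1.9–2.2, the regime the
published endpoint pairs describe, and it is overridable
(`normalize_pvr_wu=None` sweeps from the raw column). Sweep grids
default to 9 evenly spaced points with endpoints exactly at the
published range bounds (PVR 1.9–8.2 WU; E_B,RV 0.0088–0.28 mmHg/mL;
T_R,RV/T_HB 30–70 %); grids outside those ranges require an explicit
opt-out. Percent reductions are always computed from the unrounded
endpoint values. Within a sweep, each point warm-starts from the
previous point's final state — purely an accelerant, since the limit
cycle is independent of the start (asserted in the tests via a
rescaled-initial-volume run).

The relaxation-time sweep replaces the RV relaxation *duration*
(T_R,RV = fraction·T_HB) while keeping its onset at contraction end; at
the 70 % upper bound the activation exactly fills the cycle with no
quiescent phase. Defect size is manipulated solely through the shunt
resistances (inverse-size proxies).

## Numerical and design notes

- Tie-break at zero valve gradient: both branches give zero flow, so
  the law is continuous; the forward branch is taken for Δp > 0
  strictly.
- A closed defect is represented as exactly zero flow, not a huge
  resistance; the right-hand side with a 1e6 mmHg·s/mL branch agrees
  with the closed branch to 1e−3 relative (tested), so the two
  representations are interchangeable in practice.
- The tenfold-stiff-RV relaxation sweep (the fifth standard curve) is
  *attenuated*, not flat, in this model: the endpoint reduction drops
  from 62 % at baseline RV stiffness to about 29 % at tenfold
  stiffness. The corresponding test asserts the attenuation, not
  flatness.
- Single-point grids are legal and give a 0 % reduction; increases
  appear as negative reductions.
- Problem sizes: the standard analyses use 9-point grids (the full
  five-curve set is 14 sweeps ≈ 130 steady states, a few minutes on one
  CPU); the test suite reuses converged runs through session fixtures
  and endpoint-only grids where only endpoints matter.

## What the model does and does not show

The simulator reproduces the *mechanistic* contrasts between pre- and
post-tricuspid shunts: PVR governs VSD shunting (convex Qp/Qs fall,
53–60 % across 1.9→8.2 WU), RV passive stiffness governs ASD shunting
(91 % collapse across the elastance range), relaxation time matters
only for the pre-tricuspid defect, and the dominant defect shapes the
combined lesion's response. It is not patient-specific: parameters are
a population-level baseline, there is no baroreflex, respiration,
valve regurgitation beyond the leak resistance, or spatial (1D/3D) wave
propagation, and absolute flows and pressures inherit the uncertainty
of the assumed total blood volume. Quantitative outputs should be read
as model-relative trends, not individual predictions.
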