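"""Parameter containers for the closed-loop 0D circulation model.

The circulation is an electric analogue: four heart chambers driven by
time-varying elastances, four valves modelled as two-resistance diodes,
four RLC (Windkessel) vascular compartments, and up to two resistive
septal-defect branches (atrial and ventricular).

Units are fixed throughout: pressures in mmHg, volumes in mL, flows in
mL/s, time in s, resistances in mmHg·s/mL, compliances in mL/mmHg,
inertances in mmHg·s²/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class ChamberParams(_Frozen):
    """Time-varying elastance chamber.

    The chamber pressure is ``p = (eb + ea·a(t)) · (V − v0)`` where the
    activation ``a(t)`` ramps 0→1 over ``[t_contract, t_contract +
    d_contract]`` and 1→0 over ``[t_relax, t_relax + d_relax]`` with
    half-cosine profiles, all intervals taken modulo the heartbeat period.

    Parameters
    ----------
    ea : float
        Active elastance amplitude, mmHg/mL (≥ 0).
    eb : float
        Passive (diastolic) elastance, mmHg/mL (> 0).
    v0 : float
        Unstressed (rest) volume, mL. Default 0.
    t_contract, d_contract : float
        Contraction onset time and duration, s.
    t_relax, d_relax : float
        Relaxation onset time and duration, s. As tabulated,
        ``t_relax = t_contract + d_contract``.
    """

    ea: float
    eb: float
    v0: float = 0.0
    t_contract: float
    d_contract: float
    t_relax: float
    d_relax: float

    @field_validator("ea", "v0")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be non-negative")
        return v

    @field_validator("eb", "d_contract", "d_relax")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v


class ValveParams(_Frozen):
    """Diode-with-leak valve: open resistance ``rmin``, closed ``rmax``."""

    rmin: float
    rmax: float

    @model_validator(mode="after")
    def _ordered(self) -> "ValveParams":
        if not (0 < self.rmin < self.rmax):
            raise ValueError(
                "valve resistances must satisfy 0 < rmin < rmax "
                f"(got rmin={self.rmin}, rmax={self.rmax})"
            )
        return self


class WindkesselParams(_Frozen):
    """RLC vascular compartment: resistance, compliance, inertance."""

    r: float
    c: float
    l: float

    @field_validator("r", "c", "l")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v


def _closed_to_none(v):
    if isinstance(v, str):
        if v.lower() == "closed":
            return None
        raise ValueError(f"shunt resistance must be a number or 'closed', got {v!r}")
    return v


class ShuntParams(_Frozen):
    """Septal-defect branches as pure resistances.

    ``None`` (serialized as the string ``"closed"``) means the defect is
    absent: zero flow for any pressure gradient. Resistance is an inverse
    proxy for defect size — smaller resistance, larger defect.
    """

    rasd: Optional[float] = None
    rvsd: Optional[float] = None

    @field_validator("rasd", "rvsd", mode="before")
    @classmethod
    def _closed(cls, v):
        return _closed_to_none(v)

    @field_validator("rasd", "rvsd")
    @classmethod
    def _pos(cls, v):
        if v is not None and v <= 0:
            raise ValueError("open shunt resistance must be positive")
        return v


class ModelParams(_Frozen):
    """Full parameterization of the closed-loop circuit.

    Chambers: la, lv, ra, rv. Valves: mv (mitral), av (aortic),
    tv (tricuspid), pv (pulmonary). Compartments: arsys/vensys
    (systemic arterial/venous) and arpul/venpul (pulmonary
    arterial/venous). ``thb`` is the heartbeat period in s.
    """

    thb: float
    la: ChamberParams
    lv: ChamberParams
    ra: ChamberParams
    rv: ChamberParams
    mv: ValveParams
    av: ValveParams
    tv: ValveParams
    pv: ValveParams
    arsys: WindkesselParams
    vensys: WindkesselParams
    arpul: WindkesselParams
    venpul: WindkesselParams
    shunts: ShuntParams = ShuntParams()

    @field_validator("thb")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("heartbeat period must be positive")
        return v

    @model_validator(mode="after")
    def _timing(self) -> "ModelParams":
        for name in ("la", "lv", "ra", "rv"):
            ch: ChamberParams = getattr(self, name)
            if not (0 <= ch.t_contract < self.thb):
                raise ValueError(
                    f"chamber {name}: contraction onset {ch.t_contract} "
                    f"outside [0, thb={self.thb})"
                )
            gap = (ch.t_relax - ch.t_contract - ch.d_contract) % self.thb
            if min(gap, self.thb - gap) > 1e-9 * self.thb:
                raise ValueError(
                    f"chamber {name}: relaxation onset must equal contraction "
                    "onset + contraction duration (mod thb)"
                )
        return self

    def _revalidated(self, **updates) -> "ModelParams":
        # model_copy skips validators; rebuild through the constructor
        data = {name: getattr(self, name) for name in type(self).model_fields}
        data.update(updates)
        return type(self)(**data)

    def with_shunts(
        self,
        rasd: Union[float, str, None] = "keep",
        rvsd: Union[float, str, None] = "keep",
    ) -> "ModelParams":
        """Copy with replaced shunt resistances; ``None``/'closed' closes."""
        new_rasd = self.shunts.rasd if rasd == "keep" else _closed_to_none(rasd)
        new_rvsd = self.shunts.rvsd if rvsd == "keep" else _closed_to_none(rvsd)
        return self._revalidated(shunts=ShuntParams(rasd=new_rasd, rvsd=new_rvsd))

    def with_chamber(self, name: str, **updates) -> "ModelParams":
        """Validated copy with one chamber's fields replaced (e.g. ``eb=0.28``)."""
        ch = getattr(self, name)
        data = {f: getattr(ch, f) for f in type(ch).model_fields}
        data.update(updates)
        return self._revalidated(**{name: ChamberParams(**data)})


STATE_NAMES = (
    "v_la", "v_lv", "v_ra", "v_rv",
    "p_arsys", "p_vensys", "p_arpul", "p_venpul",
    "q_arsys", "q_vensys", "q_arpul", "q_venpul",
)

DERIVED_NAMES = (
    "p_la", "p_lv", "p_ra", "p_rv",
    "q_mv", "q_av", "q_tv", "q_pv", "q_asd", "q_vsd",
)


@dataclass(frozen=True)
class CircuitState:
    """The 12 dynamic unknowns: chamber volumes (mL), compartment
    pressures (mmHg) and compartment flows (mL/s), in the fixed order of
    :data:`STATE_NAMES`."""

    v_la: float
    v_lv: float
    v_ra: float
    v_rv: float
    p_arsys: float
    p_vensys: float
    p_arpul: float
    p_venpul: float
    q_arsys: float = 0.0
    q_vensys: float = 0.0
    q_arpul: float = 0.0
    q_venpul: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CircuitState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_NAMES),):
            raise ValueError(f"state vector must have shape ({len(STATE_NAMES)},)")
        return cls(**dict(zip(STATE_NAMES, y.tolist())))
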