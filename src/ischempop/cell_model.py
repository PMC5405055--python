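"""Typed interface to the myocyte model backend.

The population-of-models study varies six maximal conductances
(``g_to``, ``g_CaL``, ``g_Kr``, ``g_Ks``, ``g_K1``, ``g_NaK``) around a
fixed Shannon-type baseline, and superimposes acute-ischemia parameter
changes: graded I_K,ATP activation (hypoxia), fractional inhibition of
I_Na and I_CaL (acidosis), reduced I_NaK with raised intracellular Na+,
and elevated extracellular K+ (hyperkalemia).

This module defines the domain types and the operations that apply a
population member and an ischemic condition to the pristine baseline
parameter set. Scaling is always applied to the baseline, never
compounded, so applying a member twice cannot double-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import shannon
from .shannon import N_STATES, PIDX, RESTING_STATE, STATE_NAMES  # noqa: F401

__all__ = [
    "ConductanceSet",
    "IschemiaState",
    "ModelParameters",
    "CONTROL_MEMBER",
    "CONTROL_ISCHEMIA",
    "baseline_parameters",
    "apply_member",
    "apply_ischemia",
    "ikatp_current",
    "rhs",
]


@dataclass(frozen=True)
class ConductanceSet:
    """Six dimensionless scaling factors defining one population member.

    Factors multiply the baseline maximal conductances; all ones
    reproduces the unmodified base model.
    """

    s_to: float = 1.0
    s_cal: float = 1.0
    s_kr: float = 1.0
    s_ks: float = 1.0
    s_k1: float = 1.0
    s_nak: float = 1.0

    FIELDS = ("s_to", "s_cal", "s_kr", "s_ks", "s_k1", "s_nak")

    def __post_init__(self):
        for name in self.FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"conductance factor {name}={v!r} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS])

    @classmethod
    def from_array(cls, a) -> "ConductanceSet":
        return cls(*(float(x) for x in a))


#: population member used as the control model: closest APD90 to the
#: experimental means at all three pacing rates (+30% g_to, -15% g_Ks,
#: -30% g_K1, +15% g_NaK relative to baseline)
CONTROL_MEMBER = ConductanceSet(1.30, 1.00, 1.00, 0.85, 0.70, 1.15)


@dataclass(frozen=True)
class IschemiaState:
    """Instantaneous ischemic parameter vector.

    ``f_katp`` is the fractional activation of the ATP-sensitive K+
    conductance (0.008 means "0.8%"); ``f_inhib`` and ``f_nak`` are
    fractional reductions, so conductances are multiplied by ``1 - f``.
    """

    f_katp: float = 0.0
    f_inhib: float = 0.0
    f_nak: float = 0.0
    k_o: float = 5.4          # mM
    na_i_offset: float = 0.0  # mM added to intracellular Na at t = 0

    def __post_init__(self):
        if not 0.0 <= self.f_katp <= 1.0:
            raise ValueError(f"f_katp={self.f_katp} outside [0, 1]")
        if not 0.0 <= self.f_inhib < 1.0:
            raise ValueError(f"f_inhib={self.f_inhib} outside [0, 1)")
        if not 0.0 <= self.f_nak < 1.0:
            raise ValueError(f"f_nak={self.f_nak} outside [0, 1)")
        if self.k_o < 5.4:
            raise ValueError(f"k_o={self.k_o} below the control value 5.4 mM")
        if self.na_i_offset < 0:
            raise ValueError(f"na_i_offset={self.na_i_offset} must be >= 0")

    @property
    def is_control(self) -> bool:
        return (self.f_katp == 0 and self.f_inhib == 0 and self.f_nak == 0
                and self.k_o == 5.4 and self.na_i_offset == 0)


CONTROL_ISCHEMIA = IschemiaState()


@dataclass(frozen=True)
class ModelParameters:
    """Full constant set of the backend: a parameter vector plus the
    I_K,ATP maximal conductance (g_KATP, mS/uF) and rectification
    exponent, which live outside the vector until ischemia is applied."""

    vec: np.ndarray = field(default_factory=shannon.baseline_params)
    g_katp: float = 2.61   # mS/uF; f_KATP * g_KATP is the total channel conductance
    katp_exp: float = 0.24

    def __post_init__(self):
        if self.g_katp <= 0:
            raise ValueError("g_katp must be positive")
        if self.vec.shape != (shannon.N_PARAMS,):
            raise ValueError("parameter vector has wrong length")

    def __getitem__(self, name: str) -> float:
        return float(self.vec[PIDX[name]])

    def with_values(self, **kw) -> "ModelParameters":
        v = self.vec.copy()
        for name, val in kw.items():
            v[PIDX[name]] = val
        return replace(self, vec=v)


def baseline_parameters() -> ModelParameters:
    """Pristine baseline parameters (all scalings 1, control bath)."""
    return ModelParameters()


def apply_member(params: ModelParameters, scaling: ConductanceSet) -> ModelParameters:
    """Scale the six variable maximal conductances by a member's factors.

    Must be given pristine (baseline) parameters; the six factors each
    multiply one baseline conductance and everything else is unchanged.
    """
    return params.with_values(
        g_tos=params["g_tos"] * scaling.s_to,
        g_tof=params["g_tof"] * scaling.s_to,
        p_ca=params["p_ca"] * scaling.s_cal,
        p_na=params["p_na"] * scaling.s_cal,
        p_k=params["p_k"] * scaling.s_cal,
        g_kr0=params["g_kr0"] * scaling.s_kr,
        g_ks_scale=params["g_ks_scale"] * scaling.s_ks,
        g_k10=params["g_k10"] * scaling.s_k1,
        ibar_nak=params["ibar_nak"] * scaling.s_nak,
    )


def apply_ischemia(params: ModelParameters, state0: np.ndarray,
                   isch: IschemiaState) -> tuple[ModelParameters, np.ndarray]:
    """Impose an ischemic condition on member-scaled parameters.

    I_Na and I_CaL conductances are multiplied by ``1 - f_inhib``, the
    Na/K pump rate by ``1 - f_nak``; [K+]o is set; I_K,ATP is enabled at
    ``f_katp * g_katp``; the initial intracellular Na+ (all three Na
    compartments) is raised by ``na_i_offset``.
    """
    p = params.with_values(
        g_na=params["g_na"] * (1.0 - isch.f_inhib),
        p_ca=params["p_ca"] * (1.0 - isch.f_inhib),
        p_na=params["p_na"] * (1.0 - isch.f_inhib),
        p_k=params["p_k"] * (1.0 - isch.f_inhib),
        ibar_nak=params["ibar_nak"] * (1.0 - isch.f_nak),
        k_o=isch.k_o,
        g_katp_eff=isch.f_katp * params.g_katp,
        katp_exp=params.katp_exp,
    )
    y0 = np.asarray(state0, dtype=float).copy()
    if y0.shape != (N_STATES,):
        raise ValueError("state vector has wrong length")
    for name in ("na_j", "na_sl", "na_i"):
        y0[shannon.IDX[name]] += isch.na_i_offset
    return p, y0


def ikatp_current(v_m: float, k_o: float, k_i: float, f_katp: float,
                  g_katp: float = 2.61, exponent: float = 0.24) -> float:
    """ATP-sensitive K+ current density (uA/uF, outward positive).

    I = f_KATP * g_KATP * (K_o / 5.4)^exponent * (V - E_K); the total
    channel conductance is the product f_KATP * g_KATP, weakly rectified
    by extracellular K+.
    """
    if k_o <= 0 or k_i <= 0:
        raise ValueError("K+ concentrations must be positive")
    e_k = (shannon._R * shannon._T / shannon._F) * np.log(k_o / k_i)
    return f_katp * g_katp * (k_o / 5.4) ** exponent * (v_m - e_k)


def rhs(t: float, y: np.ndarray, params: ModelParameters,
        stim: float = 0.0) -> np.ndarray:
    """Time derivative of the state vector; ``stim`` is the inward
    stimulus amplitude in uA/uF (book-kept as a K+ flux)."""
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state passed to rhs")
    p = params.vec.copy()
    p[PIDX["stim"]] = stim
    return shannon.rhs(float(t), np.asarray(y, dtype=float), p)
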