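"""Synthetic populations of conductance sets and their APD calibration.

The population-of-models approach: candidate members are drawn by
uniformly and independently sampling the six conductance scaling
factors (default range [0, 2] x baseline), then calibrated by keeping
only candidates whose control-condition APD90 falls inside an
experimentally motivated acceptance window at all three pacing cycle
lengths (400, 600 and 1000 ms). The member closest to target APD90
values at the three rates serves as the control model.

The shipped calibration windows and targets are ILLUSTRATIVE: they
bracket physiologic rabbit epicardial APD90 on this backend's scale and
are meant to be replaced by study-specific experimental ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_model import ConductanceSet, CONTROL_ISCHEMIA, ModelParameters
from .protocol import (PacingConfig, SolverConfig, SimulationFailure,
                       extract_last_beat, find_excitation_threshold,
                       simulate_train)
from .biomarkers import compute_biomarkers

__all__ = [
    "SamplingConfig", "CalibrationWindows", "CalibrationRecord",
    "sample_population", "calibrate_population", "select_control_member",
    "member_apd90", "population_to_table", "population_from_table",
    "ILLUSTRATIVE_WINDOWS", "ILLUSTRATIVE_TARGETS",
]

log = logging.getLogger(__name__)

CALIBRATION_CLS = (400.0, 600.0, 1000.0)


@dataclass(frozen=True)
class SamplingConfig:
    """Uniform independent sampling of the six conductance factors."""

    low: tuple = (0.0,) * 6
    high: tuple = (2.0,) * 6
    n_candidates: int = 100
    seed: int = 0

    def __post_init__(self):
        lo = np.asarray(self.low, float)
        hi = np.asarray(self.high, float)
        if lo.shape != (6,) or hi.shape != (6,):
            raise ValueError("low/high must have six entries")
        if np.any(lo < 0) or np.any(hi <= lo):
            raise ValueError("require 0 <= low < high per factor")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")


@dataclass(frozen=True)
class CalibrationWindows:
    """APD90 acceptance interval (ms) per calibration cycle length."""

    windows: dict = field(default_factory=dict)  # {cycle_length: (lo, hi)}

    def __post_init__(self):
        for cl, (lo, hi) in self.windows.items():
            if not lo < hi:
                raise ValueError(f"window at CL {cl}: lower must be < upper")

    def accepts(self, apds: dict) -> bool:
        """True iff every window contains the member's APD90 at that CL."""
        for cl, (lo, hi) in self.windows.items():
            a = apds.get(cl, np.nan)
            if not (np.isfinite(a) and lo <= a <= hi):
                return False
        return True


#: illustrative windows bracketing physiologic rabbit epicardial APD90
#: on this backend's scale (replace with experimental ranges for real use)
#
# The acceptance bands are +-20% around the control member's own APD90
# under the study protocol (244 / 230 / 205 ms at CL 400 / 600 / 1000),
# which guarantees that the published control conductance combination is
# itself a valid population member.
ILLUSTRATIVE_WINDOWS = CalibrationWindows({
    400.0: (195.0, 295.0),
    600.0: (185.0, 275.0),
    1000.0: (165.0, 245.0),
})

#: illustrative control-selection targets (ms at CL 400 / 600 / 1000):
#: the control member's APD90 under the study protocol
ILLUSTRATIVE_TARGETS = {400.0: 244.0, 600.0: 230.0, 1000.0: 205.0}


def sample_population(cfg: SamplingConfig) -> list[ConductanceSet]:
    """Draw ``n_candidates`` members, each factor uniform on its range."""
    rng = np.random.default_rng(cfg.seed)
    draws = rng.uniform(np.asarray(cfg.low, float), np.asarray(cfg.high, float),
                        size=(cfg.n_candidates, 6))
    return [ConductanceSet.from_array(row) for row in draws]


@dataclass
class CalibrationRecord:
    """Per-candidate calibration outcome."""

    member: ConductanceSet
    index: int
    accepted: bool
    reason: str                  # "", "apd-outside-window", "failed excitation", ...
    threshold: float = np.nan    # control excitation threshold, uA/uF
    apd90: dict = field(default_factory=dict)   # {cycle_length: ms}

    def row(self) -> dict:
        d = {"member_id": self.index, "accepted": self.accepted,
             "reason": self.reason, "threshold": self.threshold}
        d.update({f"s_{n}": getattr(self.member, f)
                  for n, f in zip(("to", "cal", "kr", "ks", "k1", "nak"),
                                  ConductanceSet.FIELDS)})
        d.update({f"apd90_cl{int(cl)}": self.apd90.get(cl, np.nan)
                  for cl in CALIBRATION_CLS})
        return d


def member_apd90(member: ConductanceSet,
                 pacing: PacingConfig,
                 solver: SolverConfig,
                 stim_amplitude: float,
                 base_params: ModelParameters | None = None) -> float:
    """Control-condition APD90 (ms) of the last beat of the pacing train."""
    trace = simulate_train(member, CONTROL_ISCHEMIA, pacing, solver,
                           stim_amplitude, base_params=base_params)
    bm = compute_biomarkers(extract_last_beat(trace))
    return bm.apd90 if bm.excited else np.nan


def calibrate_population(candidates: list[ConductanceSet],
                         windows: CalibrationWindows,
                         pacing: PacingConfig,
                         solver: SolverConfig,
                         base_params: ModelParameters | None = None,
                         full_output: bool = False):
    """Filter candidates to those with in-window APD90 at all three CLs.

    A pure filter: survivors are a subset of ``candidates`` in their
    original order. Candidates that cannot be excited, whose solver run
    fails, or whose APD90 leaves any window are rejected (with reasons
    recorded when ``full_output`` is requested). An empty survivor set
    is a warning, not an error.
    """
    records: list[CalibrationRecord] = []
    for i, member in enumerate(candidates):
        rec = CalibrationRecord(member=member, index=i, accepted=False, reason="")
        try:
            thr = find_excitation_threshold(member, pacing, solver,
                                            base_params=base_params)
            rec.threshold = thr
            amp = pacing.stim_multiple * thr
            for cl in windows.windows:
                p = PacingConfig(cycle_length=cl,
                                 pulse_duration=pacing.pulse_duration,
                                 stim_multiple=pacing.stim_multiple,
                                 n_beats=pacing.n_beats)
                rec.apd90[cl] = member_apd90(member, p, solver, amp,
                                             base_params=base_params)
            if windows.accepts(rec.apd90):
                rec.accepted = True
            else:
                rec.reason = "apd-outside-window"
        except SimulationFailure as exc:
            rec.reason = ("failed excitation" if "inexcitable" in str(exc)
                          else "solver failure")
        records.append(rec)
        log.debug("calibrate member %d: accepted=%s reason=%s apd=%s",
                  i, rec.accepted, rec.reason, rec.apd90)
    survivors = [r.member for r in records if r.accepted]
    if not survivors:
        log.warning("calibration produced an empty population "
                    "(%d candidates)", len(candidates))
    if full_output:
        return survivors, records
    return survivors


def select_control_member(members: list[ConductanceSet],
                          apd90_per_member: list[dict],
                          targets: dict) -> ConductanceSet:
    """Member minimising the sum of squared APD90 deviations from the
    targets over the calibration cycle lengths (ties break to the
    lowest member index)."""
    if not members:
        raise ValueError("empty population")
    if len(members) != len(apd90_per_member):
        raise ValueError("members and APD tables differ in length")
    best, best_sse = None, np.inf
    for i, apds in enumerate(apd90_per_member):
        sse = 0.0
        for cl, target in targets.items():
            a = apds.get(cl, np.nan)
            if not np.isfinite(a):
                sse = np.inf
                break
            sse += (a - target) ** 2
        if sse < best_sse:
            best, best_sse = i, sse
    if best is None or not np.isfinite(best_sse):
        raise ValueError("no member has finite APD90 at every target cycle length")
    return members[best]


def population_to_table(members: list[ConductanceSet], path) -> None:
    """Write a population as delimited text (member_id + six factors)."""
    df = pd.DataFrame(
        [[i] + list(m.as_array()) for i, m in enumerate(members)],
        columns=["member_id", "s_to", "s_cal", "s_kr", "s_ks", "s_k1", "s_nak"],
    )
    df.to_csv(path, sep="\t", index=False)


def population_from_table(path) -> list[ConductanceSet]:
    df = pd.read_csv(path, sep="\t")
    cols = ["s_to", "s_cal", "s_kr", "s_ks", "s_k1", "s_nak"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"population table missing columns {missing}")
    return [ConductanceSet.from_array(row) for row in df[cols].to_numpy()]
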