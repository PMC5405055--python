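"""Pacing protocol, stimulus-threshold search, and numerical integration.

The study protocol: 10 stimulated beats at a cycle length of 600 ms
(calibration also uses 400 and 1000 ms) with 3 ms pulses at 1.5x the
member's excitation threshold measured in control; the same amplitude is
reused unchanged at every ischemic severity of that member. Integration
uses an adaptive stiff solver (LSODA) at rtol 1e-7 / atol 1e-9 with a
compiled finite-difference Jacobian, and traces are resampled onto a
uniform 0.05 ms grid for biomarker extraction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.integrate import solve_ivp

from . import shannon
from .cell_model import (ConductanceSet, IschemiaState, ModelParameters,
                         CONTROL_ISCHEMIA, apply_ischemia, apply_member,
                         baseline_parameters)

__all__ = [
    "PacingConfig", "SolverConfig", "Trace", "SimulationFailure",
    "simulate_train", "extract_last_beat", "find_excitation_threshold",
]


class SimulationFailure(RuntimeError):
    """The stiff solver failed or produced non-finite states."""


@dataclass(frozen=True)
class PacingConfig:
    cycle_length: float = 600.0   # ms
    pulse_duration: float = 3.0   # ms
    stim_multiple: float = 1.5    # x excitation threshold
    n_beats: int = 10

    def __post_init__(self):
        if self.pulse_duration >= self.cycle_length:
            raise ValueError("pulse_duration must be < cycle_length")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.stim_multiple <= 1:
            raise ValueError("stim_multiple must be > 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-7
    atol: float = 1e-9
    max_step: float = np.inf   # ms
    output_dt: float = 0.05    # ms, uniform resampling interval

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0 or self.output_dt <= 0:
            raise ValueError("rtol, atol and output_dt must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["max_step"] = None if np.isinf(self.max_step) else self.max_step
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SolverConfig":
        d = dict(d)
        if d.get("max_step") is None:
            d["max_step"] = np.inf
        return cls(**d)


@dataclass
class Trace:
    """Uniformly sampled voltage / Na-gate trace of a pacing run."""

    time: np.ndarray          # ms, uniform strictly increasing grid
    vm: np.ndarray            # mV
    hj: np.ndarray            # product of the I_Na inactivation gates
    stim_onsets: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    states: np.ndarray | None = None   # optional (n_samples, n_states)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        self.hj = np.asarray(self.hj, dtype=float)
        self.stim_onsets = np.atleast_1d(np.asarray(self.stim_onsets, dtype=float))
        if self.time.size == 0:
            raise ValueError("empty trace")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("trace time grid must be strictly increasing")
        if self.time.shape != self.vm.shape or self.time.shape != self.hj.shape:
            raise ValueError("time, vm and hj must have equal length")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else np.nan

    def save(self, path) -> None:
        """Write as delimited text: one header line plus time/Vm/hj columns;
        stimulus onsets are carried in a leading comment."""
        onsets = " ".join(f"{t:.6g}" for t in self.stim_onsets)
        buf = io.StringIO()
        buf.write(f"# stim_onsets_ms: {onsets}\n")
        buf.write("time_ms\tVm_mV\thj\n")
        np.savetxt(buf, np.column_stack([self.time, self.vm, self.hj]),
                   fmt="%.10g", delimiter="\t")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "Trace":
        onsets = [0.0]
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# stim_onsets_ms:"):
                onsets = [float(x) for x in first.split(":", 1)[1].split()]
            else:
                fh.seek(0)
            data = np.loadtxt(fh, delimiter="\t", skiprows=1)
        data = np.atleast_2d(data)
        return cls(time=data[:, 0], vm=data[:, 1], hj=data[:, 2],
                   stim_onsets=np.array(onsets))


def _integrate(y, p, t0, t1, solver, t_eval=None):
    sol = solve_ivp(shannon.rhs, (t0, t1), y, method="LSODA", args=(p,),
                    jac=shannon.fd_jacobian, rtol=solver.rtol,
                    atol=solver.atol, max_step=solver.max_step,
                    t_eval=t_eval, dense_output=False)
    if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
        raise SimulationFailure(sol.message)
    return sol


def simulate_train(member: ConductanceSet,
                   isch: IschemiaState,
                   pacing: PacingConfig,
                   solver: SolverConfig,
                   stim_amplitude: float,
                   base_params: ModelParameters | None = None,
                   y0: np.ndarray | None = None,
                   record: str = "last",
                   keep_states: bool = False) -> Trace:
    """Run a stimulated-beat train and return the resampled trace.

    ``stim_amplitude`` is the inward pulse amplitude in uA/uF (the
    caller fixes it to stim_multiple x the member's control threshold,
    and reuses it unchanged across ischemic severities).

    ``record`` selects the uniformly resampled window: ``"last"`` keeps
    only the final beat (cheapest; the study analyses the last AP),
    ``"all"`` keeps the whole train. Returned times are absolute (the
    final-beat window starts at ``(n_beats - 1) * cycle_length``).
    """
    if record not in ("last", "all"):
        raise ValueError("record must be 'last' or 'all'")
    base = baseline_parameters() if base_params is None else base_params
    params = apply_member(base, member)
    start = shannon.RESTING_STATE if y0 is None else y0
    params, y = apply_ischemia(params, start, isch)

    p_on = params.vec.copy()
    p_on[shannon.PIDX["stim"]] = float(stim_amplitude)
    p_off = params.vec.copy()

    cl = pacing.cycle_length
    dt = solver.output_dt
    onsets = np.arange(pacing.n_beats) * cl

    times, vms, hjs, states = [], [], [], []
    for b in range(pacing.n_beats):
        t0 = b * cl
        sampled = record == "all" or b == pacing.n_beats - 1
        # stimulus-on segment
        if sampled:
            te = np.arange(np.ceil(t0 / dt) * dt, t0 + pacing.pulse_duration, dt)
            te = np.unique(np.concatenate([te, [t0 + pacing.pulse_duration]]))
            te = te[te >= t0]
        else:
            te = None
        sol = _integrate(y, p_on, t0, t0 + pacing.pulse_duration, solver, te)
        if sampled:
            keep = sol.t < t0 + pacing.pulse_duration
            times.append(sol.t[keep]); vms.append(sol.y[0, keep])
            hjs.append(sol.y[shannon.IDX_H, keep] * sol.y[shannon.IDX_J, keep])
            if keep_states:
                states.append(sol.y[:, keep].T)
        y = sol.y[:, -1]
        # stimulus-off remainder of the cycle
        if sampled:
            lo = np.ceil((t0 + pacing.pulse_duration) / dt) * dt
            te = np.arange(lo, t0 + cl, dt)
            te = np.unique(np.concatenate([te, [t0 + cl]]))
        else:
            te = None
        sol = _integrate(y, p_off, t0 + pacing.pulse_duration, t0 + cl, solver, te)
        if sampled:
            last = b == pacing.n_beats - 1
            keep = sol.t <= t0 + cl if last else sol.t < t0 + cl
            times.append(sol.t[keep]); vms.append(sol.y[0, keep])
            hjs.append(sol.y[shannon.IDX_H, keep] * sol.y[shannon.IDX_J, keep])
            if keep_states:
                states.append(sol.y[:, keep].T)
        y = sol.y[:, -1]

    time = np.concatenate(times)
    trace = Trace(
        time=time,
        vm=np.concatenate(vms),
        hj=np.concatenate(hjs),
        stim_onsets=onsets if record == "all" else onsets[-1:],
        states=np.vstack(states) if keep_states else None,
    )
    return trace


def extract_last_beat(trace: Trace) -> Trace:
    """Sub-trace from the final stimulus onset onward, time re-zeroed."""
    if trace.stim_onsets.size == 0:
        raise ValueError("trace has no stimulus onsets")
    t_on = trace.stim_onsets[-1]
    i0 = int(np.searchsorted(trace.time, t_on - 1e-9))
    if i0 >= trace.time.size:
        raise ValueError("final stimulus onset beyond end of trace")
    return Trace(
        time=trace.time[i0:] - trace.time[i0],
        vm=trace.vm[i0:],
        hj=trace.hj[i0:],
        stim_onsets=np.array([0.0]),
        states=None if trace.states is None else trace.states[i0:],
    )


def find_excitation_threshold(member: ConductanceSet,
                              pacing: PacingConfig,
                              solver: SolverConfig,
                              base_params: ModelParameters | None = None,
                              train_beats: int = 3,
                              bracket_hi: float = 8.0,
                              bracket_max: float = 80.0,
                              rel_tol: float = 0.01) -> float:
    """Minimal 3 ms pulse amplitude (uA/uF) that elicits an AP in control.

    Excitation is judged on the final beat of a short train by the 44 mV
    amplitude criterion. The upper bracket is doubled until it excites
    (up to ``bracket_max``), then the threshold is bisected to
    ``rel_tol`` relative accuracy; the returned amplitude excites.
    """
    from .biomarkers import detect_ap

    train = PacingConfig(cycle_length=pacing.cycle_length,
                         pulse_duration=pacing.pulse_duration,
                         stim_multiple=pacing.stim_multiple,
                         n_beats=train_beats)

    def excites(amp: float) -> bool:
        if amp <= 0:
            return False
        try:
            tr = simulate_train(member, CONTROL_ISCHEMIA, train, solver, amp,
                                base_params=base_params, record="last")
        except SimulationFailure:
            return False
        return detect_ap(extract_last_beat(tr))

    lo, hi = 0.0, bracket_hi
    while not excites(hi):
        hi *= 2.0
        if hi > bracket_max:
            raise SimulationFailure(
                f"inexcitable member: no AP up to {bracket_max} uA/uF")
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if excites(mid):
            hi = mid
        else:
            lo = mid
    return hi
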