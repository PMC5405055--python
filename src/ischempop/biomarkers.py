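"""AP morphology and refractoriness biomarkers from a single-beat trace.

Definitions used throughout the study:

* an AP occurred iff the amplitude of the Vm response to the last
  stimulus is at least 44 mV (strictly smaller is a failed excitation);
* V_rest is Vm at the stimulus onset of the analysed beat;
* dV/dt_max is computed by central differences on the uniform grid;
* APD90 runs from the sample of dV/dt_max to the first subsequent
  crossing of Vm below V_rest + 0.1 * (V_max - V_rest), with linear
  interpolation between samples;
* ERP is proxied by recovery of the I_Na inactivation-gate product:
  the first instant after the upstroke at which h*j exceeds 0.012,
  measured from the stimulus onset (and also reported relative to the
  upstroke). If h*j never recovers within the beat window, ERP is
  censored at >= cycle length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .protocol import Trace

__all__ = ["APBiomarkers", "HJ_THRESHOLD", "AP_AMPLITUDE_THRESHOLD",
           "detect_ap", "apd90", "erp_from_gates", "compute_biomarkers"]

#: minimum Vm excursion (mV) for a stimulation to count as an AP
AP_AMPLITUDE_THRESHOLD = 44.0
#: h*j product above which the cell is considered re-excitable
HJ_THRESHOLD = 0.012


@dataclass
class APBiomarkers:
    """Biomarkers of one analysed beat; non-excited beats carry NaNs."""

    excited: bool
    v_rest: float = np.nan      # mV
    v_max: float = np.nan       # mV
    dvdt_max: float = np.nan    # mV/ms
    apd90: float = np.nan       # ms
    erp: float = np.nan         # ms, from stimulus onset
    erp_from_upstroke: float = np.nan  # ms, from the dV/dt_max sample
    erp_censored: bool = False  # True: h*j never recovered (ERP >= window)
    unrepolarised: bool = False  # True: no 90% repolarisation in the window

    def to_dict(self) -> dict:
        return asdict(self)


def _onset_index(beat: Trace) -> int:
    return 0   # single-beat traces are re-zeroed to the stimulus onset


def detect_ap(beat: Trace) -> bool:
    """True iff the Vm excursion from the stimulus onset reaches 44 mV."""
    amplitude = float(np.max(beat.vm) - beat.vm[_onset_index(beat)])
    return amplitude >= AP_AMPLITUDE_THRESHOLD


def _dvdt(beat: Trace) -> np.ndarray:
    return np.gradient(beat.vm, beat.time)


def _upstroke_index(beat: Trace) -> int:
    return int(np.argmax(_dvdt(beat)))


def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t0
    return t0 + (t1 - t0) * (level - v0) / (v1 - v0)


def apd90(beat: Trace) -> float:
    """APD at 90% repolarisation (ms); NaN if the beat never repolarises."""
    v_rest = beat.vm[_onset_index(beat)]
    v_max = float(np.max(beat.vm))
    level = v_rest + 0.1 * (v_max - v_rest)
    iup = _upstroke_index(beat)
    t_up = beat.time[iup]
    # central differencing can anchor one sample before the depolarised
    # phase; start the search at the first post-upstroke sample above
    # the repolarisation level
    above = np.nonzero(beat.vm[iup:] > level)[0]
    if above.size == 0:
        return 0.0   # never above the level: immediate "repolarisation"
    i0 = iup + above[0]
    below = np.nonzero(beat.vm[i0:] <= level)[0]
    if below.size == 0:
        return np.nan
    k = i0 + below[0]
    t_cross = _interp_crossing(beat.time[k - 1], beat.time[k],
                               beat.vm[k - 1], beat.vm[k], level)
    return float(t_cross - t_up)


def erp_from_gates(beat: Trace, reference: str = "onset") -> float:
    """Time to Na-channel availability recovery, h*j > 0.012 (ms).

    ``reference`` selects the time origin: ``"onset"`` (stimulus onset,
    the default) or ``"upstroke"`` (the dV/dt_max sample). Returns NaN
    if h*j never exceeds the threshold within the beat window (ERP
    censored at >= cycle length).
    """
    if reference not in ("onset", "upstroke"):
        raise ValueError("reference must be 'onset' or 'upstroke'")
    iup = _upstroke_index(beat)
    t_ref = 0.0 if reference == "onset" else float(beat.time[iup])
    hj = beat.hj
    # inactivation completes shortly after the upstroke; ERP is the first
    # upward recovery crossing after that
    below = np.nonzero(hj[iup:] <= HJ_THRESHOLD)[0]
    if below.size == 0:
        # gates never inactivated below threshold: immediately re-excitable
        return float(beat.time[iup] - t_ref)
    i0 = iup + below[0]
    above = np.nonzero(hj[i0:] > HJ_THRESHOLD)[0]
    if above.size == 0:
        return np.nan
    k = i0 + above[0]
    t_cross = _interp_crossing(beat.time[k - 1], beat.time[k],
                               hj[k - 1], hj[k], HJ_THRESHOLD)
    return float(t_cross - t_ref)


def compute_biomarkers(beat: Trace) -> APBiomarkers:
    """Assemble all biomarkers for one single-beat trace."""
    if beat.time.size < 3:
        raise ValueError("beat trace too short for biomarker extraction")
    if not detect_ap(beat):
        return APBiomarkers(excited=False)
    v_rest = float(beat.vm[_onset_index(beat)])
    v_max = float(np.max(beat.vm))
    dv = _dvdt(beat)
    a90 = apd90(beat)
    erp = erp_from_gates(beat, "onset")
    erp_up = erp_from_gates(beat, "upstroke")
    return APBiomarkers(
        excited=True,
        v_rest=v_rest,
        v_max=v_max,
        dvdt_max=float(np.max(dv)),
        apd90=a90,
        erp=erp,
        erp_from_upstroke=erp_up,
        erp_censored=bool(np.isnan(erp)),
        unrepolarised=bool(np.isnan(a90)),
    )
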