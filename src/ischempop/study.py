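"""Convenience builders for the standard study population.

Both the test suite and the reproduction script need the same object: a
calibrated synthetic population of at least ``n_min`` members with their
control excitation thresholds. This module builds it from a single seed
under the study's default conditions (uniform sampling on [0, 2] per
conductance, the illustrative APD90 calibration windows, 10-beat pacing
at the study cycle lengths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_model import ConductanceSet
from .population import (SamplingConfig, ILLUSTRATIVE_WINDOWS,
                         calibrate_population, sample_population)
from .protocol import PacingConfig, SolverConfig

__all__ = ["StudyPopulation", "build_study_population"]


@dataclass
class StudyPopulation:
    """Calibrated members with their control thresholds and APD90s."""

    members: list            # ConductanceSet per member
    thresholds: np.ndarray   # control excitation threshold, uA/uF
    apd90: list              # {cycle_length: ms} per member
    member_ids: np.ndarray   # candidate indices (stable IDs)
    n_candidates: int
    pacing: PacingConfig
    solver: SolverConfig

    def __len__(self) -> int:
        return len(self.members)

    def stim_amplitude(self, i: int) -> float:
        return self.pacing.stim_multiple * float(self.thresholds[i])


def build_study_population(seed: int,
                           n_min: int = 50,
                           n_candidates: int = 400,
                           pacing: PacingConfig | None = None,
                           solver: SolverConfig | None = None,
                           windows=ILLUSTRATIVE_WINDOWS) -> StudyPopulation:
    """Sample and calibrate until at least ``n_min`` members survive.

    Candidates are drawn once (``n_candidates``, uniform on [0, 2] per
    factor) and calibrated in order; the population keeps the first
    ``n_min`` survivors, preserving candidate order, so the result is
    reproducible from the seed alone. Raises if the candidate budget
    yields fewer than ``n_min`` survivors.
    """
    pacing = pacing or PacingConfig()
    solver = solver or SolverConfig()
    candidates = sample_population(SamplingConfig(n_candidates=n_candidates,
                                                  seed=seed))
    # calibrate in chunks so we stop as soon as n_min members survived
    kept: list = []
    records_all = []
    chunk = max(4 * n_min, 50)
    for lo in range(0, n_candidates, chunk):
        batch = candidates[lo:lo + chunk]
        _, records = calibrate_population(batch, windows, pacing, solver,
                                          full_output=True)
        for r in records:
            r.index += lo
        records_all.extend(records)
        kept = [r for r in records_all if r.accepted]
        if len(kept) >= n_min:
            break
    if len(kept) < n_min:
        raise RuntimeError(
            f"only {len(kept)} of {len(records_all)} candidates survived "
            f"calibration; raise n_candidates")
    kept = kept[:n_min]
    return StudyPopulation(
        members=[r.member for r in kept],
        thresholds=np.array([r.threshold for r in kept]),
        apd90=[r.apd90 for r in kept],
        member_ids=np.array([r.index for r in kept]),
        n_candidates=len(records_all),
        pacing=pacing,
        solver=solver,
    )
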