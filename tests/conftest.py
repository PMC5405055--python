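import numpy as np
import pytest

from ischempop.cell_model import CONTROL_MEMBER
from ischempop.protocol import (PacingConfig, SolverConfig, Trace,
                                find_excitation_threshold)


@pytest.fixture(scope="session")
def solver():
    return SolverConfig()


@pytest.fixture(scope="session")
def pacing():
    return PacingConfig()


@pytest.fixture(scope="session")
def control_threshold(pacing, solver):
    """Control-condition excitation threshold of the control member."""
    return find_excitation_threshold(CONTROL_MEMBER, pacing, solver)


@pytest.fixture(scope="session")
def control_amplitude(pacing, control_threshold):
    return pacing.stim_multiple * control_threshold


def make_triangle_beat(v_rest=-85.0, v_max=35.0, slope=-0.6, dt=0.05,
                       total=600.0, t_up=2.0):
    """Synthetic beat: instantaneous upstroke at t_up, then linear
    repolarisation at ``slope`` mV/ms; closed-form APD90 available."""
    t = np.arange(0.0, total, dt)
    vm = np.full_like(t, v_rest)
    rise = t >= t_up
    vm[rise] = np.maximum(v_max + slope * (t[rise] - t_up), v_rest)
    hj = np.full_like(t, 0.5)
    return Trace(time=t, vm=vm, hj=hj, stim_onsets=np.array([0.0]))


@pytest.fixture
def triangle_beat():
    return make_triangle_beat()


@pytest.fixture(scope="session")
def study_population():
    """Shared calibrated synthetic population (>= 50 members).

    Session-scoped: built once and reused by all population-level
    tests (the expensive part is the calibration filter).
    """
    from ischempop.study import build_study_population
    return build_study_population(seed=2024, n_min=50)


@pytest.fixture(scope="session")
def population_results(study_population):
    """Biomarkers of the shared population across the ischemia schedule.

    Simulates every member at t = 0, 2, 6, 8, 10 min for the K12 and
    K17 presets (the mild and severe hyperkalemia endpoints) and
    returns one tidy table.
    """
    import pandas as pd
    from ischempop.runner import simulate_member_biomarkers
    from ischempop.schedule import PRESETS, schedule_at

    pop = study_population
    rows = []
    for preset in ("K12", "K17"):
        for tmin in (0.0, 2.0, 6.0, 8.0, 10.0):
            if preset == "K17" and tmin == 0.0:
                continue   # t = 0 is identical across presets
            isch = schedule_at(tmin, PRESETS[preset])
            for i, member in enumerate(pop.members):
                row = simulate_member_biomarkers(
                    member, isch, pop.pacing, pop.solver,
                    pop.stim_amplitude(i))
                row.update(member_id=int(pop.member_ids[i]),
                           time_min=tmin, preset=preset)
                rows.append(row)
    df = pd.DataFrame(rows)
    ctrl = df.loc[(df["preset"] == "K12") & (df["time_min"] == 0.0)].copy()
    ctrl["preset"] = "K17"
    return pd.concat([df, ctrl], ignore_index=True)
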