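"""Pacing, threshold search, trace handling and solver behaviour."""

import numpy as np
import pytest

from ischempop.cell_model import CONTROL_MEMBER, CONTROL_ISCHEMIA, ConductanceSet
from ischempop.biomarkers import compute_biomarkers, detect_ap
from ischempop.protocol import (PacingConfig, SolverConfig, Trace,
                                extract_last_beat, find_excitation_threshold,
                                simulate_train)


class TestExtractLastBeat:
    def test_ten_beat_window_arithmetic(self):
        """A 10-beat CL-600 trace yields the window [5400, 6000) ms,
        re-zeroed to the final onset."""
        dt = 0.5
        t = np.arange(0.0, 6000.0, dt)
        tr = Trace(time=t, vm=np.full_like(t, -85.0),
                   hj=np.full_like(t, 0.5),
                   stim_onsets=np.arange(10) * 600.0)
        beat = extract_last_beat(tr)
        assert beat.time[0] == 0.0
        assert beat.time[-1] == pytest.approx(599.5)
        assert beat.time.size == 1200

    def test_single_beat_identity_up_to_rezero(self):
        t = np.arange(100.0, 400.0, 0.5)
        tr = Trace(time=t, vm=np.linspace(-85, -80, t.size),
                   hj=np.full_like(t, 0.5), stim_onsets=np.array([100.0]))
        beat = extract_last_beat(tr)
        assert beat.time[0] == 0.0
        np.testing.assert_array_equal(beat.vm, tr.vm)

    def test_empty_onsets_rejected(self):
        t = np.arange(0.0, 10.0, 0.5)
        tr = Trace(time=t, vm=np.zeros_like(t), hj=np.zeros_like(t),
                   stim_onsets=np.array([]))
        with pytest.raises(ValueError):
            extract_last_beat(tr)


class TestTraceIO:
    def test_roundtrip(self, tmp_path):
        t = np.arange(0.0, 5.0, 0.05)
        tr = Trace(time=t, vm=-85 + 10 * np.sin(t), hj=0.5 * np.ones_like(t),
                   stim_onsets=np.array([0.0, 2.5]))
        path = tmp_path / "trace.tsv"
        tr.save(path)
        back = Trace.load(path)
        np.testing.assert_allclose(back.time, tr.time, rtol=1e-9)
        np.testing.assert_allclose(back.vm, tr.vm, rtol=1e-9)
        np.testing.assert_allclose(back.hj, tr.hj, rtol=1e-9)
        np.testing.assert_allclose(back.stim_onsets, tr.stim_onsets)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            Trace(time=np.array([0.0, 0.0, 1.0]), vm=np.zeros(3),
                  hj=np.zeros(3))


class TestSimulateTrain:
    def test_deterministic_repeat(self, solver, control_amplitude):
        """Identical configuration gives bit-identical resampled traces."""
        pac = PacingConfig(n_beats=2)
        a = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pac, solver,
                           control_amplitude)
        b = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pac, solver,
                           control_amplitude)
        np.testing.assert_array_equal(a.vm, b.vm)
        np.testing.assert_array_equal(a.hj, b.hj)

    def test_first_beat_independent_of_train_length(self, solver,
                                                    control_amplitude):
        """With identical initial state the first beat of a 1-beat and a
        2-beat train coincide (determinism of the integrator)."""
        pac1 = PacingConfig(n_beats=1)
        pac2 = PacingConfig(n_beats=2)
        a = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pac1, solver,
                           control_amplitude, record="all")
        b = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pac2, solver,
                           control_amplitude, record="all")
        n = a.time.size
        np.testing.assert_allclose(a.vm, b.vm[:n], atol=1e-6)

    def test_uniform_grid_and_onsets(self, solver, control_amplitude):
        pac = PacingConfig(n_beats=3)
        tr = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pac, solver,
                            control_amplitude, record="all")
        assert np.allclose(np.diff(tr.time), solver.output_dt, atol=1e-9)
        np.testing.assert_allclose(tr.stim_onsets, [0.0, 600.0, 1200.0])
        last = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pac, solver,
                              control_amplitude, record="last")
        assert last.time[0] == pytest.approx(1200.0)

    def test_tolerance_convergence(self, pacing, solver, control_amplitude):
        """Tightening rtol/atol tenfold moves final-beat APD90 by
        < 0.5 ms: the default tolerances are converged."""
        from ischempop.biomarkers import compute_biomarkers
        tight = SolverConfig(rtol=solver.rtol / 10, atol=solver.atol / 10,
                             output_dt=solver.output_dt)
        a = compute_biomarkers(extract_last_beat(
            simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pacing, solver,
                           control_amplitude)))
        b = compute_biomarkers(extract_last_beat(
            simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pacing, tight,
                           control_amplitude)))
        assert abs(a.apd90 - b.apd90) < 0.5


class TestThreshold:
    def test_null_stimulus_elicits_nothing(self, solver):
        """Zero amplitude is a valid lower bracket: no AP."""
        pac = PacingConfig(n_beats=1)
        tr = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pac, solver, 0.0)
        assert not detect_ap(extract_last_beat(tr))

    def test_threshold_finite_positive_and_tight(self, pacing, solver,
                                                 control_threshold):
        """The control member's threshold is finite and positive;
        stimulating at it succeeds and at 0.99x it fails."""
        thr = control_threshold
        assert 0 < thr < 80
        pac = PacingConfig(n_beats=3)
        above = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pac, solver,
                               thr)
        below = simulate_train(CONTROL_MEMBER, CONTROL_ISCHEMIA, pac, solver,
                               0.99 * thr)
        assert detect_ap(extract_last_beat(above))
        assert not detect_ap(extract_last_beat(below))

    def test_bisection_matches_linear_scan(self, solver):
        """The bisected threshold agrees with an exhaustive 0.1 uA/uF
        grid scan to within one grid step (single-beat train)."""
        pac = PacingConfig(n_beats=1)
        thr = find_excitation_threshold(ConductanceSet(), pac, solver,
                                        train_beats=1)
        lo = max(0.1, thr - 1.0)
        grid = np.arange(lo, thr + 1.0, 0.1)
        scan = None
        for amp in grid:
            tr = simulate_train(ConductanceSet(), CONTROL_ISCHEMIA, pac,
                                solver, amp)
            if detect_ap(extract_last_beat(tr)):
                scan = amp
                break
        assert scan is not None
        # one grid step plus the bisection's own 1% relative tolerance
        assert abs(scan - thr) <= 0.1 + 0.01 * thr + 1e-9

    def test_inexcitable_member_raises(self, solver):
        """A member that cannot fire within the bracket is reported as
        inexcitable (here: no fast Na+ current at all and no Ca window,
        via zero L-type conductance and a tiny bracket)."""
        from ischempop.protocol import SimulationFailure
        pac = PacingConfig(n_beats=1)
        quenched = ConductanceSet(s_cal=0.0, s_k1=2.0)
        with pytest.raises(SimulationFailure, match="inexcitable"):
            find_excitation_threshold(quenched, pac, solver, train_beats=1,
                                      bracket_hi=0.5, bracket_max=1.0)
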