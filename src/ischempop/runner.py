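"""Experiment orchestration: sample -> calibrate -> simulate -> analyse.

A :class:`RunConfig` fully determines an experiment; a saved config plus
its seed re-runs to identical outputs. Per-member simulations are
independent and order-free by contract: each uses only the member's own
parameters, threshold and the shared initial state.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cell_model import ConductanceSet, IschemiaState
from .schedule import ScheduleConfig, PRESETS, schedule_at
from .protocol import (PacingConfig, SolverConfig, SimulationFailure,
                       extract_last_beat, simulate_train)
from .biomarkers import compute_biomarkers
from .population import (CalibrationWindows, SamplingConfig,
                         ILLUSTRATIVE_TARGETS, ILLUSTRATIVE_WINDOWS,
                         calibrate_population, sample_population,
                         select_control_member, population_to_table)
from .analysis import (PopulationResult, population_summary,
                       column_plot_matrix, plot_columns, GridSpec)

__all__ = ["RunConfig", "run_experiment", "simulate_member_biomarkers",
           "single_factor_states", "run_grid_sweep", "render_figures"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serialisable configuration of a complete experiment."""

    backend: str = "shannon"
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    windows: CalibrationWindows = field(default_factory=lambda: ILLUSTRATIVE_WINDOWS)
    control_targets: dict = field(default_factory=lambda: dict(ILLUSTRATIVE_TARGETS))
    pacing: PacingConfig = field(default_factory=PacingConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    presets: tuple = ("K12",)
    timepoints: tuple = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)  # min
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self):
        if self.backend != "shannon":
            raise ValueError(f"unknown backend {self.backend!r}; only the "
                             "'shannon' backend is implemented")
        unknown = [p for p in self.presets if p not in PRESETS]
        if unknown:
            raise ValueError(f"unknown presets {unknown}")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "backend": self.backend,
            "sampling": {"low": list(self.sampling.low),
                         "high": list(self.sampling.high),
                         "n_candidates": self.sampling.n_candidates,
                         "seed": self.sampling.seed},
            "windows": {str(cl): list(w) for cl, w in self.windows.windows.items()},
            "control_targets": {str(cl): t for cl, t in self.control_targets.items()},
            "pacing": self.pacing.to_dict(),
            "solver": self.solver.to_dict(),
            "presets": list(self.presets),
            "timepoints": list(self.timepoints),
            "outdir": self.outdir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        kw["sampling"] = SamplingConfig(
            low=tuple(d["sampling"]["low"]), high=tuple(d["sampling"]["high"]),
            n_candidates=d["sampling"]["n_candidates"], seed=d["sampling"]["seed"])
        kw["windows"] = CalibrationWindows(
            {float(cl): tuple(w) for cl, w in d["windows"].items()})
        kw["control_targets"] = {float(cl): t
                                 for cl, t in d["control_targets"].items()}
        kw["pacing"] = PacingConfig(**d["pacing"])
        kw["solver"] = SolverConfig.from_dict(d["solver"])
        kw["presets"] = tuple(d["presets"])
        kw["timepoints"] = tuple(d["timepoints"])
        return cls(**kw)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def simulate_member_biomarkers(member: ConductanceSet,
                               isch: IschemiaState,
                               pacing: PacingConfig,
                               solver: SolverConfig,
                               stim_amplitude: float) -> dict:
    """Biomarkers of a member under one condition, with exclusion flags.

    Non-excited and unrepolarised beats are excluded from population
    statistics (with reasons); solver failures likewise.
    """
    try:
        trace = simulate_train(member, isch, pacing, solver, stim_amplitude)
    except SimulationFailure:
        return dict(excluded=True, reason="solver failure", excited=False,
                    v_rest=np.nan, v_max=np.nan, dvdt_max=np.nan,
                    apd90=np.nan, erp=np.nan, erp_censored=False)
    bm = compute_biomarkers(extract_last_beat(trace))
    excluded, reason = False, ""
    if not bm.excited:
        excluded, reason = True, "failed excitation"
    elif bm.unrepolarised:
        excluded, reason = True, "unrepolarised"
    return dict(excluded=excluded, reason=reason, excited=bm.excited,
                v_rest=bm.v_rest, v_max=bm.v_max, dvdt_max=bm.dvdt_max,
                apd90=bm.apd90, erp=bm.erp, erp_censored=bm.erp_censored)


def single_factor_states(cfg: ScheduleConfig) -> dict:
    """Ischemic states with each factor alone at its endpoint value.

    The pump-impairment axis pairs the I_NaK reduction with its
    companion [Na+]i increase (over a 10-beat quasi-static run the pump
    block alone cannot develop the Na+ accumulation that shortens APD).
    """
    return {
        "f_katp": IschemiaState(f_katp=cfg.f_katp_end),
        "f_inhib": IschemiaState(f_inhib=cfg.f_inhib_end),
        "f_nak": IschemiaState(f_nak=cfg.f_nak_end,
                               na_i_offset=cfg.na_i_offset_end),
        "k_o": IschemiaState(k_o=cfg.k_o_end),
    }


def run_experiment(cfg: RunConfig, figures: bool = True) -> PopulationResult:
    """Execute the full pipeline and write all artefacts to cfg.outdir.

    Stages: sample -> calibrate (thresholds + control APD90 at three
    CLs) -> select control member -> per-preset, per-time-point
    simulation of every calibrated member -> biomarker tables,
    summaries, figures and a provenance log. Partial outputs are kept
    if a later stage raises.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("sampling %d candidates (seed %d)",
             cfg.sampling.n_candidates, cfg.sampling.seed)
    candidates = sample_population(cfg.sampling)

    log.info("calibrating against windows %s", cfg.windows.windows)
    survivors, records = calibrate_population(
        candidates, cfg.windows, cfg.pacing, cfg.solver, full_output=True)
    calib = pd.DataFrame([r.row() for r in records])
    calib.to_csv(out / "calibration.tsv", sep="\t", index=False)
    population_to_table(survivors, out / "population.tsv")
    log.info("calibration kept %d / %d members", len(survivors), len(candidates))

    accepted = [r for r in records if r.accepted]
    thresholds = {r.index: r.threshold for r in accepted}
    if accepted:
        control = select_control_member([r.member for r in accepted],
                                        [r.apd90 for r in accepted],
                                        cfg.control_targets)
        pd.DataFrame([control.as_array()],
                     columns=["s_to", "s_cal", "s_kr", "s_ks", "s_k1", "s_nak"]
                     ).to_csv(out / "control_member.tsv", sep="\t", index=False)

    rows = []
    for preset in cfg.presets:
        sched = PRESETS[preset]
        for tmin in cfg.timepoints:
            isch = schedule_at(tmin, sched)
            for rec in accepted:
                amp = cfg.pacing.stim_multiple * thresholds[rec.index]
                row = simulate_member_biomarkers(rec.member, isch, cfg.pacing,
                                                 cfg.solver, amp)
                row.update(member_id=rec.index, time_min=tmin, preset=preset)
                rows.append(row)
            log.info("preset %s t=%g min: %d members simulated",
                     preset, tmin, len(accepted))
    result = PopulationResult(pd.DataFrame(rows)) if rows else None
    if result is not None:
        result.save(out / "biomarkers.tsv")
        summaries = []
        from .analysis import BIOMARKER_METRICS
        for metric in BIOMARKER_METRICS:
            s = population_summary(result, metric)
            s = s.drop(columns=["hist_counts", "hist_edges"])
            s.insert(0, "metric", metric)
            summaries.append(s)
        pd.concat(summaries).to_csv(out / "summary.tsv", sep="\t", index=False)
        if figures:
            render_figures(out)

    provenance = {
        "config": cfg.to_dict(),
        "config_sha256_16": cfg.digest(),
        "seed": cfg.seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return result


def render_figures(outdir) -> list:
    """(Re)generate column-plot PNGs from the saved biomarker table
    alone -- no re-simulation (idempotent post-processing)."""
    out = Path(outdir)
    result = PopulationResult.load(out / "biomarkers.tsv")
    written = []
    for metric in ("apd90", "erp"):
        for preset in sorted(result.table["preset"].unique()):
            try:
                mat, order, times = column_plot_matrix(result, metric, preset)
            except ValueError:
                continue
            path = out / f"columns_{metric}_{preset}.png"
            plot_columns(mat, times, path,
                         title=f"{metric} ({preset}), rows by control APD90")
            written.append(path)
    return written


def run_grid_sweep(grid: GridSpec,
                   isch: IschemiaState,
                   pacing: PacingConfig,
                   solver: SolverConfig,
                   metric: str = "apd90",
                   dims: tuple | None = None,
                   thresholds: np.ndarray | None = None) -> np.ndarray:
    """Evaluate a biomarker on a full-factorial conductance grid (the
    separate sweep mode backing CBDR images). Returns an array of grid
    shape; inexcitable/failed cells are NaN.

    ``dims`` names the ConductanceSet field of each grid dimension
    (default: the first ``len(grid.shape)`` of the six factors);
    factors not on the grid stay at 1.
    """
    from .protocol import find_excitation_threshold

    shape = grid.shape
    if dims is None:
        dims = ConductanceSet.FIELDS[:len(shape)]
    if len(dims) != len(shape):
        raise ValueError("dims must name one conductance per grid dimension")
    values = np.full(shape, np.nan)
    for idx in np.ndindex(*shape):
        member = ConductanceSet(**{d: grid.levels[k][idx[k]]
                                   for k, d in enumerate(dims)})
        try:
            if thresholds is not None:
                thr = float(thresholds[idx])
            else:
                thr = find_excitation_threshold(member, pacing, solver)
            row = simulate_member_biomarkers(member, isch, pacing, solver,
                                             pacing.stim_multiple * thr)
        except SimulationFailure:
            continue
        if not row["excluded"]:
            values[idx] = row[metric]
    return values
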