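"""Linear acute-ischemia schedule.

Severity is indexed by nominal ischemia "time" in minutes (0-10) purely
as a label: each time point is a quasi-static parameter set, simulated
as its own pacing run, not a continuously time-varying condition. All
ischemic parameters rise linearly from their control value at t = 0 to
their endpoint at t = duration:

==================  =======  ====================================
parameter           t = 0    t = 10 min (default endpoints)
==================  =======  ====================================
f_KATP              0        0.8%
f_inhib             0        25%
f_NaK               0        30%
[K+]o               5.4 mM   12 / 15 / 17 mM (presets K12/K15/K17)
[Na+]i offset       0        +3 mM (model assumption)
==================  =======  ====================================
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .cell_model import IschemiaState

__all__ = ["ScheduleConfig", "schedule_at", "PRESETS", "preset"]


@dataclass(frozen=True)
class ScheduleConfig:
    """Endpoints of the linear ischemia schedule."""

    f_katp_end: float = 0.008
    f_inhib_end: float = 0.25
    f_nak_end: float = 0.30
    k_o_start: float = 5.4
    k_o_end: float = 12.0
    na_i_offset_end: float = 3.0   # mM; magnitude is a model assumption
    duration: float = 10.0         # min

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.k_o_end < self.k_o_start:
            raise ValueError("k_o_end must be >= k_o_start")
        for name in ("f_katp_end", "f_inhib_end", "f_nak_end", "na_i_offset_end"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScheduleConfig":
        return cls(**d)


#: the three hyperkalemia severity presets ([K+]o endpoint in mM)
PRESETS = {
    "K12": ScheduleConfig(k_o_end=12.0),
    "K15": ScheduleConfig(k_o_end=15.0),
    "K17": ScheduleConfig(k_o_end=17.0),
}


def preset(name: str) -> ScheduleConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None


def schedule_at(t: float, cfg: ScheduleConfig = ScheduleConfig()) -> IschemiaState:
    """Ischemic parameter vector at nominal time ``t`` minutes.

    Every field is linearly interpolated between its control value at
    t = 0 and its endpoint at t = duration.
    """
    if not 0.0 <= t <= cfg.duration:
        raise ValueError(f"t={t} outside [0, {cfg.duration}] min")
    x = t / cfg.duration
    return IschemiaState(
        f_katp=x * cfg.f_katp_end,
        f_inhib=x * cfg.f_inhib_end,
        f_nak=x * cfg.f_nak_end,
        k_o=cfg.k_o_start + x * (cfg.k_o_end - cfg.k_o_start),
        na_i_offset=x * cfg.na_i_offset_end,
    )
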