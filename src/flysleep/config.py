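"""YAML experiment configuration.

A small declarative description of a recording: the light regime, which
day of the regime to analyze (day 3 by default, i.e. the third day after
entering the regime), scoring thresholds, and an optional startle-stimulus
schedule given in ZT hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time
from pathlib import Path

import yaml

from .core import LightRegime

__all__ = ["ExperimentConfig", "load_config", "save_config"]

DEFAULT_ANALYSIS_DAY = 3


@dataclass(frozen=True)
class ExperimentConfig:
    regime: LightRegime
    analysis_day: int = DEFAULT_ANALYSIS_DAY
    min_bout_min: int = 5
    dart_distance_threshold_mm: float = 3.0
    dead_fly_quiescence_hours: float = 24.0
    response_window_s: int = 60
    stimulus_zt_hours: tuple[float, ...] = field(default_factory=tuple)


def _parse_clock(s: str) -> time:
    h, m = s.split(":")
    return time(int(h), int(m))


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    r = raw["regime"]
    mode = r["mode"]
    if mode == "LD":
        regime = LightRegime(
            mode="LD",
            lights_on_clock=_parse_clock(r["lights_on"]),
            light_hours=float(r["light_hours"]),
        )
    else:
        regime = LightRegime(
            mode=mode,
            entrainment_anchor=_parse_clock(r.get("entrainment_anchor", r.get("lights_on"))),
            entrainment_light_hours=float(r.get("entrainment_light_hours", 12.0)),
        )
    return ExperimentConfig(
        regime=regime,
        analysis_day=int(raw.get("analysis_day", DEFAULT_ANALYSIS_DAY)),
        min_bout_min=int(raw.get("min_bout_min", 5)),
        dart_distance_threshold_mm=float(raw.get("dart_distance_threshold_mm", 3.0)),
        dead_fly_quiescence_hours=float(raw.get("dead_fly_quiescence_hours", 24.0)),
        response_window_s=int(raw.get("response_window_s", 60)),
        stimulus_zt_hours=tuple(raw.get("stimulus_zt_hours", [])),
    )


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    regime: dict = {"mode": cfg.regime.mode}
    if cfg.regime.mode == "LD":
        regime["lights_on"] = cfg.regime.lights_on_clock.strftime("%H:%M")
        regime["light_hours"] = cfg.regime.light_hours
    else:
        regime["entrainment_anchor"] = cfg.regime.entrainment_anchor.strftime("%H:%M")
        regime["entrainment_light_hours"] = cfg.regime.entrainment_light_hours
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "regime": regime,
                "analysis_day": cfg.analysis_day,
                "min_bout_min": cfg.min_bout_min,
                "dart_distance_threshold_mm": cfg.dart_distance_threshold_mm,
                "dead_fly_quiescence_hours": cfg.dead_fly_quiescence_hours,
                "response_window_s": cfg.response_window_s,
                "stimulus_zt_hours": list(cfg.stimulus_zt_hours),
            },
            fh,
            sort_keys=True,
        )
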