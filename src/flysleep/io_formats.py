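"""Readers/writers for the two acquisition formats plus phase annotation.

Supported dialects:

* **TriKinetics DAM monitor files** — tab-separated text, one row per
  sampling bin: record index, date (``d Mon yy``), time (``HH:MM:SS``), a
  status code (1 = valid reading), six auxiliary fields, then 32 per-channel
  beam-cross counts.
* **DART-style velocity tables** — CSV with an ISO timestamp column followed
  by one column per fly holding the distance moved (mm) in that interval.

Also provides activity re-binning, ZT/phase annotation against a
:class:`~flysleep.core.LightRegime`, and dead-fly exclusion.
"""

from __future__ import annotations

import logging
import warnings
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DAY,
    NIGHT,
    ActivityTrace,
    LightRegime,
    PhaseAnnotation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_dam_monitor",
    "write_dam_monitor",
    "read_dart_velocity",
    "write_dart_velocity",
    "rebin_activity",
    "annotate_phase",
    "flag_dead_flies",
    "DamFormatError",
]

DAM_CHANNELS = 32
DAM_STATUS_OK = 1
#: isolated dropouts up to this many bins are zero-filled; larger gaps abort
MAX_FILL_GAP_BINS = 5


class DamFormatError(ValueError):
    """Raised for malformed or non-uniform monitor files."""


def _parse_dam_row(line: str, lineno: int) -> tuple[int, datetime, int, np.ndarray]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4 + DAM_CHANNELS:
        raise DamFormatError(
            f"line {lineno}: expected >= {4 + DAM_CHANNELS} tab-separated fields, got {len(fields)}"
        )
    try:
        index = int(fields[0])
        stamp = datetime.strptime(f"{fields[1]} {fields[2]}", "%d %b %y %H:%M:%S")
        status = int(fields[3])
        counts = np.array([int(x) for x in fields[-DAM_CHANNELS:]], dtype=float)
    except (ValueError, IndexError) as exc:
        raise DamFormatError(f"line {lineno}: malformed monitor row ({exc})") from exc
    if np.any(counts < 0):
        raise DamFormatError(f"line {lineno}: negative beam-cross count")
    return index, stamp, status, counts


def read_dam_monitor(
    path: str | Path,
    channel_map: Mapping[int, str] | Sequence[str] | None = None,
) -> list[ActivityTrace]:
    """Read a TriKinetics monitor file into one trace per channel.

    Rows whose status code is not 1 are excluded.  Isolated dropped bins
    (gaps of at most :data:`MAX_FILL_GAP_BINS`) are zero-filled and logged;
    larger gaps raise :class:`DamFormatError`.

    ``channel_map`` optionally assigns fly ids per 1-based channel number
    (mapping or 32-element sequence); default ids are ``<stem>:c01`` ...
    ``<stem>:c32``.
    """
    path = Path(path)
    rows: list[tuple[datetime, np.ndarray]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            _, stamp, status, counts = _parse_dam_row(line, lineno)
            if status != DAM_STATUS_OK:
                logger.info("%s line %d: status %d row excluded", path.name, lineno, status)
                continue
            rows.append((stamp, counts))
    if not rows:
        raise DamFormatError(f"{path}: no valid rows")
    rows.sort(key=lambda r: r[0])
    stamps = [r[0] for r in rows]
    if len(rows) == 1:
        bin_seconds = 60
    else:
        deltas = np.array(
            [(b - a).total_seconds() for a, b in zip(stamps[:-1], stamps[1:])]
        )
        positive = deltas[deltas > 0]
        if positive.size == 0:
            raise DamFormatError(f"{path}: duplicate timestamps throughout")
        # modal spacing: robust to dropped rows anywhere in the file
        vals, counts = np.unique(positive, return_counts=True)
        bin_seconds = int(vals[np.argmax(counts)])
    # gap repair: zero-fill isolated dropouts, abort on long gaps
    grid: list[np.ndarray] = [rows[0][1]]
    for (t_prev, _), (t_cur, counts) in zip(rows[:-1], rows[1:]):
        step = (t_cur - t_prev).total_seconds()
        if step == 0 or step % bin_seconds != 0:
            raise DamFormatError(
                f"{path}: non-uniform sampling ({step:.0f} s step vs {bin_seconds} s bins)"
            )
        missing = int(step // bin_seconds) - 1
        if missing > MAX_FILL_GAP_BINS:
            raise DamFormatError(
                f"{path}: gap of {missing} bins at {t_cur} exceeds fill limit"
            )
        if missing:
            logger.warning(
                "%s: zero-filling %d dropped bin(s) before %s", path.name, missing, t_cur
            )
            grid.extend([np.zeros(DAM_CHANNELS)] * missing)
        grid.append(counts)
    matrix = np.vstack(grid)

    def _fly_id(channel: int) -> str:
        if channel_map is None:
            return f"{path.stem}:c{channel:02d}"
        if isinstance(channel_map, Mapping):
            return str(channel_map.get(channel, f"{path.stem}:c{channel:02d}"))
        return str(channel_map[channel - 1])

    return [
        ActivityTrace(
            fly_id=_fly_id(ch + 1),
            modality="DAM",
            start_time=stamps[0],
            bin_seconds=bin_seconds,
            values=matrix[:, ch],
        )
        for ch in range(DAM_CHANNELS)
    ]


def write_dam_monitor(traces: Sequence[ActivityTrace], path: str | Path) -> None:
    """Write up to 32 aligned DAM traces as a TriKinetics monitor file.

    Unused channels are padded with zero counts.
    """
    if not traces:
        raise ValueError("no traces to write")
    if len(traces) > DAM_CHANNELS:
        raise ValueError(f"at most {DAM_CHANNELS} channels per monitor")
    first = traces[0]
    for t in traces:
        if t.modality != "DAM":
            raise ValueError("write_dam_monitor accepts DAM traces only")
        if (t.start_time, t.bin_seconds, t.n_bins) != (
            first.start_time,
            first.bin_seconds,
            first.n_bins,
        ):
            raise ValueError("traces must share start time, bin width and length")
    matrix = np.zeros((first.n_bins, DAM_CHANNELS), dtype=int)
    for ch, t in enumerate(traces):
        matrix[:, ch] = np.round(t.values).astype(int)
    with open(path, "w") as fh:
        for i in range(first.n_bins):
            stamp = first.bin_start(i)
            fields = [
                str(i + 1),
                stamp.strftime("%d %b %y").lstrip("0"),
                stamp.strftime("%H:%M:%S"),
                str(DAM_STATUS_OK),
                *["0"] * 6,
                *(str(c) for c in matrix[i]),
            ]
            fh.write("\t".join(fields) + "\n")


def read_dart_velocity(path: str | Path) -> list[ActivityTrace]:
    """Read a DART-style wide CSV (timestamp + one distance column per fly)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a timestamp column plus at least one fly column")
    stamps = pd.to_datetime(df.iloc[:, 0])
    if len(stamps) < 2:
        raise ValueError(f"{path}: need at least two rows to infer the sampling interval")
    deltas = stamps.diff().dropna().dt.total_seconds().to_numpy()
    if np.any(deltas <= 0):
        raise ValueError(f"{path}: timestamps must be strictly increasing")
    bin_seconds = deltas[0]
    if not np.all(deltas == bin_seconds):
        raise ValueError(f"{path}: non-uniform sampling interval")
    if bin_seconds != int(bin_seconds):
        raise ValueError(f"{path}: sampling interval must be a whole number of seconds")
    traces = []
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().all():
            warnings.warn(f"{path}: column {col!r} is empty, trace excluded", stacklevel=2)
            continue
        if vals.isna().any():
            raise ValueError(f"{path}: column {col!r} has missing cells")
        if (vals < 0).any():
            raise ValueError(f"{path}: column {col!r} has negative distances")
        traces.append(
            ActivityTrace(
                fly_id=str(col),
                modality="DART",
                start_time=stamps.iloc[0].to_pydatetime(),
                bin_seconds=int(bin_seconds),
                values=vals.to_numpy(dtype=float),
            )
        )
    return traces


def write_dart_velocity(traces: Sequence[ActivityTrace], path: str | Path) -> None:
    """Write aligned DART traces as a wide CSV, one column per fly."""
    if not traces:
        raise ValueError("no traces to write")
    first = traces[0]
    for t in traces:
        if t.modality != "DART":
            raise ValueError("write_dart_velocity accepts DART traces only")
        if (t.start_time, t.bin_seconds, t.n_bins) != (
            first.start_time,
            first.bin_seconds,
            first.n_bins,
        ):
            raise ValueError("traces must share start time, bin width and length")
    stamps = [first.bin_start(i).isoformat(sep=" ") for i in range(first.n_bins)]
    df = pd.DataFrame({"time": stamps})
    for t in traces:
        df[t.fly_id] = t.values
    df.to_csv(path, index=False)


def rebin_activity(trace: ActivityTrace, target_bin_seconds: int) -> ActivityTrace:
    """Aggregate a trace onto a coarser grid by summing within target bins.

    Total activity is conserved exactly; trailing bins that do not fill a
    whole target bin are dropped.
    """
    if target_bin_seconds % trace.bin_seconds != 0:
        raise ValueError(
            f"target bin {target_bin_seconds}s is not a multiple of {trace.bin_seconds}s"
        )
    factor = target_bin_seconds // trace.bin_seconds
    if factor == 1:
        return trace
    n_full = trace.n_bins // factor
    if n_full == 0:
        raise ValueError("trace shorter than one target bin")
    summed = trace.values[: n_full * factor].reshape(n_full, factor).sum(axis=1)
    return trace.with_values(summed, bin_seconds=target_bin_seconds)


def _anchor_before(t: datetime, anchor) -> datetime:
    """Most recent occurrence of clock time ``anchor`` at or before ``t``."""
    candidate = t.replace(
        hour=anchor.hour, minute=anchor.minute, second=anchor.second, microsecond=0
    )
    if candidate > t:
        candidate -= timedelta(days=1)
    return candidate


def annotate_phase(trace: ActivityTrace, regime: LightRegime) -> PhaseAnnotation:
    """Per-bin ZT (or CT under DD/LL), day/night phase and 1-based day index.

    Bins are labeled by their start time, half-open convention: day is
    ``[ZT0, ZT day_hours)``.  Day 1 is the (possibly partial) ZT-day that
    contains the first bin.
    """
    zt0 = _anchor_before(trace.start_time, regime.anchor)
    offset_h = (trace.start_time - zt0).total_seconds() / 3600.0
    bin_h = trace.bin_seconds / 3600.0
    elapsed = offset_h + np.arange(trace.n_bins) * bin_h
    zt = np.mod(elapsed, 24.0)
    day_index = (elapsed // 24.0).astype(int) + 1
    phase = np.where(zt < regime.day_hours, DAY, NIGHT)
    return PhaseAnnotation(
        zt_hours=zt,
        phase=phase,
        analysis_day_index=day_index,
        bin_seconds=trace.bin_seconds,
    )


def flag_dead_flies(
    traces: Iterable[ActivityTrace], terminal_quiescence_hours: float = 24.0
) -> dict[str, bool]:
    """Flag flies immobile from some point through the end of the recording.

    A fly is dead iff its activity is zero over the final
    ``terminal_quiescence_hours`` (or longer).  Dead flies are dropped from
    all downstream stages by the pipeline drivers.
    """
    flags: dict[str, bool] = {}
    for t in traces:
        nz = np.nonzero(t.values)[0]
        tail_bins = t.n_bins if nz.size == 0 else t.n_bins - (int(nz[-1]) + 1)
        tail_hours = tail_bins * t.bin_seconds / 3600.0
        flags[t.fly_id] = tail_hours >= terminal_quiescence_hours
    return flags
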