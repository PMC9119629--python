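"""Trace, spike-train and event-record file formats.

Time series are CSV with a ``time_ms,<value>`` header on a strictly
uniform grid; spike trains are plain text, one millisecond value per
line; sampled events are CSV ``time_ms,mechanism,component,spike_index``.
All times are serialized at full precision (repr round-trip).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from presyn.calcium import CalciumTrace
from presyn.profile import SpikeTrain
from presyn.sampler import EventRecord

__all__ = [
    "read_trace",
    "write_trace",
    "read_spike_train",
    "write_spike_train",
    "write_events",
    "read_events",
]

#: relative tolerance on grid uniformity when parsing time columns
_GRID_RTOL = 1e-9


def write_trace(path: str | Path, trace: CalciumTrace, value_name: str = "ca_uM") -> None:
    """Write a trace as ``time_ms,<value_name>`` CSV at full precision."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ms", value_name])
        for t, v in zip(trace.times, trace.values):
            w.writerow([repr(float(t)), repr(float(v))])


def read_trace(path: str | Path, value_name: str = "ca_uM", baseline: float | None = None) -> CalciumTrace:
    """Read a ``time_ms,<value_name>`` CSV back into a trace.

    Raises a descriptive error (naming the offending row) on a missing
    header, non-numeric cells, or a non-uniform time grid.
    """
    path = Path(path)
    with open(path) as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][:1] != ["time_ms"]:
        raise ValueError(f"{path}: missing 'time_ms,...' header")
    header = rows[0]
    if value_name not in header:
        raise ValueError(f"{path}: no column named {value_name!r} in header {header}")
    vcol = header.index(value_name)
    times, values = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        try:
            times.append(float(row[0]))
            values.append(float(row[vcol]))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric or short row {row!r}") from exc
    times = np.asarray(times)
    values = np.asarray(values)
    if times.size == 0:
        raise ValueError(f"{path}: no data rows")
    if times.size > 1:
        steps = np.diff(times)
        dt = steps[0]
        if dt <= 0:
            raise ValueError(f"{path}: line 3: time grid not strictly increasing")
        bad = np.flatnonzero(np.abs(steps - dt) > _GRID_RTOL * max(abs(dt), 1.0))
        if bad.size:
            raise ValueError(
                f"{path}: line {bad[0] + 3}: non-uniform time grid "
                f"(step {steps[bad[0]]!r} != {dt!r})"
            )
    else:
        dt = 1.0  # degenerate 1-row trace: constant
    if baseline is None:
        baseline = float(values.min())
    return CalciumTrace(t0=float(times[0]), dt=float(dt), values=values, baseline=baseline)


def write_spike_train(path: str | Path, train: SpikeTrain) -> None:
    Path(path).write_text("".join(f"{repr(float(t))}\n" for t in train.times))


def read_spike_train(path: str | Path) -> SpikeTrain:
    path = Path(path)
    times = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            times.append(float(line))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric spike time {line!r}") from exc
    return SpikeTrain(np.asarray(times))


def write_events(path: str | Path, events: list[EventRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ms", "mechanism", "component", "spike_index"])
        for ev in events:
            w.writerow([repr(ev.time), ev.mechanism, ev.component, ev.spike_index])


def read_events(path: str | Path) -> list[EventRecord]:
    df = pd.read_csv(path)
    return [
        EventRecord(
            time=float(r.time_ms),
            mechanism=str(r.mechanism),
            component=int(r.component),
            spike_index=int(r.spike_index),
        )
        for r in df.itertuples()
    ]
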