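"""Collation of heterogeneous time series per experiment entity.

Imaging-derived traces rarely live alone: locomotion, whisking, or categorical
behavioral state come from other devices with their own clocks and sampling
rates.  This module registers such series under a common entity (experiment or
trial id), resamples them onto a shared time grid — linear interpolation for
numeric series, zero-order hold for categorical ones — and slices windows
around categorical state transitions (e.g. quiet wakefulness → running).

Missing data (outside a series' support) are marked with NaN/None sentinels,
never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class CollisionError(KeyError):
    """(entity, name) pair already registered."""


class AlignmentError(ValueError):
    """Target grid does not intersect the overlap of the series."""


@dataclass
class SeriesEntry:
    """One registered time series: numeric values or categorical labels.

    ``time_offset`` (seconds) corrects clock differences between acquisition
    devices; retrieved times are times + offset.  ``values`` may be a
    callable for lazy sources; it is invoked on first access.
    """

    entity_id: str
    name: str
    times: np.ndarray
    values: object
    time_offset: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.entity_id}/{self.name}: times must be "
                             "strictly increasing")

    def _materialized(self) -> np.ndarray:
        if callable(self.values):
            self.values = self.values()
        vals = np.asarray(self.values)
        if len(vals) != len(self.times):
            raise ValueError(f"{self.entity_id}/{self.name}: "
                             f"{len(vals)} values for {len(self.times)} times")
        return vals

    @property
    def categorical(self) -> bool:
        return self._materialized().dtype.kind in "USO"

    @property
    def corrected_times(self) -> np.ndarray:
        return self.times + self.time_offset

    def data(self) -> tuple[np.ndarray, np.ndarray]:
        return self.corrected_times, self._materialized()


class MultiTable:
    """Registry of time series grouped by experiment entity."""

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], SeriesEntry] = {}

    def add(self, entry: SeriesEntry) -> "MultiTable":
        key = (entry.entity_id, entry.name)
        if key in self._entries:
            raise CollisionError(f"series {key} already registered")
        self._entries[key] = entry
        return self

    def get(self, entity_id: str, name: str) -> SeriesEntry:
        return self._entries[(entity_id, name)]

    def names(self, entity_id: str) -> list[str]:
        return [n for (e, n) in self._entries if e == entity_id]

    def entries(self, entity_id: str | None = None) -> list[SeriesEntry]:
        return [v for (e, _), v in self._entries.items()
                if entity_id is None or e == entity_id]


def add_series(table: MultiTable, entry: SeriesEntry) -> MultiTable:
    """Register ``entry``; duplicate (entity, name) raises CollisionError."""
    return table.add(entry)


def _resample_one(entry: SeriesEntry, target: np.ndarray) -> np.ndarray:
    times, values = entry.data()
    inside = (target >= times[0]) & (target <= times[-1])
    if entry.categorical:
        out = np.full(len(target), None, dtype=object)
        idx = np.searchsorted(times, target[inside], side="right") - 1
        out[inside] = values[idx]  # nearest-previous / zero-order hold
    else:
        out = np.full(len(target), np.nan)
        out[inside] = np.interp(target[inside], times,
                                np.asarray(values, dtype=float))
    return out


def resample_align(entries: Sequence[SeriesEntry],
                   target_times: np.ndarray) -> pd.DataFrame:
    """Resample every series onto ``target_times``.

    Numeric series are linearly interpolated, categorical ones carried
    forward from the nearest previous sample; grid points outside a series'
    support get a missing marker (NaN/None).  Raises AlignmentError if no
    grid point falls inside the common overlap of all series.
    """
    if not entries:
        raise ValueError("need at least one series")
    target = np.asarray(target_times, dtype=float)
    lo = max(e.corrected_times[0] for e in entries)
    hi = min(e.corrected_times[-1] for e in entries)
    if lo > hi or not np.any((target >= lo) & (target <= hi)):
        raise AlignmentError("target grid misses the overlap of the series")
    data = {"time_s": target}
    for e in entries:
        col = f"{e.entity_id}/{e.name}" if len(
            {x.entity_id for x in entries}) > 1 else e.name
        data[col] = _resample_one(e, target)
    return pd.DataFrame(data)


def find_transitions(cat: SeriesEntry, from_state, to_state) -> np.ndarray:
    """Timestamps of each from→to boundary, defined as the time of the first
    sample in the new state."""
    times, values = cat.data()
    if not cat.categorical:
        raise ValueError("transition slicing needs a categorical series")
    hits = (values[:-1] == from_state) & (values[1:] == to_state)
    return times[1:][hits]


@dataclass
class TransitionSlice:
    """Window of target data around one state transition."""

    transition_time: float
    rel_times: np.ndarray
    data: pd.DataFrame     # columns: one per target series, on rel_times
    truncated: bool


def slice_on_transition(cat: SeriesEntry, from_state, to_state,
                        window: tuple[float, float],
                        targets: Sequence[SeriesEntry],
                        dt: float | None = None) -> list[TransitionSlice]:
    """One slice per from→to transition, with each target resampled onto the
    common window-relative grid [−pre, +post).

    ``dt`` defaults to the finest median sampling interval of the targets.
    Slices whose window extends beyond a target's coverage are flagged
    ``truncated`` (missing points carry the NaN/None sentinel).
    """
    pre_s, post_s = window
    if dt is None:
        dt = min(float(np.median(np.diff(t.corrected_times))) for t in targets)
    rel = np.arange(-pre_s, post_s - 1e-12, dt)
    slices = []
    for t0 in find_transitions(cat, from_state, to_state):
        grid = t0 + rel
        cols = {}
        truncated = False
        for tgt in targets:
            col = _resample_one(tgt, grid)
            if tgt.categorical:
                truncated |= any(v is None for v in col)
            else:
                truncated |= bool(np.isnan(col).any())
            cols[tgt.name] = col
        slices.append(TransitionSlice(
            transition_time=float(t0), rel_times=rel,
            data=pd.DataFrame({"rel_time_s": rel, **cols}),
            truncated=truncated))
    return slices


def to_long_frame(aligned: pd.DataFrame, entity_id: str) -> pd.DataFrame:
    """Long-format export (entity, name, time, value) of an aligned table."""
    long = aligned.melt(id_vars="time_s", var_name="name", value_name="value")
    long.insert(0, "entity", entity_id)
    return long[["entity", "name", "time_s", "value"]]
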