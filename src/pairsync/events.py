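"""Behavioral event tables, framewise state encoding and bout segmentation.

The raw observational unit is an event table: per-individual onsets and
offsets (seconds) of three mutually exclusive behaviors -- ``vigilance``,
``feeding`` and ``out_of_sight`` -- within a recording session. Events are
half-open intervals [onset, offset): a video frame belongs to an event iff
its timestamp falls inside that interval, which avoids double assignment at
shared boundaries.

Encoding maps each frame to a numeric state: vigilance -> 1.0,
feeding -> 0.0, anything else -> 0.5. The 0.5 code covers two distinct
situations: a coded out-of-sight event (a transition *within* an ongoing
bout) and the absence of any event (a break in engagement). The two must be
distinguished for bout segmentation, so :class:`StateSeries` carries an
``engaged`` mask marking frames covered by *any* coded event.

A joint bout is a maximal stretch in which both individuals are engaged,
where interruptions shorter than a cutoff (default 10 s) are bridged and
interruptions of at least the cutoff split bouts (an exactly-10.0 s break
splits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BEHAVIORS = ("vigilance", "feeding", "out_of_sight")
STATE_CODE = {"vigilance": 1.0, "feeding": 0.0, "out_of_sight": 0.5}

EVENT_COLUMNS = [
    "individual_id",
    "behavior",
    "onset_s",
    "offset_s",
    "session_id",
    "location",
    "bowls",
    "condition",
]


class EventTableError(ValueError):
    """Raised when an event table violates its invariants."""


@dataclass
class StateSeries:
    """Framewise behavioral state of one individual at a fixed rate.

    Parameters
    ----------
    individual_id : str
    rate_hz : float
        Frames per second (25 for the video material this emulates).
    values : ndarray of float
        One value per frame, each in {0.0, 0.5, 1.0}.
    t0_s : float
        Session-clock time of frame 0.
    engaged : ndarray of bool, optional
        True where any coded event covers the frame. When absent,
        engagement is inferred as ``values != 0.5``.
    """

    individual_id: str
    rate_hz: float
    values: np.ndarray
    t0_s: float = 0.0
    engaged: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("StateSeries needs a nonempty 1-D value array")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        bad = ~np.isin(self.values, (0.0, 0.5, 1.0))
        if bad.any():
            raise ValueError("state values must be in {0, 0.5, 1}")
        if self.engaged is not None:
            self.engaged = np.asarray(self.engaged, dtype=bool)
            if self.engaged.shape != self.values.shape:
                raise ValueError("engaged mask must match values in length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.rate_hz

    def engagement(self) -> np.ndarray:
        if self.engaged is not None:
            return self.engaged
        return self.values != 0.5

    def slice(self, start: int, stop: int) -> "StateSeries":
        return StateSeries(
            individual_id=self.individual_id,
            rate_hz=self.rate_hz,
            values=self.values[start:stop],
            t0_s=self.t0_s + start / self.rate_hz,
            engaged=None if self.engaged is None else self.engaged[start:stop],
        )

    def segments(self) -> list[tuple[float, float, float]]:
        """Run-length encode as (start_s, end_s, value) triples."""
        v = self.values
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [v.size]))
        return [
            (self.t0_s + s / self.rate_hz, self.t0_s + e / self.rate_hz, float(v[s]))
            for s, e in zip(starts, ends)
        ]


@dataclass
class BoutPair:
    """Two time-aligned state series for one pair, with condition metadata."""

    bout_id: str
    series_a: StateSeries
    series_b: StateSeries
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.series_a) != len(self.series_b):
            raise ValueError("paired series must have equal length")
        if self.series_a.rate_hz != self.series_b.rate_hz:
            raise ValueError("paired series must share the frame rate")

    @property
    def rate_hz(self) -> float:
        return self.series_a.rate_hz

    @property
    def n_frames(self) -> int:
        return len(self.series_a)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate_hz


def read_events(path_or_buffer, sep: str = ",") -> pd.DataFrame:
    """Read and validate a behavioral event table (CSV/TSV)."""
    df = pd.read_csv(path_or_buffer, sep=sep)
    return validate_events(df)


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c in
               ("individual_id", "behavior", "onset_s", "offset_s")]
    if missing:
        raise EventTableError(f"event table lacks required columns: {missing}")
    bad_behavior = set(df["behavior"].unique()) - set(BEHAVIORS)
    if bad_behavior:
        raise EventTableError(f"unknown behavior labels: {sorted(bad_behavior)}")
    if (df["offset_s"] <= df["onset_s"]).any():
        raise EventTableError("every event must satisfy offset_s > onset_s")
    group_cols = ["individual_id"]
    if "session_id" in df.columns:
        group_cols.append("session_id")
    for key, g in df.groupby(group_cols):
        g = g.sort_values("onset_s")
        overlap = g["onset_s"].to_numpy()[1:] < g["offset_s"].to_numpy()[:-1]
        if overlap.any():
            raise EventTableError(f"overlapping events for {key}")
    return df


def encode_states(
    events: pd.DataFrame,
    individual_id: str,
    rate_hz: float = 25.0,
    span: tuple[float, float] | None = None,
    session_id: str | None = None,
) -> StateSeries:
    """Encode one individual's events as a framewise state series.

    Frame f sits at time ``span[0] + f/rate_hz`` and is assigned 1.0 if it
    falls inside a vigilance event, 0.0 inside a feeding event and 0.5
    otherwise (out-of-sight events and uncoded gaps both yield 0.5, but only
    the former count as engaged).
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    ev = events[events["individual_id"] == individual_id]
    if session_id is not None:
        ev = ev[ev["session_id"] == session_id]
    ev = ev.sort_values("onset_s")
    _check_no_overlap(ev)
    if span is None:
        if ev.empty:
            raise EventTableError("no events and no span given")
        span = (float(ev["onset_s"].min()), float(ev["offset_s"].max()))
    start_s, end_s = float(span[0]), float(span[1])
    n = int(round((end_s - start_s) * rate_hz))
    if n < 1:
        raise EventTableError("empty span")
    values = np.full(n, 0.5)
    engaged = np.zeros(n, dtype=bool)
    for onset, offset, behavior in ev[["onset_s", "offset_s", "behavior"]].itertuples(index=False):
        # frame f covered iff onset <= start + f/rate < offset (half-open)
        f0 = int(np.ceil((onset - start_s) * rate_hz - 1e-9))
        f1 = int(np.ceil((offset - start_s) * rate_hz - 1e-9))
        f0, f1 = max(f0, 0), min(f1, n)
        if f1 <= f0:
            continue
        values[f0:f1] = STATE_CODE[behavior]
        engaged[f0:f1] = True
    return StateSeries(individual_id=individual_id, rate_hz=rate_hz,
                       values=values, t0_s=start_s, engaged=engaged)


def _check_no_overlap(ev: pd.DataFrame) -> None:
    if len(ev) < 2:
        return
    onsets = ev["onset_s"].to_numpy()
    offsets = ev["offset_s"].to_numpy()
    if (onsets[1:] < offsets[:-1] - 1e-12).any():
        raise EventTableError("overlapping vigilance/feeding events for one individual")


def extract_bouts(
    series_a: StateSeries,
    series_b: StateSeries,
    gap_threshold_s: float = 10.0,
    pair_id: str | None = None,
    metadata: Mapping | None = None,
) -> list[BoutPair]:
    """Segment two aligned series into joint bouts of mutual engagement.

    Interruptions (frames where either individual has no coded event)
    shorter than ``gap_threshold_s`` are bridged; interruptions of at least
    the threshold split bouts. Returned bouts are aligned slices of both
    series spanning first-to-last jointly engaged frame of each run.
    """
    if len(series_a) != len(series_b):
        raise ValueError("mismatched series lengths")
    if series_a.rate_hz != series_b.rate_hz:
        raise ValueError("mismatched frame rates")
    rate = series_a.rate_hz
    joint = series_a.engagement() & series_b.engagement()
    runs = _true_runs(joint)
    if not runs:
        return []
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        gap_s = (start - merged[-1][1]) / rate
        if gap_s < gap_threshold_s:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    pair_id = pair_id or f"{series_a.individual_id}-{series_b.individual_id}"
    meta = dict(metadata or {})
    meta.setdefault("pair_id", pair_id)
    bouts = []
    for i, (start, stop) in enumerate(merged):
        m = dict(meta)
        m["start_s"] = series_a.t0_s + start / rate
        bouts.append(BoutPair(
            bout_id=f"{pair_id}_b{i:03d}",
            series_a=series_a.slice(start, stop),
            series_b=series_b.slice(start, stop),
            metadata=m,
        ))
    return bouts


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean array."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def filter_bouts(
    bouts: Sequence[BoutPair],
    oscillation_counts: Mapping[str, tuple[float, float]] | Sequence[tuple[float, float]],
    min_duration_s: float = 10.0,
    min_oscillations: float = 2.0,
) -> tuple[list[BoutPair], list[dict]]:
    """Apply the bout-inclusion criteria.

    A bout is retained iff its duration is at least ``min_duration_s`` and
    at least one individual completed at least ``min_oscillations`` full
    cycles. Returns (retained bouts, discard log); the log holds one record
    per discarded bout with the reason.
    """
    if not isinstance(oscillation_counts, Mapping):
        oscillation_counts = {b.bout_id: c for b, c in zip(bouts, oscillation_counts)}
    kept: list[BoutPair] = []
    log: list[dict] = []
    for bout in bouts:
        reasons = []
        if bout.duration_s < min_duration_s:
            reasons.append(f"duration {bout.duration_s:.2f}s < {min_duration_s:g}s")
        ca, cb = oscillation_counts.get(bout.bout_id, (np.nan, np.nan))
        if not (ca >= min_oscillations or cb >= min_oscillations):
            reasons.append(
                f"both individuals < {min_oscillations:g} oscillations ({ca:.2f}, {cb:.2f})")
        if reasons:
            log.append({"bout_id": bout.bout_id, "duration_s": bout.duration_s,
                        "reason": "; ".join(reasons)})
        else:
            kept.append(bout)
    return kept, log


def bout_manifest(bouts: Iterable[BoutPair]) -> pd.DataFrame:
    """Tabulate bouts (one row each) for writing alongside state series."""
    rows = []
    for b in bouts:
        row = {"bout_id": b.bout_id, "start_s": b.series_a.t0_s,
               "duration_s": b.duration_s, "rate_hz": b.rate_hz,
               "individual_a": b.series_a.individual_id,
               "individual_b": b.series_b.individual_id}
        row.update(b.metadata)
        rows.append(row)
    return pd.DataFrame(rows)


def write_bout_series(bout: BoutPair, path) -> None:
    """Write one bout's paired state series as a two-column CSV."""
    pd.DataFrame({
        "t_s": bout.series_a.times_s,
        bout.series_a.individual_id: bout.series_a.values,
        bout.series_b.individual_id: bout.series_b.values,
    }).to_csv(path, index=False)
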