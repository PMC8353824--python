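"""Accelerometer count-stream processing.

Converts per-minute activity counts (hip-worn uniaxial counts per minute) into
daily and person-level behavior minutes:

* non-wear detection: a period of >= 90 consecutive minutes of zero counts is
  non-wear, tolerating up to 2 interruption minutes with counts 1-99 provided
  each interruption is flanked on both sides by >= 30 consecutive zero-count
  minutes (a flank truncated by the start or end of the recording counts);
* intensity classification by vertical-axis cut points:
  SB <= 100 cpm, LLPA 101-760, HLPA 761-1951, MVPA >= 1952;
* valid-wear screening: days with < 10 h of wear are dropped and subjects with
  fewer than 4 remaining days are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import PARTS

__all__ = [
    "MinuteSeries",
    "DailySummary",
    "SubjectExposure",
    "detect_nonwear",
    "classify_minute",
    "summarize_day",
    "build_exposures",
    "read_minute_streams",
    "exposures_to_frame",
]

# vertical-axis counts-per-minute cut points (upper bound of each band; MVPA open-ended)
SB_MAX = 100
LLPA_MAX = 760
HLPA_MAX = 1951

NONWEAR_WINDOW = 90
NONWEAR_ALLOWANCE = 2
NONWEAR_FLANK = 30


@dataclass(frozen=True)
class MinuteSeries:
    """One subject-day of per-minute counts."""

    subject_id: Hashable
    day_index: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("counts must be a non-empty 1-d sequence")
        if c.size > 1440:
            raise ValueError("a day holds at most 1440 minutes")
        if np.any(c < 0):
            raise ValueError("negative counts are not valid accelerometer data")


@dataclass(frozen=True)
class DailySummary:
    """Wear and behavior minutes for one subject-day (behaviors partition wear)."""

    subject_id: Hashable
    day_index: int
    wear_minutes: int
    mvpa_min: int
    hlpa_min: int
    llpa_min: int
    sb_min: int

    def __post_init__(self) -> None:
        parts = self.mvpa_min + self.hlpa_min + self.llpa_min + self.sb_min
        if parts != self.wear_minutes:
            raise ValueError(
                f"behavior minutes ({parts}) must sum exactly to wear minutes "
                f"({self.wear_minutes})"
            )
        if min(self.mvpa_min, self.hlpa_min, self.llpa_min, self.sb_min) < 0:
            raise ValueError("behavior minutes must be non-negative")


@dataclass(frozen=True)
class SubjectExposure:
    """Per-subject mean minutes/day over valid wear days."""

    subject_id: Hashable
    n_valid_days: int
    mvpa_min: float
    hlpa_min: float
    llpa_min: float
    sb_min: float
    wear_minutes: float


def detect_nonwear(
    series: MinuteSeries,
    window: int = NONWEAR_WINDOW,
    allowance_max: int = NONWEAR_ALLOWANCE,
    flank: int = NONWEAR_FLANK,
) -> np.ndarray:
    """Boolean per-minute wear mask (True = worn).

    A minute is non-wear iff it lies inside a span of >= ``window`` minutes
    consisting of zero counts, where up to ``allowance_max`` interior minutes
    with counts 1-99 are tolerated when each is flanked by >= ``flank``
    consecutive zero minutes on both sides (a flank cut short by the recording
    boundary counts as satisfied).  Any count >= 100 terminates a span.
    """
    counts = series.counts
    n = counts.size
    wear = np.ones(n, dtype=bool)

    # maximal zero runs as (start, stop) half-open intervals
    zero = counts == 0
    if not zero.any():
        return wear
    edges = np.flatnonzero(np.diff(np.concatenate(([0], zero.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    runs = list(zip(starts.tolist(), stops.tolist()))

    def flank_ok(run_len: int, touches_boundary: bool) -> bool:
        return touches_boundary or run_len >= flank

    # from each zero run, greedily extend rightwards across tolerable gaps
    for a in range(len(runs)):
        s0, e = runs[a]
        gap_budget = allowance_max
        b = a
        while b + 1 < len(runs):
            gap_start, gap_end = runs[b][1], runs[b + 1][0]
            gap = counts[gap_start:gap_end]
            if gap.size > gap_budget or np.any(gap >= 100):
                break
            left_len = runs[b][1] - runs[b][0]
            right_len = runs[b + 1][1] - runs[b + 1][0]
            if not (
                flank_ok(left_len, runs[b][0] == 0)
                and flank_ok(right_len, runs[b + 1][1] == n)
            ):
                break
            gap_budget -= gap.size
            b += 1
            e = runs[b][1]
        if e - s0 >= window:
            wear[s0:e] = False
    return wear


def classify_minute(count: int) -> str:
    """Intensity band of a single counts-per-minute value."""
    if count < 0:
        raise ValueError("counts must be non-negative")
    if count <= SB_MAX:
        return "SB"
    if count <= LLPA_MAX:
        return "LLPA"
    if count <= HLPA_MAX:
        return "HLPA"
    return "MVPA"


def _band_minutes(counts: np.ndarray) -> tuple[int, int, int, int]:
    """(mvpa, hlpa, llpa, sb) minute totals of a count vector."""
    sb = int(np.count_nonzero(counts <= SB_MAX))
    llpa = int(np.count_nonzero((counts > SB_MAX) & (counts <= LLPA_MAX)))
    hlpa = int(np.count_nonzero((counts > LLPA_MAX) & (counts <= HLPA_MAX)))
    mvpa = int(np.count_nonzero(counts > HLPA_MAX))
    return mvpa, hlpa, llpa, sb


def summarize_day(series: MinuteSeries, mask: np.ndarray | None = None) -> DailySummary:
    """Behavior minutes over wear time for one subject-day.

    ``mask`` is the boolean wear mask; if omitted it is computed with
    :func:`detect_nonwear`.
    """
    if mask is None:
        mask = detect_nonwear(series)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.counts.shape:
        raise ValueError("wear mask length does not match the count series")
    worn = series.counts[mask]
    mvpa, hlpa, llpa, sb = _band_minutes(worn)
    return DailySummary(
        subject_id=series.subject_id,
        day_index=series.day_index,
        wear_minutes=int(mask.sum()),
        mvpa_min=mvpa,
        hlpa_min=hlpa,
        llpa_min=llpa,
        sb_min=sb,
    )


def build_exposures(
    days: Iterable[DailySummary],
    min_wear_hours: float = 10.0,
    min_days: int = 4,
) -> tuple[list[SubjectExposure], pd.DataFrame]:
    """Screen days and subjects for valid wear and average the survivors.

    Days with less than ``min_wear_hours`` of wear are dropped first; subjects
    left with fewer than ``min_days`` days are excluded.  Returns the included
    exposures plus an exclusion log (subject_id, n_valid_days, reason).
    """
    min_wear = 60.0 * min_wear_hours
    by_subject: dict[Hashable, list[DailySummary]] = {}
    for d in days:
        by_subject.setdefault(d.subject_id, []).append(d)

    exposures: list[SubjectExposure] = []
    excluded: list[dict] = []
    for sid, ds in by_subject.items():
        valid = [d for d in ds if d.wear_minutes >= min_wear]
        if len(valid) < min_days:
            excluded.append(
                {
                    "subject_id": sid,
                    "n_valid_days": len(valid),
                    "reason": f"fewer than {min_days} days with >= {min_wear:g} wear min",
                }
            )
            continue
        arr = np.array(
            [
                [d.mvpa_min, d.hlpa_min, d.llpa_min, d.sb_min, d.wear_minutes]
                for d in valid
            ],
            dtype=float,
        )
        means = arr.mean(axis=0)
        exposures.append(
            SubjectExposure(
                subject_id=sid,
                n_valid_days=len(valid),
                mvpa_min=means[0],
                hlpa_min=means[1],
                llpa_min=means[2],
                sb_min=means[3],
                wear_minutes=means[4],
            )
        )
    log = pd.DataFrame(excluded, columns=["subject_id", "n_valid_days", "reason"])
    return exposures, log


def exposures_to_frame(exposures: Sequence[SubjectExposure]) -> pd.DataFrame:
    """Tabulate exposures with the canonical behavior column names."""
    return pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in exposures],
            "n_valid_days": [e.n_valid_days for e in exposures],
            "MVPA": [e.mvpa_min for e in exposures],
            "HLPA": [e.hlpa_min for e in exposures],
            "LLPA": [e.llpa_min for e in exposures],
            "SB": [e.sb_min for e in exposures],
            "wear_minutes": [e.wear_minutes for e in exposures],
        }
    )


def read_minute_streams(path) -> list[MinuteSeries]:
    """Read per-minute count streams from delimited text.

    Two layouts are auto-detected from the header:

    * long — columns ``subject_id, day_index, minute_index, count``;
    * wide — columns ``subject_id, day_index, m1, m2, ...`` (one column per
      minute; trailing empty fields mark a shorter recording).
    """
    df = pd.read_csv(path, comment="#")
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if {"subject_id", "day_index"} - set(cols):
        raise ValueError(f"{path}: expected 'subject_id' and 'day_index' columns")
    out: list[MinuteSeries] = []
    if {"minute_index", "count"} <= set(cols):
        for (sid, day), grp in df.groupby(["subject_id", "day_index"], sort=True):
            grp = grp.sort_values("minute_index")
            out.append(
                MinuteSeries(sid, int(day), grp["count"].to_numpy(dtype=np.int64))
            )
    else:
        minute_cols = [c for c in cols if c not in ("subject_id", "day_index")]
        for _, row in df.iterrows():
            counts = row[minute_cols].dropna().to_numpy(dtype=np.int64)
            out.append(MinuteSeries(row["subject_id"], int(row["day_index"]), counts))
    return out
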