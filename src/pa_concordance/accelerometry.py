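"""Accelerometer epoch processing.

Turns MET (metabolic equivalent of task) time series into weekly minutes of
moderate (MPA) and vigorous (VPA) physical activity:

1. re-aggregate the base-resolution series to an analysis epoch length
   (commonly 10 s or 60 s) by averaging constituent epochs;
2. classify each wear epoch against MET cut points
   (MPA 3.0-5.9 MET, VPA >= 6 MET);
3. summarize calendar days (a day is valid at >= 8 h wear);
4. extrapolate a week as 7 x the mean over valid days, requiring at least
   4 valid days, otherwise the week is missing.

Epochs are anchored at local midnight: epoch k of a day covers
[k*e, (k+1)*e) seconds, half-open, so results are shift-invariant across days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

SECONDS_PER_DAY = 86400

#: wear-validity defaults: >= 8 h wear on >= 4 of the 7 days
MIN_WEAR_MINUTES = 480
MIN_VALID_DAYS = 4

#: epoch intensity labels
LABEL_NONWEAR = "nonwear"
LABEL_BELOW = "below"
LABEL_MPA = "MPA"
LABEL_VPA = "VPA"

MISSING = None  # sentinel alias for a missing weekly estimate


@dataclass(frozen=True)
class CutPoints:
    """MET thresholds for intensity classification.

    The closed MPA band is ``[mpa_lo, mpa_hi]`` and VPA is ``met >= vpa_lo``.
    Values in the open gap ``(mpa_hi, vpa_lo)`` classify as below-moderate;
    with the defaults the gap (5.9, 6.0) is essentially never hit by real
    epoch means but the convention is explicit.
    """

    mpa_lo: float = 3.0
    mpa_hi: float = 5.9
    vpa_lo: float = 6.0

    def __post_init__(self) -> None:
        if not (0 < self.mpa_lo <= self.mpa_hi):
            raise ValidationError(
                f"cut points require 0 < mpa_lo <= mpa_hi, got {self.mpa_lo}..{self.mpa_hi}"
            )
        if not self.vpa_lo > self.mpa_hi:
            raise ValidationError(
                f"cut points require vpa_lo > mpa_hi, got vpa_lo={self.vpa_lo}, mpa_hi={self.mpa_hi}"
            )


@dataclass
class MetSeries:
    """A participant-week MET series at fixed epoch length with wear flags.

    The series must span whole days (``len(met) * epoch_s`` divisible by
    86400) and start at local midnight.
    """

    participant_id: str
    week: str  # "T0" or "T1"
    epoch_s: int
    start: pd.Timestamp
    met: np.ndarray
    wear: np.ndarray

    def __post_init__(self) -> None:
        self.met = np.asarray(self.met, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        if self.epoch_s <= 0:
            raise ValidationError(f"epoch_s must be positive, got {self.epoch_s}")
        if self.met.shape != self.wear.shape or self.met.ndim != 1:
            raise ValidationError("met and wear must be 1-D arrays of equal length")
        if self.met.size == 0:
            raise ValidationError("empty MET series")
        if (self.met.size * self.epoch_s) % SECONDS_PER_DAY != 0:
            raise AlignmentError(
                f"series of {self.met.size} x {self.epoch_s}-s epochs does not span whole days"
            )
        self.start = pd.Timestamp(self.start)
        if self.start != self.start.normalize():
            raise AlignmentError(f"series must start at local midnight, got {self.start}")

    @property
    def n_days(self) -> int:
        return (self.met.size * self.epoch_s) // SECONDS_PER_DAY

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_s


@dataclass(frozen=True)
class DailySummary:
    """Wear and intensity minutes for one calendar day."""

    participant_id: str
    week: str
    date: date
    wear_min: float
    mpa_min: float
    vpa_min: float
    valid: bool


@dataclass(frozen=True)
class WeeklyEstimate:
    """Minutes/week of one intensity from one tool for one participant-week.

    This is the common currency of every downstream comparison.
    ``minutes_per_week is None`` marks a missing estimate (e.g., insufficient
    wear).
    """

    participant_id: str
    week: str
    tool: str  # acc10 | acc60 | diary | ipaq
    intensity: str  # MPA | VPA
    minutes_per_week: float | None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.minutes_per_week is not None and self.minutes_per_week < 0:
            raise ValidationError(
                f"minutes_per_week must be >= 0, got {self.minutes_per_week}"
            )


# ---------------------------------------------------------------------------
# epoch aggregation
# ---------------------------------------------------------------------------

def aggregate_epochs(series: MetSeries, target_epoch_s: int) -> MetSeries:
    """Average a MET series into longer epochs.

    Each output epoch is the mean of its constituent epochs; the output wear
    flag is true iff at least 50% of constituents are wear, and when the
    output epoch is wear only wear constituents enter the mean (non-wear rest
    values would dilute the activity signal). MET x time is conserved exactly
    whenever wear flags are homogeneous within each output window.
    """
    if target_epoch_s % series.epoch_s != 0:
        raise AlignmentError(
            f"target epoch {target_epoch_s}s is not a multiple of base epoch {series.epoch_s}s"
        )
    factor = target_epoch_s // series.epoch_s
    if factor == 1:
        return replace(series, met=series.met.copy(), wear=series.wear.copy())
    if series.met.size % factor != 0:
        raise AlignmentError("series length is not divisible by the aggregation factor")

    met = series.met.reshape(-1, factor)
    wear = series.wear.reshape(-1, factor)
    n_wear = wear.sum(axis=1)
    out_wear = n_wear * 2 >= factor

    out_met = met.mean(axis=1)
    mixed = out_wear & (n_wear < factor)
    if mixed.any():
        wear_sum = np.where(wear[mixed], met[mixed], 0.0).sum(axis=1)
        out_met[mixed] = wear_sum / n_wear[mixed]

    return replace(series, epoch_s=target_epoch_s, met=out_met, wear=out_wear)


# ---------------------------------------------------------------------------
# intensity classification
# ---------------------------------------------------------------------------

def classify_intensity(series: MetSeries, cuts: CutPoints = CutPoints()) -> np.ndarray:
    """Label every epoch as nonwear / below / MPA / VPA.

    Cut-point intervals are closed as printed: MPA is ``mpa_lo <= met <= mpa_hi``
    and VPA is ``met >= vpa_lo``. Non-wear epochs are excluded from all minute
    counts downstream.
    """
    met = series.met
    if np.any(met < 0):
        raise ValidationError("negative MET values are not physical")
    labels = np.full(met.shape, LABEL_BELOW, dtype="U7")
    labels[(met >= cuts.mpa_lo) & (met <= cuts.mpa_hi)] = LABEL_MPA
    labels[met >= cuts.vpa_lo] = LABEL_VPA
    labels[~series.wear] = LABEL_NONWEAR
    return labels


# ---------------------------------------------------------------------------
# non-wear detection (variance stand-in)
# ---------------------------------------------------------------------------

def detect_nonwear(
    series: MetSeries,
    window_min: int = 10,
    interval_s: int = 30,
    sd_threshold: float = 0.05,
    level_max: float = 1.0,
) -> MetSeries:
    """Flag motionless stretches as non-wear from the MET signal alone.

    A 30-s interval is marked non-wear when the surrounding ``window_min``
    window has MET standard deviation below ``sd_threshold`` and mean level at
    most ``level_max`` — an unworn device records a flat resting-level signal.
    This is a variance-threshold detector operating on MET only; synthetic
    input carries ground-truth wear flags, so the detector is opt-in there.

    Returns a copy of the series with ``wear`` replaced.
    """
    if series.epoch_s > interval_s:
        raise ValidationError(
            f"epoch length {series.epoch_s}s exceeds detection interval {interval_s}s"
        )
    if interval_s % series.epoch_s != 0:
        raise AlignmentError("interval_s must be a multiple of the series epoch")

    per_int = interval_s // series.epoch_s
    n_int = series.met.size // per_int
    met = series.met[: n_int * per_int].reshape(n_int, per_int)

    # sufficient statistics per 30-s interval
    s1 = met.sum(axis=1)
    s2 = (met**2).sum(axis=1)

    half = max(1, (window_min * 60) // (2 * interval_s))  # intervals per half-window
    c1 = np.concatenate([[0.0], np.cumsum(s1)])
    c2 = np.concatenate([[0.0], np.cumsum(s2)])
    lo = np.maximum(0, np.arange(n_int) - half + 1)
    hi = np.minimum(n_int, np.arange(n_int) + half + 1)
    cnt = (hi - lo) * per_int
    w1 = c1[hi] - c1[lo]
    w2 = c2[hi] - c2[lo]
    mean = w1 / cnt
    var = np.maximum(0.0, w2 / cnt - mean**2)
    nonwear_int = (np.sqrt(var) < sd_threshold) & (mean <= level_max)

    wear = np.repeat(~nonwear_int, per_int)
    if wear.size < series.met.size:  # ragged tail keeps its original flags
        wear = np.concatenate([wear, series.wear[wear.size:]])
    return replace(series, met=series.met.copy(), wear=wear)


# ---------------------------------------------------------------------------
# daily and weekly summaries
# ---------------------------------------------------------------------------

def summarize_days(labels: np.ndarray, series: MetSeries) -> list[DailySummary]:
    """Per-calendar-day wear/MPA/VPA minutes; a day is valid at >= 8 h wear."""
    if labels.shape != series.met.shape:
        raise ValidationError("labels and series length mismatch")
    per_day = series.epochs_per_day
    min_per_epoch = series.epoch_s / 60.0
    out = []
    for d in range(series.n_days):
        sl = slice(d * per_day, (d + 1) * per_day)
        lab = labels[sl]
        wear_min = float(series.wear[sl].sum()) * min_per_epoch
        mpa_min = float((lab == LABEL_MPA).sum()) * min_per_epoch
        vpa_min = float((lab == LABEL_VPA).sum()) * min_per_epoch
        out.append(
            DailySummary(
                participant_id=series.participant_id,
                week=series.week,
                date=(series.start + timedelta(days=d)).date(),
                wear_min=wear_min,
                mpa_min=mpa_min,
                vpa_min=vpa_min,
                valid=wear_min >= MIN_WEAR_MINUTES,
            )
        )
    return out


def weekly_estimate(
    days: Sequence[DailySummary], min_valid_days: int = MIN_VALID_DAYS
) -> tuple[WeeklyEstimate, WeeklyEstimate]:
    """Extrapolate weekly MPA/VPA minutes from daily summaries.

    With fewer than ``min_valid_days`` valid days the week is missing
    (``insufficient_wear`` flag); otherwise minutes/week is 7 x the mean over
    valid days only. Requires exactly 7 daily records.
    """
    if len(days) != 7:
        raise ValidationError(f"weekly_estimate requires exactly 7 days, got {len(days)}")
    pid, week = days[0].participant_id, days[0].week
    tool = "acc"  # caller renames to acc10/acc60 via tool=
    valid = [d for d in days if d.valid]

    def mk(intensity: str, minutes: float | None, flags: frozenset[str]) -> WeeklyEstimate:
        return WeeklyEstimate(pid, week, tool, intensity, minutes, flags)

    if len(valid) < min_valid_days:
        flags = frozenset({"insufficient_wear"})
        return mk("MPA", MISSING, flags), mk("VPA", MISSING, flags)
    mpa = 7.0 * float(np.mean([d.mpa_min for d in valid]))
    vpa = 7.0 * float(np.mean([d.vpa_min for d in valid]))
    return mk("MPA", mpa, frozenset()), mk("VPA", vpa, frozenset())


def acc_weekly_estimates(
    series: MetSeries,
    analysis_epoch_s: int,
    cuts: CutPoints = CutPoints(),
    min_valid_days: int = MIN_VALID_DAYS,
) -> tuple[WeeklyEstimate, WeeklyEstimate]:
    """Full device pipeline: aggregate, classify, summarize, extrapolate.

    The tool id is ``acc{analysis_epoch_s}`` (e.g., ``acc10``, ``acc60``).
    """
    agg = aggregate_epochs(series, analysis_epoch_s)
    labels = classify_intensity(agg, cuts)
    days = summarize_days(labels, agg)
    mpa, vpa = weekly_estimate(days, min_valid_days=min_valid_days)
    tool = f"acc{analysis_epoch_s}"
    return replace(mpa, tool=tool), replace(vpa, tool=tool)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

MET_CSV_COLUMNS = ["participant_id", "week", "timestamp", "epoch_s", "met", "wear"]


def met_series_to_frame(series: MetSeries) -> pd.DataFrame:
    ts = series.start + pd.to_timedelta(np.arange(series.met.size) * series.epoch_s, unit="s")
    return pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "week": series.week,
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
            "epoch_s": series.epoch_s,
            "met": series.met,
            "wear": series.wear.astype(int),
        }
    )


def write_met_csv(series_list: Iterable[MetSeries], path) -> None:
    frames = [met_series_to_frame(s) for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_met_csv(path) -> list[MetSeries]:
    df = pd.read_csv(path)
    missing = set(MET_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"met series CSV missing columns: {sorted(missing)}")
    out = []
    for (pid, week), grp in df.groupby(["participant_id", "week"], sort=True):
        grp = grp.sort_values("timestamp")
        epoch_s = int(grp["epoch_s"].iloc[0])
        start = pd.Timestamp(grp["timestamp"].iloc[0])
        out.append(
            MetSeries(
                participant_id=str(pid),
                week=str(week),
                epoch_s=epoch_s,
                start=start,
                met=grp["met"].to_numpy(float),
                wear=grp["wear"].to_numpy(bool),
            )
        )
    return out


def estimates_to_frame(estimates: Iterable[WeeklyEstimate]) -> pd.DataFrame:
    """Tidy long-format table of weekly estimates (NaN = missing)."""
    rows = [
        {
            "participant_id": e.participant_id,
            "week": e.week,
            "tool": e.tool,
            "intensity": e.intensity,
            "minutes_per_week": math.nan if e.minutes_per_week is None else e.minutes_per_week,
            "flags": ";".join(sorted(e.flags)),
        }
        for e in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=["participant_id", "week", "tool", "intensity", "minutes_per_week", "flags"],
    )


def write_estimates_csv(estimates: Iterable[WeeklyEstimate] | pd.DataFrame, path) -> None:
    df = estimates if isinstance(estimates, pd.DataFrame) else estimates_to_frame(estimates)
    df.to_csv(path, index=False)


def read_estimates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"participant_id", "week", "tool", "intensity", "minutes_per_week"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"estimates CSV missing columns: {sorted(missing)}")
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df
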