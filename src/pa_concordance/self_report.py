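"""Diary and IPAQ short-form scoring.

Both instruments are scored into the same minutes/week currency as the
device pipeline:

* diary — participants log individual activities with a perceived intensity
  (light / moderate / vigorous); MPA is the sum of moderate durations, VPA of
  vigorous ones; light is ignored because the questionnaire has no comparable
  item. Participants are instructed to record only activities longer than
  10 min, and by default entries of <= 10 min are dropped at scoring time too.
* IPAQ short form — days x minutes/day per item; walking counts toward MPA
  together with the moderate item. Plain multiplication, no truncation by
  default (an optional 180 min/day cap is available for users who want the
  official protocol's cleaning rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import pandas as pd

from .accelerometry import MISSING, WeeklyEstimate
from .errors import ValidationError

INTENSITY_LEVELS = ("light", "moderate", "vigorous")

#: diary instruction threshold, minutes; "more than 10 min" is strict
DIARY_MIN_DURATION = 10.0


@dataclass(frozen=True)
class DiaryEntry:
    """One logged activity in the physical-activity diary."""

    participant_id: str
    week: str
    date: date
    duration_min: float
    perceived_intensity: str  # light | moderate | vigorous
    start_time: str | None = None
    activity_type: str = ""

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValidationError(f"diary duration must be > 0 min, got {self.duration_min}")
        if self.perceived_intensity not in INTENSITY_LEVELS:
            raise ValidationError(
                f"unknown perceived intensity {self.perceived_intensity!r}"
            )


@dataclass(frozen=True)
class IpaqResponse:
    """IPAQ short-form items for one participant-week (adults only)."""

    participant_id: str
    week: str
    vig_days: int
    vig_min_per_day: float
    mod_days: int
    mod_min_per_day: float
    walk_days: int
    walk_min_per_day: float

    def __post_init__(self) -> None:
        for name in ("vig_days", "mod_days", "walk_days"):
            v = getattr(self, name)
            if not (isinstance(v, int) and 0 <= v <= 7):
                raise ValidationError(f"{name} must be an integer in 0..7, got {v!r}")
        for name in ("vig_min_per_day", "mod_min_per_day", "walk_min_per_day"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def score_diary(
    entries: Sequence[DiaryEntry],
    participant_id: str | None = None,
    week: str | None = None,
    enforce_10min: bool = True,
    week_start: date | None = None,
) -> tuple[WeeklyEstimate, WeeklyEstimate]:
    """Sum diary entries into weekly MPA/VPA estimates.

    An empty entry list scores as 0 minutes with an ``empty_week`` flag: the
    diary format cannot distinguish "no activity" from "not filled in", so the
    flag lets callers choose either interpretation. When ``week_start`` is
    given, entries dated outside the 7-day window raise a validation error
    naming the offending rows.
    """
    if entries:
        pids = {e.participant_id for e in entries}
        weeks = {e.week for e in entries}
        if len(pids) > 1 or len(weeks) > 1:
            raise ValidationError("diary entries span multiple participants or weeks")
        participant_id, week = entries[0].participant_id, entries[0].week
    if participant_id is None or week is None:
        raise ValidationError("participant_id and week required for an empty diary")

    if week_start is not None:
        bad = [
            i
            for i, e in enumerate(entries)
            if not (week_start <= e.date <= week_start + timedelta(days=6))
        ]
        if bad:
            raise ValidationError(f"diary entries outside measurement week at rows {bad}")

    kept = [
        e for e in entries if not (enforce_10min and e.duration_min <= DIARY_MIN_DURATION)
    ]
    mpa = sum(e.duration_min for e in kept if e.perceived_intensity == "moderate")
    vpa = sum(e.duration_min for e in kept if e.perceived_intensity == "vigorous")
    flags = frozenset({"empty_week"}) if not entries else frozenset()
    return (
        WeeklyEstimate(participant_id, week, "diary", "MPA", float(mpa), flags),
        WeeklyEstimate(participant_id, week, "diary", "VPA", float(vpa), flags),
    )


def score_ipaq(
    resp: IpaqResponse, truncate_min_per_day: float | None = None
) -> tuple[WeeklyEstimate, WeeklyEstimate]:
    """Score an IPAQ short form: days x minutes/day, walking into MPA."""

    def cap(m: float) -> float:
        return min(m, truncate_min_per_day) if truncate_min_per_day is not None else m

    vpa = resp.vig_days * cap(resp.vig_min_per_day)
    mpa = resp.mod_days * cap(resp.mod_min_per_day) + resp.walk_days * cap(
        resp.walk_min_per_day
    )
    return (
        WeeklyEstimate(resp.participant_id, resp.week, "ipaq", "MPA", float(mpa)),
        WeeklyEstimate(resp.participant_id, resp.week, "ipaq", "VPA", float(vpa)),
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

DIARY_CSV_COLUMNS = [
    "participant_id",
    "week",
    "date",
    "start_time",
    "duration_min",
    "intensity",
    "activity_type",
]

IPAQ_CSV_COLUMNS = [
    "participant_id",
    "week",
    "vig_days",
    "vig_min",
    "mod_days",
    "mod_min",
    "walk_days",
    "walk_min",
]


def write_diary_csv(entries: Iterable[DiaryEntry], path) -> None:
    rows = [
        {
            "participant_id": e.participant_id,
            "week": e.week,
            "date": e.date.isoformat(),
            "start_time": e.start_time or "",
            "duration_min": e.duration_min,
            "intensity": e.perceived_intensity,
            "activity_type": e.activity_type,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=DIARY_CSV_COLUMNS).to_csv(path, index=False)


def read_diary_csv(path) -> list[DiaryEntry]:
    df = pd.read_csv(path)
    missing = set(DIARY_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"diary CSV missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            DiaryEntry(
                participant_id=str(r["participant_id"]),
                week=str(r["week"]),
                date=date.fromisoformat(str(r["date"])),
                duration_min=float(r["duration_min"]),
                perceived_intensity=str(r["intensity"]),
                start_time=None if pd.isna(r["start_time"]) else str(r["start_time"]),
                activity_type="" if pd.isna(r["activity_type"]) else str(r["activity_type"]),
            )
        )
    return out


def write_ipaq_csv(responses: Iterable[IpaqResponse], path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "week": r.week,
            "vig_days": r.vig_days,
            "vig_min": r.vig_min_per_day,
            "mod_days": r.mod_days,
            "mod_min": r.mod_min_per_day,
            "walk_days": r.walk_days,
            "walk_min": r.walk_min_per_day,
        }
        for r in responses
    ]
    pd.DataFrame(rows, columns=IPAQ_CSV_COLUMNS).to_csv(path, index=False)


def read_ipaq_csv(path) -> list[IpaqResponse]:
    df = pd.read_csv(path)
    missing = set(IPAQ_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"IPAQ CSV missing columns: {sorted(missing)}")
    return [
        IpaqResponse(
            participant_id=str(r["participant_id"]),
            week=str(r["week"]),
            vig_days=int(r["vig_days"]),
            vig_min_per_day=float(r["vig_min"]),
            mod_days=int(r["mod_days"]),
            mod_min_per_day=float(r["mod_min"]),
            walk_days=int(r["walk_days"]),
            walk_min_per_day=float(r["walk_min"]),
        )
        for _, r in df.iterrows()
    ]
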