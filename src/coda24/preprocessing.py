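"""From raw daily activity records and parent surveys to analysis-ready children.

Each child contributes up to seven days of hip-worn accelerometer output,
pre-classified minute-by-minute into five wake behaviours (sedentary,
light-intensity activities and games, walking, running, moderate-to-vigorous
activities and games), plus a parent survey with usual sleep, weekly screen
and quiet-play minutes, demographics and Strengths and Difficulties
Questionnaire (SDQ) subscale scores. This module applies the study's
inclusion rules, averages valid days, folds walking/running/MV games into a
single "energetic play" part, reallocates device non-wear proportionally to
the wake behaviours, and closes each child's day to 1440 min — optionally
splitting device sedentary time into screen and quiet play using the
parent-reported proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import (
    BEHAVIOURS_4,
    BEHAVIOURS_5,
    Composition,
    CompositionError,
    close,
    zero_replace,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DayRecord",
    "SurveyRecord",
    "ChildRecord",
    "detect_nonwear",
    "day_is_valid",
    "child_meets_wear_criteria",
    "average_wake_behaviours",
    "reallocate_nonwear",
    "disaggregate_sedentary",
    "build_child_records",
    "read_daily_csv",
    "read_survey_csv",
    "records_to_frame",
]

SDQ_SUBSCALES = ("emotional", "conduct", "hyperactivity", "peer", "prosocial")
#: subscales summed into total difficulties (prosocial excluded)
DIFFICULTY_SUBSCALES = ("emotional", "conduct", "hyperactivity", "peer")
OUTCOMES = ("total_difficulties",) + SDQ_SUBSCALES

SEXES = ("male", "female")
EDUCATION_LEVELS = ("secondary", "certificate", "tertiary")

DAILY_COLUMNS = [
    "child_id", "date", "is_weekend", "wear_min", "sedentary_min",
    "light_games_min", "walking_min", "running_min", "mv_games_min",
]
SURVEY_COLUMNS = [
    "child_id", "sleep_night_min", "sleep_day_min", "screen_weekly_min",
    "quiet_weekly_min", "age_years", "sex", "parent_education",
    "sdq_emotional", "sdq_conduct", "sdq_hyperactivity", "sdq_peer",
    "sdq_prosocial",
]


@dataclass(frozen=True)
class DayRecord:
    """One day of classified accelerometer output for one child."""

    child_id: str
    date: str
    is_weekend: bool
    wear_min: float
    sedentary_min: float
    light_games_min: float
    walking_min: float
    running_min: float
    mv_games_min: float

    def __post_init__(self) -> None:
        mins = (self.wear_min, self.sedentary_min, self.light_games_min,
                self.walking_min, self.running_min, self.mv_games_min)
        if any(m < 0 for m in mins):
            raise ValueError(f"negative minutes in day record for {self.child_id}")
        if self.wear_min > 1440:
            raise ValueError(f"wear_min {self.wear_min} exceeds a day")
        total_classes = sum(mins[1:])
        # 0.01-min slack absorbs 6-significant-digit CSV round-trips
        if total_classes > self.wear_min + 1e-2:
            raise ValueError(
                f"class minutes {total_classes} exceed wear {self.wear_min} "
                f"for {self.child_id} on {self.date}"
            )


@dataclass(frozen=True)
class SurveyRecord:
    """Parent-report survey row: sleep, sedentary reports, demographics, SDQ."""

    child_id: str
    sleep_night_min: float
    sleep_day_min: float
    screen_weekly_min: float | None
    quiet_weekly_min: float | None
    age_years: float
    sex: str
    parent_education: str
    sdq: dict[str, int]

    def __post_init__(self) -> None:
        if self.sleep_night_min < 0 or self.sleep_day_min < 0:
            raise ValueError(f"negative sleep for {self.child_id}")
        if self.sleep_night_min + self.sleep_day_min >= 1440:
            raise ValueError(f"sleep >= 1440 min for {self.child_id}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.parent_education not in EDUCATION_LEVELS:
            raise ValueError(f"unknown parent_education {self.parent_education!r}")
        for k in SDQ_SUBSCALES:
            v = self.sdq.get(k)
            if v is None or not 0 <= v <= 10:
                raise ValueError(f"SDQ subscale {k} out of range for {self.child_id}: {v}")

    @property
    def sleep_total_min(self) -> float:
        return self.sleep_night_min + self.sleep_day_min


@dataclass(frozen=True)
class ChildRecord:
    """One included child: closed composition, covariates and SDQ outcomes."""

    child_id: str
    composition: Composition
    age_years: float
    sex: str
    parent_education: str
    outcomes: dict[str, float]

    def __post_init__(self) -> None:
        expected = sum(self.outcomes[k] for k in DIFFICULTY_SUBSCALES)
        if abs(self.outcomes["total_difficulties"] - expected) > 1e-9:
            raise ValueError(
                f"total_difficulties inconsistent with subscales for {self.child_id}"
            )


def detect_nonwear(
    sd_series: np.ndarray, threshold_mg: float = 13.0, min_run_min: int = 30
) -> list[tuple[int, int]]:
    """Find non-wear intervals in a per-minute signal-SD trace.

    A minute counts as candidate non-wear when its acceleration standard
    deviation is strictly below `threshold_mg` (mg); maximal runs of at least
    `min_run_min` consecutive candidate minutes are reported as half-open
    [start, end) intervals, sorted and non-overlapping.
    """
    s = np.asarray(sd_series, dtype=float)
    if s.size == 0:
        raise ValueError("empty SD series")
    if np.any(s < 0):
        raise ValueError("negative signal SD")
    below = s < threshold_mg
    intervals: list[tuple[int, int]] = []
    # edges of runs of True
    padded = np.concatenate([[False], below, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for a, b in zip(starts, ends):
        if b - a >= min_run_min:
            intervals.append((int(a), int(b)))
    return intervals


def day_is_valid(day: DayRecord, min_wear_min: float = 480.0) -> bool:
    """A day is valid when the device was worn at least eight hours."""
    return day.wear_min >= min_wear_min


def child_meets_wear_criteria(
    days: Sequence[DayRecord], min_wear_min: float = 480.0
) -> bool:
    """Inclusion rule: >=3 valid weekdays and >=1 valid weekend day."""
    ids = {d.child_id for d in days}
    if len(ids) > 1:
        raise ValueError(f"days from multiple children: {sorted(ids)}")
    valid = [d for d in days if day_is_valid(d, min_wear_min)]
    weekdays = sum(not d.is_weekend for d in valid)
    weekend = sum(d.is_weekend for d in valid)
    return weekdays >= 3 and weekend >= 1


def average_wake_behaviours(days: Sequence[DayRecord]) -> dict[str, float]:
    """Unweighted mean of valid-day wake behaviours, energetic play aggregated.

    Energetic play is the per-day sum of walking, running and
    moderate-to-vigorous activities and games; means are taken across the
    supplied days. Returns a mapping with keys sedentary, light_games,
    energetic and wear.
    """
    if not days:
        raise ValueError("no days to average")
    sed = np.mean([d.sedentary_min for d in days])
    lg = np.mean([d.light_games_min for d in days])
    en = np.mean([d.walking_min + d.running_min + d.mv_games_min for d in days])
    wear = np.mean([d.wear_min for d in days])
    return {"sedentary": float(sed), "light_games": float(lg),
            "energetic": float(en), "wear": float(wear)}


def reallocate_nonwear(
    wake: Mapping[str, float], sleep_total_min: float
) -> Composition:
    """Close a child's day by scaling wake behaviours into the non-sleep window.

    Device non-wear (and any shortfall or excess of mean wear relative to the
    waking window) is reallocated *proportionally* across the wake
    behaviours: each wake part is scaled by
    (1440 - sleep) / sum(wake parts), which preserves the ratios between
    wake behaviours exactly. Sleep is taken from the parent report.
    """
    if not 0 < sleep_total_min < 1440:
        raise CompositionError(f"sleep must lie in (0, 1440), got {sleep_total_min}")
    wake_parts = {k: float(v) for k, v in wake.items() if k != "wear"}
    s = sum(wake_parts.values())
    if s <= 0:
        raise CompositionError("wake parts sum to zero; nothing to reallocate")
    if any(v <= 0 for v in wake_parts.values()):
        raise CompositionError("wake parts must be strictly positive")
    scale = (1440.0 - sleep_total_min) / s
    parts = {"sleep": float(sleep_total_min)}
    parts.update({k: v * scale for k, v in wake_parts.items()})
    ordered = {name: parts[name] for name in BEHAVIOURS_4}
    return Composition(ordered, 1440.0)


def disaggregate_sedentary(
    c: Composition, screen_weekly_min: float, quiet_weekly_min: float
) -> Composition:
    """Split device sedentary time into screen and quiet-play parts.

    The parent-reported usual weekly screen and quiet-play minutes are
    converted to daily values (/7), zeros replaced with 1 min, and the
    resulting proportions applied to the device-measured sedentary part.
    Screen + quiet play equals the original sedentary part exactly, so the
    1440-min total is preserved.
    """
    if c.names != BEHAVIOURS_4:
        raise CompositionError(f"expected 4-part composition, got {c.names}")
    if screen_weekly_min < 0 or quiet_weekly_min < 0:
        raise CompositionError("weekly report minutes must be non-negative")
    daily, _ = zero_replace(
        {"screen": screen_weekly_min / 7.0, "quiet_play": quiet_weekly_min / 7.0}
    )
    sb = c["sedentary"]
    denom = daily["screen"] + daily["quiet_play"]
    screen_part = sb * daily["screen"] / denom
    quiet_part = sb * daily["quiet_play"] / denom
    parts = {
        "sleep": c["sleep"],
        "screen": screen_part,
        "quiet_play": quiet_part,
        "light_games": c["light_games"],
        "energetic": c["energetic"],
    }
    return Composition(parts, c.total)


def read_daily_csv(path) -> list[DayRecord]:
    """Read the daily accelerometer CSV (exact header contract)."""
    df = pd.read_csv(path)
    missing = [c for c in DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"daily CSV missing columns: {missing}")
    return [
        DayRecord(
            child_id=str(r.child_id), date=str(r.date),
            is_weekend=bool(r.is_weekend), wear_min=float(r.wear_min),
            sedentary_min=float(r.sedentary_min),
            light_games_min=float(r.light_games_min),
            walking_min=float(r.walking_min), running_min=float(r.running_min),
            mv_games_min=float(r.mv_games_min),
        )
        for r in df.itertuples(index=False)
    ]


def read_survey_csv(path) -> list[SurveyRecord]:
    """Read the parent survey CSV (exact header contract).

    Missing screen/quiet reports may be encoded as empty cells; they become
    None and the child is dropped only in disaggregated (5-part) mode.
    """
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey CSV missing columns: {missing}")
    if df["child_id"].astype(str).duplicated().any():
        dups = df["child_id"][df["child_id"].astype(str).duplicated()].tolist()
        raise ValueError(f"duplicate child_id in survey: {dups}")
    out = []
    for r in df.itertuples(index=False):
        out.append(SurveyRecord(
            child_id=str(r.child_id),
            sleep_night_min=float(r.sleep_night_min),
            sleep_day_min=float(r.sleep_day_min),
            screen_weekly_min=None if pd.isna(r.screen_weekly_min) else float(r.screen_weekly_min),
            quiet_weekly_min=None if pd.isna(r.quiet_weekly_min) else float(r.quiet_weekly_min),
            age_years=float(r.age_years),
            sex=str(r.sex),
            parent_education=str(r.parent_education),
            sdq={
                "emotional": int(r.sdq_emotional),
                "conduct": int(r.sdq_conduct),
                "hyperactivity": int(r.sdq_hyperactivity),
                "peer": int(r.sdq_peer),
                "prosocial": int(r.sdq_prosocial),
            },
        ))
    return out


def build_child_records(
    days: Sequence[DayRecord],
    surveys: Sequence[SurveyRecord],
    disaggregate: bool = False,
    min_wear_min: float = 480.0,
) -> tuple[list[ChildRecord], dict[str, int]]:
    """Assemble one analysis record per child passing all inclusion rules.

    Children are kept only if they meet the wear criteria (>=3 valid weekdays
    and >=1 valid weekend day) and have complete survey data; in
    disaggregated mode children without screen/quiet reports are also
    excluded. Wake behaviours averaging exactly zero across valid days are
    set to 1 min before closure (logged), mirroring the zero-replacement
    convention. Returns the records plus an exclusion-count log.
    """
    seen: set[str] = set()
    for s in surveys:
        if s.child_id in seen:
            raise ValueError(f"duplicate child_id {s.child_id} in surveys")
        seen.add(s.child_id)

    by_child: dict[str, list[DayRecord]] = {}
    for d in days:
        by_child.setdefault(d.child_id, []).append(d)

    counts = {
        "n_surveys": len(surveys),
        "excluded_no_accel": 0,
        "excluded_wear_criteria": 0,
        "excluded_missing_sedentary_report": 0,
        "zero_wake_parts_replaced": 0,
        "included": 0,
    }
    records: list[ChildRecord] = []
    for s in surveys:
        child_days = by_child.get(s.child_id)
        if not child_days:
            counts["excluded_no_accel"] += 1
            continue
        if not child_meets_wear_criteria(child_days, min_wear_min):
            counts["excluded_wear_criteria"] += 1
            continue
        if disaggregate and (s.screen_weekly_min is None or s.quiet_weekly_min is None):
            counts["excluded_missing_sedentary_report"] += 1
            logger.info("child %s excluded: no parent-report sedentary data", s.child_id)
            continue
        valid_days = [d for d in child_days if day_is_valid(d, min_wear_min)]
        wake = average_wake_behaviours(valid_days)
        wake_parts, n_rep = zero_replace(
            {k: wake[k] for k in ("sedentary", "light_games", "energetic")}
        )
        if n_rep:
            counts["zero_wake_parts_replaced"] += n_rep
            logger.info("child %s: %d zero wake part(s) set to 1 min", s.child_id, n_rep)
        comp = reallocate_nonwear(wake_parts, s.sleep_total_min)
        if disaggregate:
            comp = disaggregate_sedentary(comp, s.screen_weekly_min, s.quiet_weekly_min)
        outcomes = {k: float(s.sdq[k]) for k in SDQ_SUBSCALES}
        outcomes["total_difficulties"] = float(
            sum(s.sdq[k] for k in DIFFICULTY_SUBSCALES)
        )
        records.append(ChildRecord(
            child_id=s.child_id, composition=comp, age_years=s.age_years,
            sex=s.sex, parent_education=s.parent_education, outcomes=outcomes,
        ))
        counts["included"] += 1
    return records, counts


def records_to_frame(records: Sequence[ChildRecord]) -> pd.DataFrame:
    """Flatten child records to a DataFrame (one row per child) for export."""
    rows = []
    for r in records:
        row: dict[str, object] = {"child_id": r.child_id}
        row.update({f"{k}_min": v for k, v in r.composition.parts.items()})
        row.update({
            "age_years": r.age_years, "sex": r.sex,
            "parent_education": r.parent_education,
        })
        row.update({k: r.outcomes[k] for k in OUTCOMES})
        rows.append(row)
    return pd.DataFrame(rows)
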