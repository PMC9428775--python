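"""Epoch-level accelerometer count processing.

Counts accumulated over fixed-length epochs (15 s by default) are turned
into daily sedentary / light (LPA) / moderate-to-vigorous (MVPA) minutes:

* nonwear is any maximal run of zero-count epochs lasting at least 60 min,
  evaluated within a calendar day (runs do not span midnight);
* wear epochs are classified by count cut-points — sedentary at or below 25
  counts per 15-s epoch, MVPA at or above an age-specific threshold, LPA in
  between;
* a day is valid with >=8 h wear on weekdays or >=7 h on weekend days, and a
  participant-time point is included with >=3 valid days, class minutes
  averaged over the valid days.

All thresholds live in :class:`CutPoints` and are configurable; the shipped
age-specific MVPA default solves the Freedson youth energy-cost equation
``METs = 2.757 + 0.0015*cpm - 0.08957*age - 0.000038*cpm*age`` for the
4-MET counts-per-minute threshold and rescales it to the epoch length.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochSeries",
    "CutPoints",
    "DaySummary",
    "ParticipantActivity",
    "freedson_mvpa_cutpoint",
    "detect_nonwear",
    "classify_epochs",
    "summarize_day",
    "aggregate_participant",
    "summarize_cohort",
    "epochs_to_frame",
    "frame_to_series",
]

#: epoch class codes used throughout
NONWEAR, SEDENTARY, LPA, MVPA = "nonwear", "sedentary", "lpa", "mvpa"
CLASSES = (SEDENTARY, LPA, MVPA)

MIN_VALID_DAYS = 3
WEEKDAY_VALID_MIN = 8 * 60
WEEKEND_VALID_MIN = 7 * 60


@dataclass
class EpochSeries:
    """One participant-day of accelerometer counts at fixed epoch length."""

    participant_id: str
    date: dt.date
    counts: np.ndarray
    epoch_len: int = 15  # seconds

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(self.counts) * self.epoch_len > 86400:
            raise ValueError("counts cover more than 24 hours")

    @property
    def epochs_per_minute(self) -> int:
        if 60 % self.epoch_len:
            raise ValueError(
                f"epoch length {self.epoch_len}s does not divide 60 s evenly"
            )
        return 60 // self.epoch_len


def freedson_mvpa_cutpoint(age_years: float, epoch_len: int = 15, mets: float = 4.0) -> float:
    """Age-specific MVPA count threshold per epoch (Freedson youth equation).

    Solves ``mets = 2.757 + 0.0015*cpm - 0.08957*age - 0.000038*cpm*age`` for
    counts per minute and rescales to the epoch length.  Supported for ages
    where the count coefficient stays positive (< ~39 years).
    """
    denom = 0.0015 - 0.000038 * age_years
    if denom <= 0:
        raise ValueError(f"age {age_years} outside the supported range of the equation")
    cpm = (mets - 2.757 + 0.08957 * age_years) / denom
    if cpm <= 0:
        raise ValueError(f"age {age_years} yields a nonpositive MVPA threshold")
    return cpm * epoch_len / 60.0


@dataclass(frozen=True)
class CutPoints:
    """Count thresholds for intensity classification and nonwear detection.

    ``mvpa_min`` is a fixed counts-per-epoch threshold; when ``None`` the
    age-specific default equation is used (``age`` must then be supplied to
    :func:`classify_epochs`).
    """

    sedentary_max: float = 25.0
    mvpa_min: float | None = None
    nonwear_run_min: int = 60

    def __post_init__(self) -> None:
        if self.sedentary_max <= 0:
            raise ValueError("sedentary_max must be positive")
        if self.nonwear_run_min <= 0:
            raise ValueError("nonwear_run_min must be positive")
        if self.mvpa_min is not None and self.mvpa_min <= self.sedentary_max:
            raise ValueError("mvpa_min must exceed sedentary_max")

    def mvpa_threshold(self, age_years: float | None, epoch_len: int = 15) -> float:
        if self.mvpa_min is not None:
            return self.mvpa_min
        if age_years is None:
            raise ValueError("age required for the age-specific MVPA threshold")
        thr = freedson_mvpa_cutpoint(age_years, epoch_len)
        if thr <= self.sedentary_max:
            raise ValueError(
                f"age {age_years}: MVPA threshold {thr:.1f} does not exceed "
                f"sedentary_max {self.sedentary_max}"
            )
        return thr


@dataclass
class DaySummary:
    participant_id: str
    date: dt.date
    is_weekend: bool
    wear_min: float
    sedentary_min: float
    lpa_min: float
    mvpa_min: float
    nonwear_min: float
    valid: bool


@dataclass
class ParticipantActivity:
    participant_id: str
    time_point: str
    n_valid_days: int
    avg_wear_min: float
    avg_sedentary_min: float
    avg_lpa_min: float
    avg_mvpa_min: float
    included: bool


def detect_nonwear(series: EpochSeries, cutpoints: CutPoints) -> np.ndarray:
    """Boolean wear mask: False where the epoch lies in a maximal zero-count
    run of at least ``nonwear_run_min`` minutes.

    Runs are strict (any nonzero count breaks them) and are evaluated within
    the day only.
    """
    run_epochs = cutpoints.nonwear_run_min * series.epochs_per_minute
    zero = series.counts == 0
    wear = np.ones(len(zero), dtype=bool)
    if not zero.any():
        return wear
    # run-length encode the zero indicator
    boundaries = np.flatnonzero(np.diff(zero.astype(np.int8)))
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [len(zero)]))
    for s, e in zip(starts, ends):
        if zero[s] and e - s >= run_epochs:
            wear[s:e] = False
    return wear


def classify_epochs(
    series: EpochSeries,
    wear_mask: np.ndarray,
    cutpoints: CutPoints,
    age_years: float | None = None,
) -> np.ndarray:
    """Per-epoch class labels in {nonwear, sedentary, lpa, mvpa}.

    Nonwear epochs keep the nonwear label regardless of counts; zero counts
    during wear (sub-threshold zero runs) are sedentary.
    """
    if len(wear_mask) != len(series.counts):
        raise ValueError("wear mask not aligned with the epoch series")
    mvpa_thr = cutpoints.mvpa_threshold(age_years, series.epoch_len)
    labels = np.where(
        series.counts <= cutpoints.sedentary_max,
        SEDENTARY,
        np.where(series.counts >= mvpa_thr, MVPA, LPA),
    )
    labels = np.where(wear_mask, labels, NONWEAR)
    return labels


def summarize_day(series: EpochSeries, labels: np.ndarray) -> DaySummary:
    """Minute totals per class and the daily validity flag."""
    per_min = series.epochs_per_minute
    minutes = {c: float(np.count_nonzero(labels == c)) / per_min for c in CLASSES}
    nonwear_min = float(np.count_nonzero(labels == NONWEAR)) / per_min
    wear_min = sum(minutes.values())
    is_weekend = series.date.weekday() >= 5
    threshold = WEEKEND_VALID_MIN if is_weekend else WEEKDAY_VALID_MIN
    return DaySummary(
        participant_id=series.participant_id,
        date=series.date,
        is_weekend=is_weekend,
        wear_min=wear_min,
        sedentary_min=minutes[SEDENTARY],
        lpa_min=minutes[LPA],
        mvpa_min=minutes[MVPA],
        nonwear_min=nonwear_min,
        valid=wear_min >= threshold,
    )


def aggregate_participant(
    days: Sequence[DaySummary], time_point: str
) -> ParticipantActivity:
    """Unweighted mean over valid days; ``included`` requires >=3 valid days.

    With fewer than 3 valid days the averages over the valid days (or NaN if
    none) are still reported, flagged excluded.
    """
    if not days:
        raise ValueError("empty day list")
    pids = {d.participant_id for d in days}
    if len(pids) > 1:
        raise ValueError(f"days belong to multiple participants: {sorted(pids)}")
    valid = [d for d in days if d.valid]
    n_valid = len(valid)

    def _mean(attr: str) -> float:
        return float(np.mean([getattr(d, attr) for d in valid])) if valid else float("nan")

    return ParticipantActivity(
        participant_id=days[0].participant_id,
        time_point=time_point,
        n_valid_days=n_valid,
        avg_wear_min=_mean("wear_min"),
        avg_sedentary_min=_mean("sedentary_min"),
        avg_lpa_min=_mean("lpa_min"),
        avg_mvpa_min=_mean("mvpa_min"),
        included=n_valid >= MIN_VALID_DAYS,
    )


def summarize_cohort(
    series_by_key: dict[tuple[str, str], list[EpochSeries]],
    cutpoints: CutPoints,
    ages: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run nonwear detection, classification and aggregation for a cohort.

    ``series_by_key`` maps ``(participant_id, time_point)`` to that
    participant's recorded days.  Returns (day summaries, participant
    activity) as data frames with the documented column names.
    """
    day_rows: list[DaySummary] = []
    part_rows: list[ParticipantActivity] = []
    for (pid, tp), series_list in series_by_key.items():
        age = ages.get(pid) if ages else None
        days = []
        for series in series_list:
            wear = detect_nonwear(series, cutpoints)
            labels = classify_epochs(series, wear, cutpoints, age)
            days.append(summarize_day(series, labels))
        day_rows.extend(days)
        part_rows.append(aggregate_participant(days, tp))
    day_df = pd.DataFrame([vars(d) for d in day_rows])
    part_df = pd.DataFrame([vars(p) for p in part_rows])
    return day_df, part_df


def epochs_to_frame(series_list: Iterable[EpochSeries]) -> pd.DataFrame:
    """Long epoch table: participant_id, date (ISO-8601), epoch_index, counts."""
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "date": s.date.isoformat(),
                    "epoch_index": np.arange(len(s.counts)),
                    "counts": s.counts.astype(np.int64),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["participant_id", "date", "epoch_index", "counts"])
    return pd.concat(frames, ignore_index=True)


def frame_to_series(frame: pd.DataFrame, epoch_len: int = 15) -> list[EpochSeries]:
    """Inverse of :func:`epochs_to_frame`; epochs sorted by index per day."""
    out = []
    for (pid, date), grp in frame.groupby(["participant_id", "date"], sort=True):
        grp = grp.sort_values("epoch_index")
        idx = grp["epoch_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError(f"epoch indices for {pid} on {date} are not contiguous from 0")
        out.append(
            EpochSeries(
                participant_id=str(pid),
                date=dt.date.fromisoformat(str(date)),
                counts=grp["counts"].to_numpy(),
                epoch_len=epoch_len,
            )
        )
    return out
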