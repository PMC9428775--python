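"""Scoring of psychosocial mediator scales from Likert item responses.

Seven instruments are registered by default, covering the social-cognitive
constructs typically targeted by adolescent physical-activity interventions:
self-efficacy, peer/family/teacher support, self-regulation strategies,
perceived barriers and enjoyment.  Each scale score is the plain sum of its
item responses; reverse-keyed items (none by default, configurable) are
mapped through ``level_min + level_max - value`` before summing.  A score is
only defined when every item is answered — missing items void the score
rather than being prorated, matching a complete-case analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ScaleDefinition",
    "ScaleScore",
    "DEFAULT_SCALES",
    "score_scale",
    "score_table",
    "validate_scale_table",
]

TIME_POINTS = ("T0", "T1")


class ScaleValidationError(ValueError):
    """Raised for responses outside the scale's admissible levels."""


@dataclass(frozen=True)
class ScaleDefinition:
    """Structure of one Likert instrument.

    Parameters
    ----------
    name:
        Scale identifier; also the prefix of its item columns
        (``<name>_<item#>_<T0|T1>``, items numbered from 1).
    n_items:
        Number of items.
    level_min, level_max:
        Admissible response levels (inclusive).
    reverse_items:
        1-based indices of reverse-keyed items, mapped through
        ``level_min + level_max - value`` before summing.
    """

    name: str
    n_items: int
    level_min: int
    level_max: int
    reverse_items: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError(f"scale {self.name!r}: n_items must be >= 1")
        if self.level_min >= self.level_max:
            raise ValueError(f"scale {self.name!r}: level_min must be < level_max")
        bad = [i for i in self.reverse_items if not 1 <= i <= self.n_items]
        if bad:
            raise ValueError(f"scale {self.name!r}: reverse_items out of range: {bad}")

    @property
    def score_min(self) -> int:
        return self.n_items * self.level_min

    @property
    def score_max(self) -> int:
        return self.n_items * self.level_max

    def reverse(self, value: int) -> int:
        """Reverse-key one response level (an involution)."""
        return self.level_min + self.level_max - value

    def item_columns(self, time_point: str) -> list[str]:
        return [f"{self.name}_{i}_{time_point}" for i in range(1, self.n_items + 1)]


@dataclass(frozen=True)
class ScaleScore:
    participant_id: str
    scale: str
    time_point: str
    score: int | None
    complete: bool


#: Default registry.  Printed score ranges: self-efficacy 5-30, peer support
#: 5-25, family support 4-20, teacher support 4-20, self-regulation 6-30,
#: perceived barriers 9-36, enjoyment 16-80.
DEFAULT_SCALES: dict[str, ScaleDefinition] = {
    s.name: s
    for s in (
        ScaleDefinition("self_efficacy", 5, 1, 6),
        ScaleDefinition("peer_support", 5, 1, 5),
        ScaleDefinition("family_support", 4, 1, 5),
        ScaleDefinition("teacher_support", 4, 1, 5),
        ScaleDefinition("self_regulation", 6, 1, 5),
        ScaleDefinition("barriers", 9, 1, 4),
        ScaleDefinition("enjoyment", 16, 1, 5),
    )
}


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(float(value))
    except (TypeError, ValueError):
        return False


def score_scale(
    responses: Sequence,
    scale: ScaleDefinition,
    participant_id: str = "",
    time_point: str = "",
) -> ScaleScore:
    """Sum one participant's item responses for one scale.

    Missing responses (``None``/NaN) yield ``complete=False`` with an
    undefined score.  Out-of-range responses raise
    :class:`ScaleValidationError` naming the offending item.
    """
    if len(responses) != scale.n_items:
        raise ScaleValidationError(
            f"scale {scale.name!r}: expected {scale.n_items} responses, "
            f"got {len(responses)}"
        )
    total = 0
    complete = True
    for idx, value in enumerate(responses, start=1):
        if _is_missing(value):
            complete = False
            continue
        level = int(value)
        if level != float(value) or not scale.level_min <= level <= scale.level_max:
            raise ScaleValidationError(
                f"scale {scale.name!r}, item {idx}: response {value!r} outside "
                f"[{scale.level_min}, {scale.level_max}]"
            )
        total += scale.reverse(level) if idx in scale.reverse_items else level
    return ScaleScore(
        participant_id=participant_id,
        scale=scale.name,
        time_point=time_point,
        score=total if complete else None,
        complete=complete,
    )


def score_table(
    participants: pd.DataFrame,
    scales: Mapping[str, ScaleDefinition] | None = None,
    time_points: Iterable[str] = TIME_POINTS,
    id_col: str = "participant_id",
) -> pd.DataFrame:
    """Score every registered scale at every time point for a participant table.

    Returns a tidy frame with columns ``participant_id, scale, time_point,
    score, complete`` (score is NaN where incomplete).
    """
    scales = DEFAULT_SCALES if scales is None else scales
    rows = []
    for _, rec in participants.iterrows():
        pid = rec[id_col]
        for scale in scales.values():
            for tp in time_points:
                cols = scale.item_columns(tp)
                missing_cols = [c for c in cols if c not in participants.columns]
                if missing_cols:
                    raise KeyError(
                        f"item columns missing for scale {scale.name!r} at {tp}: "
                        f"{missing_cols}"
                    )
                result = score_scale([rec[c] for c in cols], scale, pid, tp)
                rows.append(
                    {
                        "participant_id": pid,
                        "scale": scale.name,
                        "time_point": tp,
                        "score": result.score,
                        "complete": result.complete,
                    }
                )
    return pd.DataFrame(rows)


def validate_scale_table(
    participants: pd.DataFrame,
    scales: Mapping[str, ScaleDefinition] | None = None,
    time_points: Iterable[str] = TIME_POINTS,
) -> pd.DataFrame:
    """Per scale and time point, count complete, partially missing and
    out-of-range records.  Reporting only; never raises on bad data."""
    scales = DEFAULT_SCALES if scales is None else scales
    rows = []
    for scale in scales.values():
        for tp in time_points:
            cols = scale.item_columns(tp)
            block = participants[cols]
            missing = block.isna()
            numeric = block.apply(pd.to_numeric, errors="coerce")
            out_of_range = (
                (~missing)
                & (
                    numeric.isna()
                    | (numeric < scale.level_min)
                    | (numeric > scale.level_max)
                    | (numeric != numeric.round())
                )
            )
            any_out = out_of_range.any(axis=1)
            any_missing = missing.any(axis=1) & ~any_out
            complete = ~missing.any(axis=1) & ~any_out
            rows.append(
                {
                    "scale": scale.name,
                    "time_point": tp,
                    "n_complete": int(complete.sum()),
                    "n_partial_missing": int(any_missing.sum()),
                    "n_out_of_range": int(any_out.sum()),
                }
            )
    return pd.DataFrame(rows)
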