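"""Therapist questionnaire scoring and progress labelling.

A 74-item instrument covers ten developmental areas. Item ratings on small
integer scales are rescaled to [0, 100]; the unweighted mean of an area's
items is that area's evaluation. Progress between two sessions of the same
child is declared for an area exactly when its evaluation strictly
increased.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

AREAS: tuple[str, ...] = (
    "communication",
    "fine_motor",
    "gross_motor",
    "following_instructions",
    "self_reliance",
    "social_emotional",
    "stereotypical",
    "stimulation_reaction",
    "attention",
    "challenging",
)

#: Items per area in the default 74-item instrument (one item per evaluated
#: element; the counts sum to 74).
DEFAULT_ITEM_COUNTS: dict[str, int] = {
    "communication": 14,
    "fine_motor": 8,
    "gross_motor": 9,
    "following_instructions": 2,
    "self_reliance": 6,
    "social_emotional": 9,
    "stereotypical": 5,
    "stimulation_reaction": 6,
    "attention": 5,
    "challenging": 10,
}

PROGRESS = "progress"
NO_PROGRESS = "no_progress"


@dataclass(frozen=True)
class QuestionnaireItem:
    item_id: str
    area: str
    scale_min: int = 1
    scale_max: int = 5
    description: str = ""

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r}")
        if self.scale_max <= self.scale_min:
            raise ValueError("scale_max must exceed scale_min")


@dataclass(frozen=True)
class Instrument:
    """The full questionnaire: an ordered collection of items."""

    items: tuple[QuestionnaireItem, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in instrument")

    def __len__(self) -> int:
        return len(self.items)

    def item(self, item_id: str) -> QuestionnaireItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def items_for_area(self, area: str) -> list[QuestionnaireItem]:
        return [it for it in self.items if it.area == area]


@dataclass
class QuestionnaireResponse:
    child_id: str
    session_index: int
    ratings: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class AreaScores:
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AREAS) - set(self.scores)
        if missing:
            raise ValueError(f"missing areas: {sorted(missing)}")

    def __getitem__(self, area: str) -> float:
        return self.scores[area]


@dataclass(frozen=True)
class ProgressLabel:
    area: str
    label: str
    from_session: int
    to_session: int

    def __post_init__(self) -> None:
        if self.to_session <= self.from_session:
            raise ValueError("to_session must exceed from_session")
        if self.label not in (PROGRESS, NO_PROGRESS):
            raise ValueError(f"bad label {self.label!r}")


def default_instrument(scale_min: int = 1, scale_max: int = 5) -> Instrument:
    """The shipped 74-item instrument: per-area item counts as published,
    uniform integer rating scales (default 1-5)."""
    items = []
    for area in AREAS:
        for k in range(1, DEFAULT_ITEM_COUNTS[area] + 1):
            items.append(
                QuestionnaireItem(
                    item_id=f"{area}_{k:02d}",
                    area=area,
                    scale_min=scale_min,
                    scale_max=scale_max,
                )
            )
    return Instrument(items=tuple(items))


def scale_rating(rating: float, scale_min: int, scale_max: int) -> float:
    """Rescale an item rating linearly onto [0, 100]."""
    if scale_max <= scale_min:
        raise ValueError("scale_max must exceed scale_min")
    if not scale_min <= rating <= scale_max:
        raise ValueError(f"rating {rating} outside [{scale_min}, {scale_max}]")
    return 100.0 * (rating - scale_min) / (scale_max - scale_min)


def area_scores(response: QuestionnaireResponse, instrument: Instrument) -> AreaScores:
    """Score a response: per area, the unweighted mean of scaled ratings."""
    scores: dict[str, float] = {}
    for area in AREAS:
        vals = []
        for it in instrument.items_for_area(area):
            if it.item_id in response.ratings:
                vals.append(
                    scale_rating(response.ratings[it.item_id], it.scale_min, it.scale_max)
                )
        if not vals:
            raise ValueError(f"area {area!r} has no rated items")
        scores[area] = sum(vals) / len(vals)
    return AreaScores(scores=scores)


def progress_label(
    score_from: float,
    score_to: float,
    area: str,
    from_session: int = 1,
    to_session: int = 2,
) -> ProgressLabel:
    """Binary label: progress iff the area score strictly increased."""
    label = PROGRESS if score_to > score_from else NO_PROGRESS
    return ProgressLabel(
        area=area, label=label, from_session=from_session, to_session=to_session
    )


# ---------------------------------------------------------------------------
# CSV interchange

def write_instrument(instrument: Instrument, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["item_id", "area", "scale_min", "scale_max", "description"])
        for it in instrument.items:
            w.writerow([it.item_id, it.area, it.scale_min, it.scale_max, it.description])


def read_instrument(path: str | Path) -> Instrument:
    items = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            items.append(
                QuestionnaireItem(
                    item_id=row["item_id"],
                    area=row["area"],
                    scale_min=int(row["scale_min"]),
                    scale_max=int(row["scale_max"]),
                    description=row.get("description", ""),
                )
            )
    return Instrument(items=tuple(items))


def write_responses(responses: Iterable[QuestionnaireResponse], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["child_id", "session_index", "item_id", "rating"])
        for r in responses:
            for item_id in sorted(r.ratings):
                w.writerow([r.child_id, r.session_index, item_id, r.ratings[item_id]])


def read_responses(path: str | Path) -> list[QuestionnaireResponse]:
    by_key: dict[tuple[str, int], QuestionnaireResponse] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["child_id"], int(row["session_index"]))
            resp = by_key.setdefault(
                key, QuestionnaireResponse(child_id=key[0], session_index=key[1])
            )
            resp.ratings[row["item_id"]] = int(row["rating"])
    return list(by_key.values())
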