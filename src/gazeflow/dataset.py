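"""Core record types: fixations, scanpaths, stimulus layouts, study datasets.

Coordinates are screen pixels with the origin at the top-left corner and y
increasing downward. All rectangles are half-open, ``[x0, x1) x [y0, y1)``,
so every in-bounds point belongs to exactly one cell of a tiling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import IntegrityError, LayoutValidationError


class Condition(str, enum.Enum):
    """Trial condition: stimulus shown with or without a clinical history."""

    HISTORY = "history"
    NO_HISTORY = "no_history"


class OrderGroup(str, enum.Enum):
    """Counterbalancing arm: whether the history condition came first."""

    HISTORY_FIRST = "history_first"
    HISTORY_LAST = "history_last"


@dataclass(frozen=True)
class Rect:
    """Axis-aligned half-open rectangle ``[x0, x1) x [y0, y1)``."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise LayoutValidationError(
                f"degenerate rectangle ({self.x0}, {self.y0}, {self.x1}, {self.y1})"
            )

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return (self.x0 + self.width / 2.0, self.y0 + self.height / 2.0)

    def intersects(self, other: "Rect") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )


@dataclass(frozen=True)
class Fixation:
    """A single fixation event, the atomic unit of the analysis.

    Parameters
    ----------
    participant_id, stimulus_id : str
        Opaque identifiers.
    condition : Condition
        Whether the trial presented the clinical history.
    index : int
        1-based ordinal of the fixation within its trial.
    x, y : float
        Screen coordinates in pixels (origin top-left).
    duration : float
        Fixation duration in milliseconds; strictly positive.
    onset : float
        Milliseconds from trial start.
    """

    participant_id: str
    stimulus_id: str
    condition: Condition
    index: int
    x: float
    y: float
    duration: float
    onset: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise IntegrityError(
                f"fixation duration must be positive, got {self.duration}"
            )
        if self.index < 1:
            raise IntegrityError(f"fixation index must be >= 1, got {self.index}")

    @property
    def trial_key(self) -> tuple[str, str, Condition]:
        return (self.participant_id, self.stimulus_id, self.condition)


@dataclass(frozen=True)
class Scanpath:
    """Ordered fixations of one participant on one stimulus in one condition."""

    participant_id: str
    stimulus_id: str
    condition: Condition
    fixations: tuple[Fixation, ...]

    def __post_init__(self) -> None:
        if not self.fixations:
            raise IntegrityError("scanpath must contain at least one fixation")
        key = (self.participant_id, self.stimulus_id, self.condition)
        prev: Fixation | None = None
        for fx in self.fixations:
            if fx.trial_key != key:
                raise IntegrityError(
                    f"fixation trial key {fx.trial_key} does not match scanpath {key}"
                )
            if prev is not None:
                if fx.index <= prev.index:
                    raise IntegrityError(
                        f"fixation indices not strictly increasing in trial {key}: "
                        f"{prev.index} followed by {fx.index}"
                    )
                if fx.onset < prev.onset:
                    raise IntegrityError(
                        f"fixation onsets decrease while indices increase in trial "
                        f"{key}: onset {prev.onset} -> {fx.onset}"
                    )
            prev = fx

    @property
    def trial_key(self) -> tuple[str, str, Condition]:
        return (self.participant_id, self.stimulus_id, self.condition)

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self) -> Iterator[Fixation]:
        return iter(self.fixations)

    def points(self) -> list[tuple[float, float]]:
        return [(fx.x, fx.y) for fx in self.fixations]


@dataclass(frozen=True)
class StimulusLayout:
    """Stimulus canvas with named lead rectangles.

    Overlapping lead rectangles are tolerated (a warning is left to the
    reader); regions extending past the canvas are rejected.
    """

    stimulus_id: str
    width: float
    height: float
    lead_regions: Mapping[str, Rect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise LayoutValidationError("canvas dimensions must be positive")
        for name, rect in self.lead_regions.items():
            if not (
                0 <= rect.x0
                and rect.x1 <= self.width
                and 0 <= rect.y0
                and rect.y1 <= self.height
            ):
                raise LayoutValidationError(
                    f"region {name!r} extends outside the "
                    f"{self.width}x{self.height} canvas"
                )

    def overlapping_pairs(self) -> list[tuple[str, str]]:
        names = list(self.lead_regions)
        out = []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self.lead_regions[a].intersects(self.lead_regions[b]):
                    out.append((a, b))
        return out

    def in_bounds(self, x: float, y: float) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height


@dataclass(frozen=True)
class StudyDataset:
    """A full study: scanpaths, per-trial responses, participant order groups.

    Invariants: at most one scanpath per (participant, stimulus, condition)
    trial; every participant carries exactly one order-group label.
    """

    scanpaths: tuple[Scanpath, ...]
    responses: Mapping[tuple[str, str, Condition], str] = field(default_factory=dict)
    order_groups: Mapping[str, OrderGroup] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, Condition]] = set()
        for sp in self.scanpaths:
            if sp.trial_key in seen:
                raise IntegrityError(f"duplicate scanpath for trial {sp.trial_key}")
            seen.add(sp.trial_key)
        for pid in self.participants():
            if pid not in self.order_groups:
                raise IntegrityError(f"participant {pid!r} has no order-group label")

    def participants(self) -> list[str]:
        return sorted({sp.participant_id for sp in self.scanpaths})

    def stimuli(self) -> list[str]:
        return sorted({sp.stimulus_id for sp in self.scanpaths})

    def n_fixations(self) -> int:
        return sum(len(sp) for sp in self.scanpaths)

    def select(
        self,
        stimulus_id: str | None = None,
        condition: Condition | None = None,
        participant_id: str | None = None,
    ) -> list[Scanpath]:
        """Scanpaths matching all given filters, in stored order."""
        out = []
        for sp in self.scanpaths:
            if stimulus_id is not None and sp.stimulus_id != stimulus_id:
                continue
            if condition is not None and sp.condition != condition:
                continue
            if participant_id is not None and sp.participant_id != participant_id:
                continue
            out.append(sp)
        return out

    def iter_fixations(self) -> Iterable[Fixation]:
        for sp in self.scanpaths:
            yield from sp.fixations
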