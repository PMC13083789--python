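"""Sort-window selection: track the RPI across stage-6 differentiation.

During stage 6 the alpha/polyhormonal and beta populations progressively
segregate on CD133, so the RPI falls over the window and the best day to
sort is where it is lowest.  Two criteria are offered: ``argmin`` (earliest
day attaining the minimum — the default) and ``first_below`` (earliest day
under a user threshold, useful when sorting earlier shortens culture and a
"good enough" separation suffices).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .events import CellClass, EventTable
from .population import RPIResult, rpi_from_table

__all__ = ["TimeCourseRPI", "compute_timecourse", "select_sort_window"]


@dataclass(frozen=True)
class TimeCourseRPI:
    """Ordered (stage-6 day, RPI) sequence."""

    points: tuple[tuple[int, RPIResult], ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("a time course needs at least one point")
        days = [d for d, _ in self.points]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"timepoints must be strictly increasing, got {days}")

    @property
    def days(self) -> list[int]:
        return [d for d, _ in self.points]

    @property
    def values(self) -> list[float]:
        return [r.value for _, r in self.points]


def compute_timecourse(
    tables: Sequence[EventTable],
    channel: str,
    alpha_class: "CellClass | str" = CellClass.ALPHA_POLY,
    beta_class: "CellClass | str" = CellClass.BETA,
) -> TimeCourseRPI:
    """One RPI per table, sorted by stage-6 day; input order is irrelevant."""
    points = []
    seen: set[int] = set()
    for i, table in enumerate(tables):
        if table.timepoint is None:
            raise ValueError(f"table {i} has no timepoint")
        if table.labels is None:
            raise ValueError(f"table {i} (day {table.timepoint}) has no labels")
        if table.timepoint in seen:
            raise ValueError(f"duplicate timepoint {table.timepoint}")
        seen.add(table.timepoint)
        points.append(
            (table.timepoint, rpi_from_table(table, channel, alpha_class, beta_class))
        )
    points.sort(key=lambda p: p[0])
    return TimeCourseRPI(points=tuple(points))


def select_sort_window(
    course: TimeCourseRPI,
    criterion: Literal["argmin", "first_below"] = "argmin",
    threshold: float | None = None,
) -> int | None:
    """Pick the sorting day from an RPI time course.

    ``argmin`` returns the earliest day attaining the minimum index (ties
    break to the earlier day: shorter culture).  ``first_below`` returns the
    earliest day with index strictly below ``threshold``, or ``None`` when
    no day qualifies — a no-window outcome, not an error.
    """
    if criterion == "argmin":
        best_day, best = course.points[0][0], course.points[0][1].value
        for day, r in course.points[1:]:
            if r.value < best:
                best_day, best = day, r.value
        return best_day
    if criterion == "first_below":
        if threshold is None:
            raise ValueError("first_below requires a threshold")
        if not (0.0 <= threshold <= 1.0):
            raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
        for day, r in course.points:
            if r.value < threshold:
                return day
        return None
    raise ValueError(f"unknown criterion {criterion!r}")
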