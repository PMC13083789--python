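"""In-silico cell sorting: gates, composition, purity, yield, enrichment.

Three gate kinds cover the sorting strategies used on SC-islets:

``top_fraction``
    Rank-based selection of the brightest fixed fraction of events on one
    channel (the CD133-high sort uses fraction 0.20).  Selection is by
    rank, not by cutoff, so exactly ``ceil(fraction * n)`` events survive;
    ties break by descending intensity then original event order.
``threshold``
    Fixed intensity cutoff, keeping events above (``>=``) or below (``<``).
``positive_split``
    Automatic positive/negative split for markers with a clearly bimodal
    distribution (CD49a): events are split at the largest gap in sorted
    log10 intensity, the two cluster centers are the mean log10 intensity
    on each side, and the threshold is the midpoint of the centers; events
    at or above it are kept.  A manual ``cutoff`` (linear scale) overrides
    the heuristic.

Sequential gating applies gates left to right with daughter-gate
semantics: a ``top_fraction`` applies to the events surviving the previous
gates, as on a sorter.  The dual beta-cell sort is
``[positive_split on CD49a, top_fraction 0.20 on CD133]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .events import CELL_CLASSES, CellClass, EventTable

__all__ = [
    "GateSpec",
    "Composition",
    "SortOutcome",
    "dual_sort_gates",
    "top_fraction_threshold",
    "apply_gate",
    "apply_sequential",
    "composition",
    "sort_outcome",
]


@dataclass(frozen=True)
class GateSpec:
    """Declarative single-channel gate; composable sequentially."""

    channel: str
    kind: Literal["top_fraction", "threshold", "positive_split"]
    fraction: float | None = None
    cutoff: float | None = None
    direction: Literal["above", "below"] = "above"

    def __post_init__(self) -> None:
        if self.kind == "top_fraction":
            if self.fraction is None or not (0.0 < self.fraction <= 1.0):
                raise ConfigurationError(
                    f"top_fraction gate needs fraction in (0, 1], got {self.fraction}"
                )
            if self.cutoff is not None:
                raise ConfigurationError("top_fraction gate takes no cutoff")
        elif self.kind == "threshold":
            if self.cutoff is None:
                raise ConfigurationError("threshold gate needs a cutoff")
            if self.fraction is not None:
                raise ConfigurationError("threshold gate takes no fraction")
        elif self.kind == "positive_split":
            if self.fraction is not None:
                raise ConfigurationError("positive_split gate takes no fraction")
            # cutoff optional: manual override of the largest-gap heuristic
        else:
            raise ConfigurationError(f"unknown gate kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "top_fraction":
            return f"top_fraction({self.channel}, fraction={self.fraction})"
        if self.kind == "threshold":
            return f"threshold({self.channel}, {self.direction} {self.cutoff})"
        if self.cutoff is not None:
            return f"positive_split({self.channel}, cutoff={self.cutoff})"
        return f"positive_split({self.channel})"

    def to_dict(self) -> dict:
        d: dict = {"channel": self.channel, "kind": self.kind}
        if self.fraction is not None:
            d["fraction"] = self.fraction
        if self.cutoff is not None:
            d["cutoff"] = self.cutoff
        if self.kind == "threshold":
            d["direction"] = self.direction
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GateSpec":
        return cls(
            channel=d["channel"],
            kind=d["kind"],
            fraction=d.get("fraction"),
            cutoff=d.get("cutoff"),
            direction=d.get("direction", "above"),
        )


def dual_sort_gates(
    cd133_fraction: float = 0.20,
    cd49a_channel: str = "CD49a",
    cd133_channel: str = "CD133",
) -> list[GateSpec]:
    """The dual beta-cell sort: CD49a-positive, then CD133 top fraction."""
    return [
        GateSpec(channel=cd49a_channel, kind="positive_split"),
        GateSpec(channel=cd133_channel, kind="top_fraction", fraction=cd133_fraction),
    ]


# ---------------------------------------------------------------------------
# Gate mechanics
# ---------------------------------------------------------------------------

def _top_fraction_order(intensities: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the ceil(fraction*n) brightest events, ties broken by
    descending intensity then original order (stable sort)."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("top-fraction selection needs at least one event")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    k = math.ceil(fraction * x.size)
    return np.argsort(-x, kind="stable")[:k]


def top_fraction_threshold(intensities, fraction: float) -> float:
    """Intensity of the ceil(fraction*n)-th largest event.

    Downstream selection is rank-based (exact count), so this cutoff is
    informational — the value a sorter operator would dial in.
    """
    x = np.asarray(intensities, dtype=float)
    order = _top_fraction_order(x, fraction)
    return float(x[order[-1]])


def positive_split_cutoff(intensities) -> float:
    """Largest-gap split threshold on the linear scale.

    Splits sorted log10 intensities at the largest consecutive gap, takes
    the mean log10 intensity of each side as the cluster centers, and
    returns ``10**midpoint`` of the centers.  With fewer than two events,
    or all values identical, the single value itself is returned (every
    event counts as positive).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("positive_split needs at least one event")
    logx = np.sort(np.log10(x))
    if logx.size < 2 or logx[0] == logx[-1]:
        return float(x.min())  # all positive: everything counts as positive
    gaps = np.diff(logx)
    i = int(np.argmax(gaps))  # ties: earliest (lowest) gap
    lo_center = float(np.mean(logx[: i + 1]))
    hi_center = float(np.mean(logx[i + 1 :]))
    return float(10.0 ** ((lo_center + hi_center) / 2.0))


def apply_gate(table: EventTable, gate: GateSpec) -> EventTable:
    """Sub-table of events passing one gate, provenance appended.

    Labels, timepoint and event identities are preserved; the gate
    description is appended to ``metadata["gates"]``.
    """
    x = table.channel_values(gate.channel)  # raises KeyError on unknown channel
    if gate.kind == "top_fraction":
        if table.n_events == 0:
            index = np.zeros(0, dtype=np.int64)
        else:
            index = np.sort(_top_fraction_order(x, gate.fraction))
    elif gate.kind == "threshold":
        index = (x >= gate.cutoff) if gate.direction == "above" else (x < gate.cutoff)
    else:  # positive_split
        if table.n_events == 0:
            index = np.zeros(0, dtype=np.int64)
        else:
            cutoff = gate.cutoff if gate.cutoff is not None else positive_split_cutoff(x)
            index = x >= cutoff
    gates = list(table.metadata.get("gates", [])) + [gate.describe()]
    return table.select(index, metadata={"gates": gates})


def apply_sequential(table: EventTable, gates: Sequence[GateSpec]) -> EventTable:
    """Gates applied left to right with daughter-gate (conditional) semantics.

    An empty intermediate table short-circuits to an empty result.
    """
    if not gates:
        raise ValueError("apply_sequential needs at least one gate")
    out = table
    for gate in gates:
        out = apply_gate(out, gate)
    return out


# ---------------------------------------------------------------------------
# Composition accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Composition:
    """Class fractions of a labeled event table.

    ``fractions`` is ``None`` for an empty table (undefined rather than
    zero, so downstream code must handle the degenerate case explicitly).
    """

    n: int
    fractions: Mapping[CellClass, float] | None

    def __post_init__(self) -> None:
        if self.n > 0:
            if self.fractions is None:
                raise ValueError("non-empty composition needs fractions")
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fractions must sum to 1, got {total}")
        elif self.fractions is not None:
            raise ValueError("empty composition must have fractions=None")

    def fraction(self, cell_class: CellClass) -> float:
        if self.fractions is None:
            raise ValueError("composition of an empty table is undefined")
        return float(self.fractions.get(cell_class, 0.0))


@dataclass(frozen=True)
class SortOutcome:
    """Pre/post compositions with yield and per-class enrichment folds.

    ``enrichment[c]`` is post fraction / pre fraction; ``None`` flags the
    undefined fold of a class absent before sorting.
    """

    pre: Composition
    post: Composition
    yield_fraction: float
    enrichment: Mapping[CellClass, float | None]

    def __post_init__(self) -> None:
        if not (0.0 <= self.yield_fraction <= 1.0):
            raise ValueError("yield_fraction must lie in [0, 1]")


def composition(table: EventTable) -> Composition:
    """Ground-truth class fractions of a labeled table."""
    if table.labels is None:
        raise ValueError("composition requires a labeled table")
    n = table.n_events
    if n == 0:
        return Composition(n=0, fractions=None)
    fractions = {
        cls: float(np.count_nonzero(table.labels == cls.value)) / n
        for cls in CELL_CLASSES
    }
    return Composition(n=n, fractions=fractions)


def sort_outcome(pre_table: EventTable, post_table: EventTable) -> SortOutcome:
    """Account a sort: compositions, yield, per-class enrichment folds.

    ``post_table`` must be a subset of ``pre_table`` (checked on event ids).
    """
    post_ids = set(post_table.event_id.tolist())
    pre_ids = set(pre_table.event_id.tolist())
    if not post_ids <= pre_ids:
        raise ValueError("post table is not a subset of the pre table")
    pre = composition(pre_table)
    post = composition(post_table)
    yield_fraction = post.n / pre.n if pre.n else 0.0
    enrichment: dict[CellClass, float | None] = {}
    for cls in CELL_CLASSES:
        pre_f = pre.fraction(cls) if pre.fractions is not None else 0.0
        if pre_f == 0.0 or post.fractions is None:
            enrichment[cls] = None
        else:
            enrichment[cls] = post.fraction(cls) / pre_f
    return SortOutcome(
        pre=pre, post=post, yield_fraction=float(yield_fraction), enrichment=enrichment
    )
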