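"""Event-level cytometry data: cell classes and the event table.

The :class:`EventTable` is the universal currency of the pipeline: one row
per cell (event), one column per fluorescence channel, values on the linear
intensity scale (arbitrary fluorescence units, strictly positive).  Tables
may carry ground-truth class labels (available when events were simulated,
or when an orthogonal staining panel classified them) and the stage-6
differentiation day they were acquired on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class CellClass(str, enum.Enum):
    """Mutually exclusive cell identities in an SC-islet preparation.

    ``beta``        INS+NKX6.1+ beta cells.
    ``alpha_poly``  GCG+ alpha cells plus GCG+INS+ polyhormonal cells
                    (lacking NKX6.1), treated as one off-target class.
    ``delta``       somatostatin-positive delta cells.
    ``ec_like``     serotonin-positive enterochromaffin-like cells.
    ``ductal``      CFTR/SOX9-expressing ductal-like cells.
    ``progenitor``  NKX6.1+NEUROG3+ endocrine progenitors.
    ``other``       everything else.
    """

    BETA = "beta"
    ALPHA_POLY = "alpha_poly"
    DELTA = "delta"
    EC_LIKE = "ec_like"
    DUCTAL = "ductal"
    PROGENITOR = "progenitor"
    OTHER = "other"


CELL_CLASSES: tuple[CellClass, ...] = tuple(CellClass)
CLASS_NAMES: tuple[str, ...] = tuple(c.value for c in CellClass)

#: Canonical channel order for SC-islet panels.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "CD133",
    "CD49a",
    "INS",
    "NKX6.1",
    "GCG",
    "NEUROG3",
    "SST",
    "SEROTONIN",
    "CFTR",
)


def as_cell_class(value: "CellClass | str") -> CellClass:
    """Coerce a string label to :class:`CellClass`, validating it."""
    if isinstance(value, CellClass):
        return value
    try:
        return CellClass(value)
    except ValueError:
        raise ValueError(
            f"unknown cell class {value!r}; expected one of {CLASS_NAMES}"
        ) from None


@dataclass
class EventTable:
    """Per-event intensity matrix with optional ground-truth labels.

    Parameters
    ----------
    channels
        Ordered channel names; one per intensity column.
    intensities
        ``(n_events, n_channels)`` array of strictly positive linear-scale
        fluorescence values.
    labels
        Optional per-event class labels (strings from :class:`CellClass`).
    timepoint
        Optional stage-6 day the events were acquired on.
    metadata
        Free-form provenance (simulation seed, gates applied, source file).
    event_id
        Stable integer identity per event, assigned at creation and
        preserved through gating; enables subset checks on sort outcomes.
    """

    channels: list[str]
    intensities: np.ndarray
    labels: np.ndarray | None = None
    timepoint: int | None = None
    metadata: dict = field(default_factory=dict)
    event_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            if self.intensities.size == 0:
                self.intensities = self.intensities.reshape(0, len(self.channels))
            else:
                raise ValueError("intensities must be a 2-D array")
        n, c = self.intensities.shape
        if c != len(self.channels):
            raise ValueError(
                f"intensities has {c} columns but {len(self.channels)} channels given"
            )
        if n and not np.all(self.intensities > 0):
            bad = int(np.argwhere(~(self.intensities > 0))[0][0])
            raise ValueError(
                f"intensities must be strictly positive; event row {bad} violates this"
            )
        if self.labels is not None:
            self.labels = np.asarray(
                [as_cell_class(l).value for l in np.asarray(self.labels).ravel()],
                dtype=object,
            )
            if self.labels.shape[0] != n:
                raise ValueError(
                    f"labels has length {self.labels.shape[0]} but table has {n} events"
                )
        if self.event_id is None:
            self.event_id = np.arange(n, dtype=np.int64)
        else:
            self.event_id = np.asarray(self.event_id, dtype=np.int64)
            if self.event_id.shape[0] != n:
                raise ValueError("event_id length does not match number of events")

    # -- basic accessors -------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]

    def __len__(self) -> int:
        return self.n_events

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in table (has {self.channels})"
            ) from None

    def channel_values(self, channel: str) -> np.ndarray:
        """Intensity vector of one channel (view)."""
        return self.intensities[:, self.channel_index(channel)]

    def class_mask(self, cell_class: "CellClass | str") -> np.ndarray:
        if self.labels is None:
            raise ValueError("table has no ground-truth labels")
        return self.labels == as_cell_class(cell_class).value

    # -- derived tables --------------------------------------------------
    def select(self, index: np.ndarray, metadata: Mapping | None = None) -> "EventTable":
        """Sub-table of the events picked by boolean mask or integer index.

        Labels, timepoint and event identities are carried over; metadata is
        copied (optionally updated) so provenance accumulates per gate.
        """
        index = np.asarray(index)
        meta = dict(self.metadata)
        if metadata:
            meta.update(metadata)
        return EventTable(
            channels=self.channels,
            intensities=self.intensities[index],
            labels=None if self.labels is None else self.labels[index],
            timepoint=self.timepoint,
            metadata=meta,
            event_id=self.event_id[index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view: event_id, label, timepoint, then one column per channel."""
        df = pd.DataFrame(self.intensities, columns=self.channels)
        df.insert(0, "timepoint", self.timepoint)
        df.insert(0, "label", self.labels if self.labels is not None else None)
        df.insert(0, "event_id", self.event_id)
        return df

    def equals(self, other: "EventTable", rtol: float = 0.0) -> bool:
        """Structural equality, with optional relative tolerance on intensities."""
        if self.channels != other.channels or self.n_events != other.n_events:
            return False
        if self.timepoint != other.timepoint:
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        if self.labels is not None and not np.array_equal(self.labels, other.labels):
            return False
        if not np.array_equal(self.event_id, other.event_id):
            return False
        if rtol == 0.0:
            return bool(np.array_equal(self.intensities, other.intensities))
        return bool(np.allclose(self.intensities, other.intensities, rtol=rtol, atol=0.0))
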