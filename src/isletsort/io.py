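"""Reading and writing event tables, gating reports and configs.

CSV is the canonical interchange format: UTF-8, comma-separated, header
``event_id,label,timepoint,<channel...>``, intensities serialized with 9
significant digits, deterministic row order (byte-identical output for
identical input).  FCS 3.0/3.1 list-mode files can be read (not written);
see :mod:`isletsort._fcs` for the supported subset.  Reports are written
as JSON (canonical machine format, fixed key order) or TSV (one row per
class, convenient for spreadsheets).  Compositions are serialized as
fractions in [0, 1], never percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._fcs import read_fcs
from .errors import FormatError
from .events import CELL_CLASSES, CLASS_NAMES, CellClass, EventTable
from .gating import Composition, GateSpec, SortOutcome

__all__ = ["GatingReport", "read_events", "write_events", "write_report"]

_FLOAT_FMT = ".9g"


@dataclass(frozen=True)
class GatingReport:
    """Before/after accounting of one gating run."""

    gates_applied: tuple[str, ...]
    n_in: int
    n_out: int
    composition_in: Composition
    composition_out: Composition
    enrichment: Mapping[CellClass, float | None]

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError("n_out cannot exceed n_in")

    @classmethod
    def from_outcome(
        cls, outcome: SortOutcome, gates: Sequence["GateSpec | str"]
    ) -> "GatingReport":
        descriptions = tuple(
            g.describe() if isinstance(g, GateSpec) else str(g) for g in gates
        )
        return cls(
            gates_applied=descriptions,
            n_in=outcome.pre.n,
            n_out=outcome.post.n,
            composition_in=outcome.pre,
            composition_out=outcome.post,
            enrichment=outcome.enrichment,
        )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def write_events(table: EventTable, path) -> None:
    """Write an event table as canonical CSV (header always present)."""
    lines = ["event_id,label,timepoint," + ",".join(table.channels)]
    tp = "" if table.timepoint is None else str(int(table.timepoint))
    for i in range(table.n_events):
        label = "" if table.labels is None else table.labels[i]
        values = ",".join(format(v, _FLOAT_FMT) for v in table.intensities[i])
        lines.append(f"{int(table.event_id[i])},{label},{tp},{values}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_events_csv(path) -> EventTable:
    try:
        df = pd.read_csv(path, dtype={"label": "string"})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"malformed CSV {path}: {exc}") from None
    required = ["event_id", "label", "timepoint"]
    if list(df.columns[:3]) != required or df.shape[1] < 4:
        raise FormatError(
            f"malformed header in {path}: expected 'event_id,label,timepoint,"
            f"<channels...>', got {list(df.columns)}"
        )
    channels = list(df.columns[3:])
    intensities = df[channels].to_numpy(dtype=float)
    if intensities.size and not np.all(intensities > 0):
        row = int(np.argwhere(~(intensities > 0))[0][0])
        raise FormatError(
            f"non-positive intensity in {path} at data row {row} "
            f"(event_id {df['event_id'].iloc[row]})"
        )
    labels = None
    raw_labels = df["label"]
    if raw_labels.notna().any():
        if raw_labels.isna().any():
            row = int(raw_labels.isna().idxmax())
            raise FormatError(f"missing label at data row {row} in {path}")
        bad = ~raw_labels.isin(CLASS_NAMES)
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(
                f"unknown label {raw_labels.iloc[row]!r} at data row {row} in "
                f"{path}; expected one of {CLASS_NAMES}"
            )
        labels = raw_labels.to_numpy(dtype=object)
    timepoint = None
    if df["timepoint"].notna().any():
        unique = df["timepoint"].dropna().unique()
        if len(unique) > 1:
            raise FormatError(f"multiple timepoints in one table: {sorted(unique)}")
        timepoint = int(unique[0])
    return EventTable(
        channels=channels,
        intensities=intensities,
        labels=labels,
        timepoint=timepoint,
        metadata={"source": str(path), "format": "csv"},
        event_id=df["event_id"].to_numpy(dtype=np.int64),
    )


def _read_events_fcs(path) -> EventTable:
    names, events, keywords = read_fcs(path)
    if events.size and not np.all(events > 0):
        row = int(np.argwhere(~(events > 0))[0][0])
        raise FormatError(f"non-positive intensity in {path} at event {row}")
    return EventTable(
        channels=names,
        intensities=events,
        labels=None,
        timepoint=None,
        metadata={"source": str(path), "format": "fcs",
                  "fcs_version": keywords.get("FCS_VERSION", "")},
    )


def read_events(path, format: str = "csv") -> EventTable:
    """Read an event table from ``csv`` (canonical) or ``fcs`` (read-only)."""
    if format == "csv":
        return _read_events_csv(path)
    if format == "fcs":
        return _read_events_fcs(path)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'fcs'")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _composition_payload(comp: Composition) -> dict | None:
    if comp.fractions is None:
        return None
    return {cls.value: round(comp.fraction(cls), 12) for cls in CELL_CLASSES}


def write_report(report: GatingReport, path, format: str = "json") -> None:
    """Serialize a gating report as JSON (canonical) or TSV."""
    if format == "json":
        payload = {
            "gates_applied": list(report.gates_applied),
            "n_in": report.n_in,
            "n_out": report.n_out,
            "composition_in": _composition_payload(report.composition_in),
            "composition_out": _composition_payload(report.composition_out),
            "enrichment": {
                cls.value: report.enrichment.get(cls) for cls in CELL_CLASSES
            },
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if format == "tsv":
        lines = ["cell_class\tfraction_in\tfraction_out\tenrichment"]
        for cls in CELL_CLASSES:
            f_in = ("" if report.composition_in.fractions is None
                    else format_float(report.composition_in.fraction(cls)))
            f_out = ("" if report.composition_out.fractions is None
                     else format_float(report.composition_out.fraction(cls)))
            fold = report.enrichment.get(cls)
            lines.append(
                f"{cls.value}\t{f_in}\t{f_out}\t"
                f"{'' if fold is None else format_float(fold)}"
            )
        lines.append(f"# gates: {'; '.join(report.gates_applied)}")
        lines.append(f"# n_in: {report.n_in}\tn_out: {report.n_out}")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\n".join(lines) + "\n")
        return
    raise ValueError(f"unknown report format {format!r}; expected 'json' or 'tsv'")


def read_report(path) -> GatingReport:
    """Read back a JSON gating report."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)

    def _comp(d: dict | None, n: int) -> Composition:
        if d is None:
            return Composition(n=n, fractions=None)
        return Composition(n=n, fractions={CellClass(k): v for k, v in d.items()})

    return GatingReport(
        gates_applied=tuple(payload["gates_applied"]),
        n_in=payload["n_in"],
        n_out=payload["n_out"],
        composition_in=_comp(payload["composition_in"], payload["n_in"]),
        composition_out=_comp(payload["composition_out"], payload["n_out"]),
        enrichment={
            CellClass(k): v for k, v in payload["enrichment"].items()
        },
    )


def format_float(x: float) -> str:
    """Project-wide deterministic float formatting (9 significant digits)."""
    return format(x, _FLOAT_FMT)
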