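"""Synthetic SC-islet cytometry: log-normal class mixtures with stage-6 drift.

The generator emulates the statistical structure of end-of-differentiation
SC-islet flow data that the downstream analysis assumes:

* a seven-class mixture (beta, alpha/polyhormonal, delta, enterochromaffin-
  like, ductal-like, endocrine progenitor, other) with beta prevalence in
  the 20-30% band typical of current differentiation protocols;
* per-class, per-channel log-normal intensity distributions (flow
  intensities are positive and right-skewed; parameters live on the log10
  scale);
* CD133 high in beta and ductal-like cells (both polarized), lower in
  alpha/polyhormonal cells; CD49a high in all endocrine classes and absent
  from ductal-like, progenitor and other cells;
* a stage-6 time course in which the alpha-beta CD133 separation grows
  from day 0 (fully overlapping) to day 7 (clearly separated), so that the
  sort-timing analysis has a well-defined optimum at the final day.

Channels are independent given the class: the analysis downstream never
uses spectral compensation, so spillover is deliberately not modeled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .events import CELL_CLASSES, DEFAULT_CHANNELS, CellClass, EventTable, as_cell_class

__all__ = [
    "ChannelModel",
    "DriftFunction",
    "SimConfig",
    "default_sc_islet_config",
    "simulate_events",
    "simulate_timecourse",
]


@dataclass(frozen=True)
class ChannelModel:
    """Log-normal intensity model for one (class, channel) pair.

    ``location`` and ``scale`` are the mean and standard deviation of
    log10 intensity (arbitrary fluorescence units); linear intensities are
    ``10**x`` and therefore strictly positive.
    """

    channel: str
    location: float
    scale: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ConfigurationError(
                f"scale must be > 0 for channel {self.channel!r}, got {self.scale}"
            )


@dataclass(frozen=True)
class DriftFunction:
    """Additive log10-location shift of one (class, channel) over stage-6 days.

    Days without an explicit entry have offset 0, so every timepoint is
    covered by construction.
    """

    channel: str
    cell_class: CellClass
    offsets: Mapping[int, float]

    def offset(self, timepoint: int) -> float:
        return float(self.offsets.get(int(timepoint), 0.0))


@dataclass(frozen=True)
class SimConfig:
    """Full mixture specification: weights, channel models, drifts, seed."""

    weights: Mapping[CellClass, float]
    channel_models: Mapping[tuple[CellClass, str], ChannelModel]
    drifts: tuple[DriftFunction, ...] = ()
    seed: int = 0
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        w = np.array([float(self.weights.get(c, 0.0)) for c in CELL_CLASSES])
        if np.any(w < 0):
            raise ConfigurationError("mixture weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"mixture weights must sum to 1 (got {w.sum():.12f})"
            )

    def model_for(self, cell_class: CellClass, channel: str) -> ChannelModel:
        try:
            return self.channel_models[(cell_class, channel)]
        except KeyError:
            raise ConfigurationError(
                f"no ChannelModel for class {cell_class.value!r}, channel {channel!r}"
            ) from None

    def location_at(self, cell_class: CellClass, channel: str, timepoint: int) -> float:
        """Effective log10 location at a stage-6 day (base + drift offsets)."""
        loc = self.model_for(cell_class, channel).location
        for d in self.drifts:
            if d.cell_class is cell_class and d.channel == channel:
                loc += d.offset(timepoint)
        return loc

    # -- JSON round-trip (CLI config files) ------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "channels": list(self.channels),
            "weights": {c.value: float(self.weights.get(c, 0.0)) for c in CELL_CLASSES},
            "channel_models": [
                {
                    "cell_class": cls.value,
                    "channel": m.channel,
                    "location": m.location,
                    "scale": m.scale,
                }
                for (cls, _), m in sorted(
                    self.channel_models.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
                )
            ],
            "drifts": [
                {
                    "cell_class": d.cell_class.value,
                    "channel": d.channel,
                    "offsets": {str(k): v for k, v in sorted(d.offsets.items())},
                }
                for d in self.drifts
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        weights = {as_cell_class(k): float(v) for k, v in data["weights"].items()}
        models = {
            (as_cell_class(m["cell_class"]), m["channel"]): ChannelModel(
                m["channel"], float(m["location"]), float(m["scale"])
            )
            for m in data["channel_models"]
        }
        drifts = tuple(
            DriftFunction(
                d["channel"],
                as_cell_class(d["cell_class"]),
                {int(k): float(v) for k, v in d["offsets"].items()},
            )
            for d in data.get("drifts", ())
        )
        return cls(
            weights=weights,
            channel_models=models,
            drifts=drifts,
            seed=int(data.get("seed", 0)),
            channels=tuple(data.get("channels", DEFAULT_CHANNELS)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=False)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Default SC-islet configuration
# ---------------------------------------------------------------------------

#: Mixture weights at end of stage 6.  Beta sits at 0.25, the middle of the
#: 20-30% beta-cell band typical SC-islet protocols yield; the remaining
#: weights qualitatively match pre-sort composition panels (alpha/
#: polyhormonal comparable to beta, minor delta/EC fractions, ductal-like
#: cells present) and are calibration choices, not measured values.
DEFAULT_WEIGHTS: dict[CellClass, float] = {
    CellClass.BETA: 0.25,
    CellClass.ALPHA_POLY: 0.25,
    CellClass.DELTA: 0.05,
    CellClass.EC_LIKE: 0.05,
    CellClass.DUCTAL: 0.10,
    CellClass.PROGENITOR: 0.15,
    CellClass.OTHER: 0.15,
}

_ENDOCRINE = (CellClass.BETA, CellClass.ALPHA_POLY, CellClass.DELTA, CellClass.EC_LIKE)

# log10 locations. CD133 marks polarized cells (newly formed beta, ductal);
# CD49a marks endocrine cells and is absent from ductal epithelium. The
# remaining channels encode class identity (hormones / TFs) so that label-
# free classification is possible in principle but never needed here.
_CD133_LOC = {
    CellClass.BETA: 2.60,       # day-7 value; drift pulls it down at earlier days
    CellClass.DUCTAL: 2.60,
    CellClass.ALPHA_POLY: 2.15,
    CellClass.DELTA: 2.15,
    CellClass.EC_LIKE: 2.15,
    CellClass.PROGENITOR: 1.90,
    CellClass.OTHER: 1.90,
}
_CD133_SCALE = 0.25

_CD49A_HIGH, _CD49A_LOW, _CD49A_SCALE = 2.60, 1.00, 0.15

_IDENTITY_LOC: dict[str, dict[CellClass, float]] = {
    "INS": {CellClass.BETA: 2.80, CellClass.ALPHA_POLY: 2.00},
    "NKX6.1": {CellClass.BETA: 2.60, CellClass.PROGENITOR: 2.60},
    "GCG": {CellClass.ALPHA_POLY: 2.80},
    "NEUROG3": {c: 2.40 for c in (*_ENDOCRINE, CellClass.PROGENITOR)},
    "SST": {CellClass.DELTA: 2.80},
    "SEROTONIN": {CellClass.EC_LIKE: 2.80},
    "CFTR": {CellClass.DUCTAL: 2.60},
}
_BASE_LOC, _BASE_SCALE = 1.00, 0.20

#: Total downward shift of beta CD133 at day 0 relative to day 7 (log10).
#: Linear in day, so the alpha-beta separation strictly increases across
#: the stage-6 window and overlap resolves only near day 7.
_BETA_CD133_DRIFT_TOTAL = -0.60


def default_sc_islet_config(seed: int = 0) -> SimConfig:
    """The documented default SC-islet configuration.

    Encodes, as fixed defaults: beta prevalence 0.25 (inside the 20-30%
    band), CD133 higher in beta and ductal-like cells than in alpha/
    polyhormonal cells at day 7, CD49a present in endocrine and absent from
    non-endocrine classes, and a linear beta-CD133 drift that makes the
    alpha-beta separation strictly increase from day 0 to day 7.
    """
    models: dict[tuple[CellClass, str], ChannelModel] = {}
    for cls in CELL_CLASSES:
        for ch in DEFAULT_CHANNELS:
            if ch == "CD133":
                m = ChannelModel(ch, _CD133_LOC[cls], _CD133_SCALE)
            elif ch == "CD49a":
                loc = _CD49A_HIGH if cls in _ENDOCRINE else _CD49A_LOW
                m = ChannelModel(ch, loc, _CD49A_SCALE)
            else:
                loc = _IDENTITY_LOC.get(ch, {}).get(cls, _BASE_LOC)
                m = ChannelModel(ch, loc, _BASE_SCALE)
            models[(cls, ch)] = m

    drift = DriftFunction(
        channel="CD133",
        cell_class=CellClass.BETA,
        offsets={d: _BETA_CD133_DRIFT_TOTAL * (7 - d) / 7.0 for d in range(8)},
    )
    return SimConfig(
        weights=dict(DEFAULT_WEIGHTS),
        channel_models=models,
        drifts=(drift,),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def simulate_events(config: SimConfig, n: int, timepoint: int) -> EventTable:
    """Draw ``n`` events at one stage-6 day.

    Class labels come from a multinomial with ``config.weights``; each
    channel intensity is log-normal with the class's model, drift offset
    applied.  Deterministic given ``(config.seed, n, timepoint)``: the
    random stream is seeded from ``SeedSequence([config.seed, timepoint])``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    timepoint = int(timepoint)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), timepoint]))

    weights = np.array([float(config.weights.get(c, 0.0)) for c in CELL_CLASSES])
    class_idx = rng.choice(len(CELL_CLASSES), size=n, p=weights)
    labels = np.array([CELL_CLASSES[i].value for i in class_idx], dtype=object)

    log_intensities = np.empty((n, len(config.channels)), dtype=float)
    for j, ch in enumerate(config.channels):
        locs = np.empty(len(CELL_CLASSES))
        scales = np.empty(len(CELL_CLASSES))
        for i, cls in enumerate(CELL_CLASSES):
            if weights[i] == 0.0 and (cls, ch) not in config.channel_models:
                locs[i], scales[i] = np.nan, 1.0  # class never sampled
                continue
            m = config.model_for(cls, ch)
            locs[i] = config.location_at(cls, ch, timepoint)
            scales[i] = m.scale
        z = rng.standard_normal(n)
        log_intensities[:, j] = locs[class_idx] + scales[class_idx] * z

    return EventTable(
        channels=list(config.channels),
        intensities=10.0 ** log_intensities,
        labels=labels,
        timepoint=timepoint,
        metadata={"seed": int(config.seed), "n": int(n), "timepoint": timepoint},
    )


def day_seed(master_seed: int, day: int) -> int:
    """Child seed for one stage-6 day, derived so that adding or removing a
    day never perturbs the draws of other days.  Kept below 2**31."""
    return int(
        np.random.SeedSequence([int(master_seed), int(day)]).generate_state(1)[0]
        % (2**31)
    )


def simulate_timecourse(
    config: SimConfig, n_per_day: int, days: Sequence[int]
) -> list[EventTable]:
    """One independent, reproducible table per stage-6 day.

    Each day's table equals ``simulate_events`` run with the derived child
    seed (:func:`day_seed`), so the course is reproducible day by day.
    """
    days = [int(d) for d in days]
    if not days:
        raise ValueError("days must be non-empty")
    if len(set(days)) != len(days):
        raise ValueError(f"duplicate days in {days}")
    if days != sorted(days):
        raise ValueError("days must be sorted ascending")
    tables = []
    for d in days:
        cfg = replace(config, seed=day_seed(config.seed, d))
        tables.append(simulate_events(cfg, n_per_day, d))
    return tables
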