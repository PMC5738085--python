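"""Shared data model for proximity-network estimation.

The study design this package targets: participants carry two Bluetooth
observers of the same underlying co-location process — a smartphone app
performing discovery scans on a five-minute schedule during office hours,
and a wearable sociometric badge — and additionally nominate up to five
colleagues in a name-generator survey.  Everything downstream (activity
reconstruction, detection grids, weighted networks, concordance tables)
is built from the types defined here.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("app", "badge")
OS_VALUES = ("android", "ios", "none")
WEIGHT_KINDS = ("eq1_strength", "time_fraction", "binary")


class ProximnetError(Exception):
    """Base class for package errors."""


class ValidationError(ProximnetError, ValueError):
    """Input violates a documented invariant."""


class ParseError(ValidationError):
    """A file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedStatisticError(ProximnetError, ArithmeticError):
    """A statistic is undefined for the given table (e.g. zero margin)."""


@dataclass(frozen=True)
class DeviceInfo:
    """One physical observer: a participant's app or badge."""

    device_id: str
    participant_id: str
    modality: str  # 'app' or 'badge'
    os: str = "none"  # 'android'/'ios' for apps, 'none' for badges

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.os not in OS_VALUES:
            raise ValidationError(f"unknown os {self.os!r}")


class DeviceTable:
    """Device metadata with participant/modality lookups.

    Invariants: device ids unique; each participant holds at most one
    device per modality.
    """

    def __init__(self, devices: Iterable[DeviceInfo]):
        self.devices = tuple(devices)
        ids = [d.device_id for d in self.devices]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate device_id in device table")
        seen: set[tuple[str, str]] = set()
        for d in self.devices:
            key = (d.participant_id, d.modality)
            if key in seen:
                raise ValidationError(
                    f"participant {d.participant_id} has more than one "
                    f"{d.modality} device"
                )
            seen.add(key)
        self._by_id = {d.device_id: d for d in self.devices}

    def __iter__(self):
        return iter(self.devices)

    def __len__(self):
        return len(self.devices)

    def __contains__(self, device_id: str) -> bool:
        return device_id in self._by_id

    def get(self, device_id: str) -> DeviceInfo:
        return self._by_id[device_id]

    @property
    def participants(self) -> tuple[str, ...]:
        seen = dict.fromkeys(d.participant_id for d in self.devices)
        return tuple(sorted(seen))

    def of_modality(self, modality: str) -> "DeviceTable":
        return DeviceTable(d for d in self.devices if d.modality == modality)

    def device_of(self, participant_id: str, modality: str) -> DeviceInfo | None:
        for d in self.devices:
            if d.participant_id == participant_id and d.modality == modality:
                return d
        return None


@dataclass(frozen=True)
class ScanEvent:
    """One directed detection, or an empty scan that found nothing.

    An empty scan (``detected_id is None``) is still evidence that the
    scanner was operating and counts toward its scan total N_i.
    """

    scanner_id: str
    timestamp: pd.Timestamp  # tz-aware UTC, second resolution
    detected_id: str | None = None
    unknown_device: bool = False  # detection of a non-participant device

    def __post_init__(self):
        if self.detected_id == self.scanner_id:
            raise ValidationError("scanner cannot detect itself")
        if self.timestamp.tzinfo is None:
            raise ValidationError("ScanEvent timestamps must be tz-aware")


@dataclass(frozen=True)
class SurveyResponse:
    """Name-generator response: an ego nominating up to five alters."""

    ego: str
    alters: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.alters) > 5:
            raise ValidationError("at most five alters per response")
        if self.ego in self.alters:
            raise ValidationError("self-nomination in survey response")


@dataclass
class StudyConfig:
    """Study window, office-hours mask and analysis grid parameters.

    Office hours are interpreted in ``timezone`` (default the study site,
    Sydney); event timestamps are stored UTC and converted before masking.
    ``activity_gap`` is the width of the evidence window used when
    reconstructing per-device active periods.
    """

    study_start: dt.date = dt.date(2015, 8, 17)
    study_end: dt.date = dt.date(2015, 9, 11)  # inclusive
    office_days: tuple[int, ...] = (0, 1, 2, 3, 4)  # Mon..Fri
    office_start: dt.time = dt.time(9, 0)
    office_end: dt.time = dt.time(17, 0)
    bin_width: pd.Timedelta = field(default_factory=lambda: pd.Timedelta(minutes=5))
    timezone: str = "Australia/Sydney"
    activity_gap: pd.Timedelta = field(default_factory=lambda: pd.Timedelta(minutes=15))
    rng_seed: int = 0

    def __post_init__(self):
        self.bin_width = pd.Timedelta(self.bin_width)
        self.activity_gap = pd.Timedelta(self.activity_gap)
        if self.office_start >= self.office_end:
            raise ValidationError("office_start must precede office_end")
        if self.study_end < self.study_start:
            raise ValidationError("study_end before study_start")
        day_len = self.office_day_length
        if day_len % self.bin_width != pd.Timedelta(0):
            raise ValidationError(
                f"bin_width {self.bin_width} does not divide the "
                f"office-day length {day_len}"
            )

    @property
    def office_day_length(self) -> pd.Timedelta:
        return pd.Timedelta(
            hours=self.office_end.hour - self.office_start.hour,
            minutes=self.office_end.minute - self.office_start.minute,
        )

    @property
    def bins_per_day(self) -> int:
        return int(self.office_day_length / self.bin_width)

    def office_dates(self) -> list[dt.date]:
        days = pd.date_range(self.study_start, self.study_end, freq="D")
        return [d.date() for d in days if d.weekday() in self.office_days]

    def to_dict(self) -> dict:
        return {
            "study_start": self.study_start.isoformat(),
            "study_end": self.study_end.isoformat(),
            "office_days": list(self.office_days),
            "office_start": self.office_start.isoformat(timespec="minutes"),
            "office_end": self.office_end.isoformat(timespec="minutes"),
            "bin_width_minutes": self.bin_width / pd.Timedelta(minutes=1),
            "timezone": self.timezone,
            "activity_gap_minutes": self.activity_gap / pd.Timedelta(minutes=1),
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kwargs = {}
        if "study_start" in d:
            kwargs["study_start"] = dt.date.fromisoformat(d["study_start"])
        if "study_end" in d:
            kwargs["study_end"] = dt.date.fromisoformat(d["study_end"])
        if "office_days" in d:
            kwargs["office_days"] = tuple(int(x) for x in d["office_days"])
        if "office_start" in d:
            kwargs["office_start"] = dt.time.fromisoformat(d["office_start"])
        if "office_end" in d:
            kwargs["office_end"] = dt.time.fromisoformat(d["office_end"])
        if "bin_width_minutes" in d:
            kwargs["bin_width"] = pd.Timedelta(minutes=float(d["bin_width_minutes"]))
        if "timezone" in d:
            kwargs["timezone"] = str(d["timezone"])
        if "activity_gap_minutes" in d:
            kwargs["activity_gap"] = pd.Timedelta(
                minutes=float(d["activity_gap_minutes"])
            )
        if "rng_seed" in d:
            kwargs["rng_seed"] = int(d["rng_seed"])
        return cls(**kwargs)


class WeightedNetwork:
    """Symmetric nonnegative participant x participant weight matrix.

    ``weight_kind`` records the weighting scheme: 'eq1_strength' (scan-
    normalised connection strength in [0,1]), 'time_fraction' (fraction of
    analysed time bins a dyad was detected, in [0,1]) or 'binary'.
    """

    def __init__(self, nodes: Sequence[str], weights: np.ndarray, weight_kind: str):
        self.nodes = tuple(nodes)
        w = np.asarray(weights, dtype=float)
        n = len(self.nodes)
        if w.shape != (n, n):
            raise ValidationError(f"weights shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T, rtol=0, atol=1e-12):
            raise ValidationError("weight matrix is not symmetric")
        if np.any(np.diag(w) != 0):
            raise ValidationError("weight matrix has nonzero diagonal")
        if np.any(w < 0):
            raise ValidationError("negative weights")
        if weight_kind not in WEIGHT_KINDS:
            raise ValidationError(f"unknown weight_kind {weight_kind!r}")
        if weight_kind in ("eq1_strength", "time_fraction") and np.any(w > 1):
            raise ValidationError(f"{weight_kind} weights must lie in [0, 1]")
        if weight_kind == "binary" and not np.all(np.isin(w, (0.0, 1.0))):
            raise ValidationError("binary network weights must be 0 or 1")
        self.weights = 0.5 * (w + w.T)  # exact symmetry
        self.weight_kind = weight_kind

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def dyad_vector(self) -> np.ndarray:
        """Upper-triangle weights in row-major dyad order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def dyads(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n_nodes, k=1)
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(*iu)]

    def density(self) -> float:
        """Fraction of dyads with nonzero weight."""
        v = self.dyad_vector()
        return float(np.mean(v > 0)) if v.size else 0.0

    def subnetwork(self, nodes: Sequence[str]) -> "WeightedNetwork":
        idx = [self.nodes.index(n) for n in nodes]
        return WeightedNetwork(
            [self.nodes[i] for i in idx],
            self.weights[np.ix_(idx, idx)],
            self.weight_kind,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WeightedNetwork)
            and self.nodes == other.nodes
            and self.weight_kind == other.weight_kind
            and np.array_equal(self.weights, other.weights)
        )

    def __repr__(self) -> str:
        return (
            f"WeightedNetwork(n={self.n_nodes}, kind={self.weight_kind}, "
            f"density={self.density():.3f})"
        )


def events_to_frame(events: Iterable[ScanEvent]) -> pd.DataFrame:
    """Tabular view of an event list used by the vectorised estimators."""
    events = list(events)
    return pd.DataFrame(
        {
            "scanner_id": [e.scanner_id for e in events],
            "timestamp": pd.DatetimeIndex([e.timestamp for e in events], tz="UTC")
            if events
            else pd.DatetimeIndex([], tz="UTC"),
            "detected_id": [e.detected_id for e in events],
            "unknown_device": [e.unknown_device for e in events],
        }
    )


def frame_to_events(frame: pd.DataFrame) -> list[ScanEvent]:
    out = []
    for row in frame.itertuples(index=False):
        det = row.detected_id
        if det is not None and (not isinstance(det, str)) and pd.isna(det):
            det = None
        out.append(
            ScanEvent(
                scanner_id=row.scanner_id,
                timestamp=pd.Timestamp(row.timestamp),
                detected_id=det,
                unknown_device=bool(getattr(row, "unknown_device", False)),
            )
        )
    return out


__all__ = [
    "DeviceInfo",
    "DeviceTable",
    "ScanEvent",
    "SurveyResponse",
    "StudyConfig",
    "WeightedNetwork",
    "ProximnetError",
    "ValidationError",
    "ParseError",
    "UndefinedStatisticError",
    "events_to_frame",
    "frame_to_events",
    "MODALITIES",
    "WEIGHT_KINDS",
    "replace",
]
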