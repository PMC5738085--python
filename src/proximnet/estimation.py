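"""From scan events to detection grids, scanning statistics and networks.

Two weighting schemes are supported.  The scan-normalised connection
strength of a dyad {i, j} over an analysis interval T is

    R_ij = (N_ij + N_ji) / (N_i + N_j),

where N_ij is the number of scans in which device i detected device j and
N_i the number of scans device i made during T; R_ij = 0 when neither
device scanned.  The alternative 'time_fraction' weight is the fraction
of analysed time bins in which the dyad was detected at all.  Proximity
is undirected, so a dyad counts as detected in a bin when either device
saw the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import ActivityTimeline, TimeGrid, all_timelines
from .datamodel import (
    DeviceTable,
    ValidationError,
    WeightedNetwork,
    events_to_frame,
)

logger = logging.getLogger(__name__)

RESTRICTIONS = ("office_hours", "both_active")
SAMPLING_RULES = ("either_scanned", "both_scanned", "all_bins")


def dyad_pairs(participants: tuple[str, ...]) -> list[tuple[str, str]]:
    """Unordered participant pairs in upper-triangle row-major order."""
    return [
        (participants[i], participants[j])
        for i in range(len(participants))
        for j in range(i + 1, len(participants))
    ]


@dataclass
class _EventArrays:
    """Per-modality event data in array form (internal)."""

    participants: tuple[str, ...]
    scans: np.ndarray  # (n_part, n_bins) int: scans made per bin
    detections: np.ndarray  # (n_part, n_part, n_bins) int: i detected j
    n_dropped_outside: int
    n_dropped_unknown: int


def _event_arrays(events, devices: DeviceTable, grid: TimeGrid, modality: str):
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    modal = devices.of_modality(modality)
    dev_to_part = {d.device_id: d.participant_id for d in modal}
    participants = modal.participants
    part_idx = {p: i for i, p in enumerate(participants)}
    n = len(participants)

    is_known_scanner = frame["scanner_id"].isin(dev_to_part).to_numpy()
    n_unknown = int((~is_known_scanner).sum())
    frame = frame.loc[is_known_scanner]

    bins = grid.bin_of(pd.DatetimeIndex(frame["timestamp"]))
    outside = bins < 0
    n_outside = int(outside.sum())
    if n_outside:
        logger.info("%d events outside the analysis grid ignored", n_outside)
    frame = frame.loc[~outside]
    bins = bins[~outside]

    scanner_part = np.array(
        [part_idx[dev_to_part[s]] for s in frame["scanner_id"]], dtype=int
    )
    scans = np.zeros((n, grid.n_bins), dtype=np.int32)
    # a scan occasion = a unique (scanner, timestamp); detections of several
    # devices in one scan share the occasion
    occ = pd.DataFrame(
        {
            "part": scanner_part,
            "ts": frame["timestamp"].to_numpy(),
            "bin": bins,
        }
    ).drop_duplicates(subset=["part", "ts"])
    np.add.at(scans, (occ["part"].to_numpy(), occ["bin"].to_numpy()), 1)

    detections = np.zeros((n, n, grid.n_bins), dtype=np.int32)
    det_mask = frame["detected_id"].isin(dev_to_part).to_numpy()
    det = frame.loc[det_mask]
    if len(det):
        det_part = np.array(
            [part_idx[dev_to_part[d]] for d in det["detected_id"]], dtype=int
        )
        np.add.at(
            detections, (scanner_part[det_mask], det_part, bins[det_mask]), 1
        )
    return _EventArrays(participants, scans, detections, n_outside, n_unknown)


@dataclass
class DetectionGrid:
    """Dyad x time-bin detection (hit) and sampling indicators for one
    modality.

    A dyad is *hit* in a bin when either device detected the other there;
    it is *sampled* when at least one of its devices emitted any scan
    event in the bin (the rule is configurable via ``sampling_rule`` in
    :func:`detection_grid`).
    """

    modality: str
    participants: tuple[str, ...]
    dyads: list[tuple[str, str]]
    hits: np.ndarray  # (n_dyads, n_bins) bool
    sampled: np.ndarray  # (n_dyads, n_bins) bool
    grid: TimeGrid

    def __post_init__(self):
        if np.any(self.hits & ~self.sampled):
            raise ValidationError("hit in an unsampled dyad-bin")


def detection_grid(
    events,
    devices: DeviceTable,
    grid: TimeGrid,
    modality: str,
    sampling_rule: str = "either_scanned",
) -> DetectionGrid:
    """Bin events of one modality into per-dyad hit/sampled matrices."""
    if sampling_rule not in SAMPLING_RULES:
        raise ValidationError(f"unknown sampling rule {sampling_rule!r}")
    arr = _event_arrays(events, devices, grid, modality)
    participants = arr.participants
    n = len(participants)
    pairs = dyad_pairs(participants)
    scanned = arr.scans > 0
    sym = arr.detections + arr.detections.transpose(1, 0, 2)
    iu = np.triu_indices(n, k=1)
    hits = sym[iu] > 0
    if sampling_rule == "either_scanned":
        sampled = scanned[iu[0]] | scanned[iu[1]]
    elif sampling_rule == "both_scanned":
        sampled = scanned[iu[0]] & scanned[iu[1]]
    else:
        sampled = np.ones((len(pairs), grid.n_bins), dtype=bool)
    # a detection is evidence of a scan even if the occasion bookkeeping
    # missed it, so force consistency
    sampled |= hits
    return DetectionGrid(modality, participants, pairs, hits, sampled, grid)


def connection_strength(N_ij: int, N_ji: int, N_i: int, N_j: int) -> float:
    """Scan-normalised connection strength R_ij in [0, 1].

    Zero when neither device scanned during the interval.
    """
    for name, n_det, n_scan in (("i", N_ij, N_i), ("j", N_ji, N_j)):
        if n_det < 0 or n_scan < 0:
            raise ValidationError("negative counts")
        if n_det > n_scan:
            raise ValidationError(
                f"device {name}: detections ({n_det}) exceed scans ({n_scan})"
            )
    denom = N_i + N_j
    if denom == 0:
        return 0.0
    return (N_ij + N_ji) / denom


def time_fraction_weight(
    dyad_hits: np.ndarray, restriction_mask: np.ndarray
) -> float:
    """Fraction of masked bins in which the dyad was detected; 0 on an
    empty mask."""
    mask = np.asarray(restriction_mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        return 0.0
    return float(np.asarray(dyad_hits, dtype=bool)[mask].sum() / n)


def build_network(
    events,
    devices: DeviceTable,
    grid: TimeGrid,
    modality: str,
    scheme: str = "eq1_strength",
    restriction: str = "office_hours",
    timelines: dict[str, ActivityTimeline] | None = None,
) -> WeightedNetwork:
    """Estimate the weighted proximity network for one modality.

    ``restriction='both_active'`` limits each dyad's analysis interval to
    the bins in which both of its devices were reconstructed as active;
    this separates missingness from true absence of proximity.
    Participants without a device of the modality are excluded with a
    warning.
    """
    if scheme not in ("eq1_strength", "time_fraction"):
        raise ValidationError(f"unknown weighting scheme {scheme!r}")
    if restriction not in RESTRICTIONS:
        raise ValidationError(f"unknown restriction {restriction!r}")
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    modal = devices.of_modality(modality)
    missing = set(devices.participants) - set(modal.participants)
    if missing:
        logger.warning(
            "participants without a %s device excluded: %s",
            modality,
            sorted(missing),
        )
    arr = _event_arrays(frame, devices, grid, modality)
    participants = arr.participants
    n = len(participants)
    part_dev = {
        d.participant_id: d.device_id for d in modal
    }

    if restriction == "both_active":
        if timelines is None:
            timelines = all_timelines(frame, modal, grid)
        act = np.stack(
            [timelines[part_dev[p]].active for p in participants]
        )
    else:
        act = np.ones((n, grid.n_bins), dtype=bool)

    sym_det = arr.detections + arr.detections.transpose(1, 0, 2)
    weights = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = act[i] & act[j]
            if scheme == "eq1_strength":
                N_i = int(arr.scans[i, mask].sum())
                N_j = int(arr.scans[j, mask].sum())
                N_ij = int(arr.detections[i, j, mask].sum())
                N_ji = int(arr.detections[j, i, mask].sum())
                # clip: a detection implies a scan occasion, but a device
                # can detect several others in one occasion
                w = connection_strength(
                    min(N_ij, N_i), min(N_ji, N_j), N_i, N_j
                )
            else:
                w = time_fraction_weight(sym_det[i, j] > 0, mask)
            weights[i, j] = weights[j, i] = w
    return WeightedNetwork(participants, weights, scheme)


@dataclass
class ScanStats:
    """Per-device and per-dyad app scanning statistics."""

    participants: tuple[str, ...]
    scans_per_hour: dict[str, float]  # by participant
    scheduled_scan_completion: dict[str, float]
    combined_scan_rate_per_hour: dict[tuple[str, str], float]  # by dyad

    def dyad_rate_fraction_at_least(self, rate_per_hour: float) -> float:
        """Fraction of dyads whose combined scan rate meets a threshold."""
        rates = np.array(list(self.combined_scan_rate_per_hour.values()))
        return float(np.mean(rates >= rate_per_hour)) if rates.size else 0.0


def scan_stats(events, devices: DeviceTable, grid: TimeGrid) -> ScanStats:
    """App scanning statistics over office hours.

    Completion is scans made over scans scheduled (one per 5-min bin);
    a dyad's combined rate sums its two devices' scans because proximity
    edges are undirected.
    """
    arr = _event_arrays(events, devices, grid, "app")
    hours = grid.total_office_hours
    scheduled = grid.n_bins
    totals = arr.scans.sum(axis=1)
    sph = {p: float(t / hours) for p, t in zip(arr.participants, totals)}
    completion = {
        p: float(min(t / scheduled, 1.0)) for p, t in zip(arr.participants, totals)
    }
    combined = {
        (pi, pj): sph[pi] + sph[pj] for pi, pj in dyad_pairs(arr.participants)
    }
    return ScanStats(arr.participants, sph, completion, combined)
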