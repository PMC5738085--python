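"""Scan-rate bias analysis by fixed-size resampling of scan occasions.

Unequal scanning rates (Android vs iOS) bias the estimated app network.
To probe this, the app network is rebuilt using a fixed number m of
randomly chosen scan occasions per participant; participants with fewer
than m scans are dropped.  Tracing the Spearman correlation against the
badge and survey networks as m grows shows how much of the app-badge
disagreement is explained by sampling effort alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .activity import TimeGrid
from .datamodel import (
    DeviceTable,
    ProximnetError,
    ValidationError,
    WeightedNetwork,
    events_to_frame,
)
logger = logging.getLogger(__name__)


class InsufficientScansError(ProximnetError):
    """The device has fewer scan occasions than requested."""


def subsample_scans(
    events,
    device_id: str,
    m: int,
    rng: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Uniform random subset of m of a device's scan occasions.

    The unit sampled is the scan occasion (a unique scan timestamp);
    detections made during a kept occasion ride along.  Sampling is
    without replacement.  Raises :class:`InsufficientScansError` when the
    device has fewer than m occasions.
    """
    if m < 0:
        raise ValidationError("m must be nonnegative")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    mine = frame[frame["scanner_id"] == device_id]
    occasions = mine["timestamp"].unique()
    if len(occasions) < m:
        raise InsufficientScansError(
            f"{device_id}: {len(occasions)} scan occasions < m={m}"
        )
    keep = rng.choice(len(occasions), size=m, replace=False)
    kept_ts = set(pd.DatetimeIndex(occasions[np.sort(keep)]))
    return mine[mine["timestamp"].isin(kept_ts)]


def scan_occasion_counts(events, devices: DeviceTable, modality="app") -> dict:
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    out = {}
    for d in devices.of_modality(modality):
        mine = frame[frame["scanner_id"] == d.device_id]
        out[d.device_id] = int(mine["timestamp"].nunique())
    return out


@dataclass
class ResampleCurve:
    """Correlation-vs-sample-count trace of the resampling analysis.

    For each sample count m: the retained node count, the median and
    0.5-99.5 percentile band of rho(app, badge) and rho(app, survey)
    across replicates, and rho(badge, survey) on the retained nodes
    (constant per m as only the app is resampled).
    """

    sample_counts: list[int]
    n_nodes: list[int]
    rho_app_badge: list[dict]  # {'median','lo','hi'}
    rho_app_survey: list[dict]
    rho_badge_survey: list[float]
    n_rep: int


def _spearman(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    return float(stats.spearmanr(x, y).statistic)


def resample_curve(
    app_events,
    devices: DeviceTable,
    grid: TimeGrid,
    badge_net: WeightedNetwork,
    survey_net: WeightedNetwork,
    counts=(10, 25, 50, 100, 250, 500),
    n_rep: int = 1000,
    seed: int = 0,
    scheme: str = "eq1_strength",
) -> ResampleCurve:
    """Rebuild the app network from m random scans per participant and
    correlate against the badge and survey networks.

    The scan-normalised (eq1) weighting is the default: it normalises per
    sampling occasion, which is exactly what unequal m would otherwise
    confound.  Counts for which fewer than 3 participants qualify
    truncate the curve with a warning.
    """
    if scheme != "eq1_strength":
        raise ValidationError("resample_curve supports the eq1_strength scheme")
    frame = (
        app_events
        if isinstance(app_events, pd.DataFrame)
        else events_to_frame(app_events)
    )
    rng = np.random.default_rng([seed, 3])
    app_devs = {d.device_id: d.participant_id for d in devices.of_modality("app")}
    dev_of_part = {p: d for d, p in app_devs.items()}

    # per-device scan occasions and the detections riding on each occasion,
    # precomputed once so each replicate is a pure index-sampling step
    in_grid = grid.bin_of(pd.DatetimeIndex(frame["timestamp"])) >= 0
    frame = frame.loc[in_grid & frame["scanner_id"].isin(app_devs)]
    occ = scan_occasion_counts(frame, devices, "app")
    per_device = {}
    for dev in app_devs:
        mine = frame[frame["scanner_id"] == dev]
        occasions = np.sort(mine["timestamp"].unique())
        occ_index = {t: k for k, t in enumerate(occasions)}
        det = mine[mine["detected_id"].isin(app_devs)]
        det_occ = np.array(
            [occ_index[t] for t in det["timestamp"]], dtype=int
        )
        det_part = np.array(
            [app_devs[d] for d in det["detected_id"]], dtype=object
        )
        per_device[dev] = (len(occasions), det_occ, det_part)

    out = ResampleCurve([], [], [], [], [], n_rep)
    for m in counts:
        eligible = sorted(dev for dev, n in occ.items() if n >= m)
        retained = sorted(app_devs[dev] for dev in eligible)
        if len(retained) < 3:
            logger.warning(
                "m=%d retains %d participants (<3); curve truncated",
                m,
                len(retained),
            )
            break
        sub_badge = badge_net.subnetwork(
            [p for p in badge_net.nodes if p in retained]
        )
        sub_survey = survey_net.subnetwork(
            [p for p in survey_net.nodes if p in retained]
        )
        ref_dyads = {
            "badge": sub_badge.dyad_vector(),
            "survey": sub_survey.dyad_vector(),
        }
        part_idx = {p: i for i, p in enumerate(retained)}
        n_ret = len(retained)
        iu = np.triu_indices(n_ret, k=1)
        rb, rs = [], []
        for _ in range(n_rep):
            det_counts = np.zeros((n_ret, n_ret))
            for p in retained:
                dev = dev_of_part[p]
                n_occ, det_occ, det_part = per_device[dev]
                chosen = rng.choice(n_occ, size=m, replace=False)
                if det_occ.size:
                    keep = np.isin(det_occ, chosen)
                    for other in det_part[keep]:
                        if other in part_idx:
                            det_counts[part_idx[p], part_idx[other]] += 1
            # R_ij = (N_ij + N_ji) / (N_i + N_j) with N_i = N_j = m
            weights = (det_counts + det_counts.T) / (2 * m)
            v = np.minimum(weights, 1.0)[iu]
            r = _spearman(v, ref_dyads["badge"])
            if r is not None:
                rb.append(r)
            r = _spearman(v, ref_dyads["survey"])
            if r is not None:
                rs.append(r)
        out.sample_counts.append(int(m))
        out.n_nodes.append(len(retained))
        for acc, dest in ((rb, out.rho_app_badge), (rs, out.rho_app_survey)):
            if acc:
                lo, med, hi = np.percentile(acc, [0.5, 50, 99.5])
            else:
                lo = med = hi = np.nan
            dest.append(
                {"median": float(med), "lo": float(lo), "hi": float(hi)}
            )
        r_bs = _spearman(ref_dyads["badge"], ref_dyads["survey"])
        out.rho_badge_survey.append(float("nan") if r_bs is None else r_bs)
    return out


def curve_frame(curve: ResampleCurve) -> pd.DataFrame:
    """Tabular form of a resample curve for CSV output."""
    return pd.DataFrame(
        {
            "m": curve.sample_counts,
            "n_nodes": curve.n_nodes,
            "rho_app_badge_median": [d["median"] for d in curve.rho_app_badge],
            "rho_app_badge_lo": [d["lo"] for d in curve.rho_app_badge],
            "rho_app_badge_hi": [d["hi"] for d in curve.rho_app_badge],
            "rho_app_survey_median": [d["median"] for d in curve.rho_app_survey],
            "rho_app_survey_lo": [d["lo"] for d in curve.rho_app_survey],
            "rho_app_survey_hi": [d["hi"] for d in curve.rho_app_survey],
            "rho_badge_survey": curve.rho_badge_survey,
        }
    )
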