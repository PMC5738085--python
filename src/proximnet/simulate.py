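"""Synthetic co-location ground truth and its imperfect observation.

The generator emulates a small office cohort (21 participants by
default) in which pairs of colleagues co-locate in interval "sessions",
and two Bluetooth observers record that process imperfectly:

* an *app* on each participant's phone, scheduled to scan every five
  minutes during office hours, with realised scan rates stratified by OS
  (Android ~5.6/h, iOS ~1.1/h) and an on/off activity process with mean
  active fraction ~0.79;
* a *badge* worn intermittently (mean active fraction ~0.37) with a
  smaller detection range than the app.

Each dyad session carries a representative distance; a scan detects the
partner only when the session distance is within the modality's range,
the partner's device is on, and a Bernoulli detection succeeds.  Because
ground truth is available, downstream estimators can be tested for
structure recovery, which no real deployment of such a study permits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import TimeGrid, build_grid
from .datamodel import (
    DeviceInfo,
    DeviceTable,
    ScanEvent,
    StudyConfig,
    SurveyResponse,
    ValidationError,
)

SCHEDULED_SCANS_PER_HOUR = 12.0  # one per five minutes


@dataclass
class SimulationParams:
    """Study-condition parameters of the generator.

    Rates are per office hour; active fractions are long-run fractions of
    office time the device is operating.  Defaults reproduce the cohort
    the package targets: 21 participants (9 Android, 12 iOS), Android
    scanning 5.6 +- 3.8 per hour vs iOS 1.1 +- 0.8, app active
    79.1 +- 22.2% of office hours vs badge 37.0 +- 18.4%, and a badge
    detection range smaller than the app's 10 m.
    """

    n_participants: int = 21
    n_android: int = 9
    n_ios: int = 12
    android_scan_rate_per_h: tuple[float, float] = (5.6, 3.8)  # mean, sd
    ios_scan_rate_per_h: tuple[float, float] = (1.1, 0.8)
    app_active_fraction: tuple[float, float] = (0.791, 0.222)
    badge_active_fraction: tuple[float, float] = (0.370, 0.184)
    app_detect_prob_within_range: float = 0.8
    badge_detect_prob_within_range: float = 0.8
    app_range_m: float = 10.0
    badge_range_m: float = 5.0
    session_rate_per_hour: float = 0.2  # per dyad, per unit affinity
    session_duration_mean_min: float = 20.0
    session_distance_range_m: tuple[float, float] = (0.5, 12.0)
    dyad_affinity_shape: float = 0.6  # gamma shape; mean fixed at 1
    activity_cycle_hours: float = 4.0  # mean on+off renewal cycle
    min_scan_rate_per_h: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_android + self.n_ios != self.n_participants:
            raise ValidationError("n_android + n_ios must equal n_participants")
        for p in (
            self.app_detect_prob_within_range,
            self.badge_detect_prob_within_range,
        ):
            if not 0 <= p <= 1:
                raise ValidationError("detection probabilities must lie in [0, 1]")
        if self.session_rate_per_hour < 0:
            raise ValidationError("session rate must be nonnegative")
        if self.badge_range_m > self.app_range_m:
            raise ValidationError("badge range should not exceed app range")


@dataclass
class ColocationTruth:
    """Per-dyad co-location sessions on the concatenated office axis.

    ``sessions[(pi, pj)]`` is an (n, 3) array of (start_s, end_s,
    distance_m) rows; intervals lie within office hours and pairs are
    stored with pi < pj.
    """

    participants: tuple[str, ...]
    sessions: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def _dyad(self, pi: str, pj: str) -> tuple[str, str]:
        return (pi, pj) if pi < pj else (pj, pi)

    def in_range_at(
        self, pi: str, pj: str, office_seconds: np.ndarray, range_m: float
    ) -> np.ndarray:
        """Whether the dyad is within ``range_m`` at each instant."""
        t = np.asarray(office_seconds, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for start, end, dist in self.sessions.get(self._dyad(pi, pj), ()):
            if dist <= range_m:
                out |= (t >= start) & (t < end)
        return out

    def in_range_seconds(self, pi: str, pj: str, range_m: float) -> float:
        """Total in-range time, counting overlapping sessions once."""
        ivals = [
            (s, e)
            for s, e, d in self.sessions.get(self._dyad(pi, pj), ())
            if d <= range_m
        ]
        if not ivals:
            return 0.0
        ivals.sort()
        total, cur_s, cur_e = 0.0, *ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        return total + (cur_e - cur_s)

    def in_range_bins(self, grid: TimeGrid, range_m: float) -> dict:
        """Per-dyad boolean vector: bin overlaps an in-range session."""
        out = {}
        for dyad, rows in self.sessions.items():
            v = np.zeros(grid.n_bins, dtype=bool)
            for start, end, dist in rows:
                if dist > range_m or end <= start:
                    continue
                first = int(start // grid.bin_seconds)
                last = min(
                    int(np.ceil(end / grid.bin_seconds)) - 1, grid.n_bins - 1
                )
                v[first : last + 1] = True
            out[dyad] = v
        return out


def default_device_table(params: SimulationParams) -> DeviceTable:
    """Participants P01.. with one app (OS-stratified) and one badge each."""
    devices = []
    for k in range(params.n_participants):
        pid = f"P{k + 1:02d}"
        os_name = "android" if k < params.n_android else "ios"
        devices.append(DeviceInfo(f"{pid}-app", pid, "app", os_name))
        devices.append(DeviceInfo(f"{pid}-badge", pid, "badge", "none"))
    return DeviceTable(devices)


def _truncnorm(rng, mean, sd, lo, hi=np.inf, size=None):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    for _ in range(200):
        if not np.any(bad):
            break
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def simulate_colocation(
    params: SimulationParams,
    config: StudyConfig,
    rng: np.random.Generator | None = None,
) -> ColocationTruth:
    """Draw the ground-truth co-location process.

    Per dyad, session counts follow a Poisson process thinned by a
    gamma-distributed affinity (mean 1), so a minority of dyads carries
    most of the co-location; each session has an exponential duration and
    a uniform representative distance, part of which falls between the
    badge and app ranges so the app sees a denser process than the badge.
    """
    if rng is None:
        rng = np.random.default_rng([params.rng_seed, 11])
    grid = build_grid(config)
    participants = tuple(d for d in default_device_table(params).participants)
    truth = ColocationTruth(participants)
    total_s = grid.total_office_seconds
    hours = grid.total_office_hours
    shape = params.dyad_affinity_shape
    dur_mean_s = params.session_duration_mean_min * 60.0
    lo_d, hi_d = params.session_distance_range_m
    for i in range(len(participants)):
        for j in range(i + 1, len(participants)):
            affinity = rng.gamma(shape, 1.0 / shape)
            n = rng.poisson(params.session_rate_per_hour * affinity * hours)
            if n == 0:
                continue
            starts = rng.uniform(0, total_s, size=n)
            durs = rng.exponential(dur_mean_s, size=n)
            day = starts // grid.day_seconds
            ends = np.minimum(starts + durs, (day + 1) * grid.day_seconds)
            dists = rng.uniform(lo_d, hi_d, size=n)
            order = np.argsort(starts)
            truth.sessions[(participants[i], participants[j])] = np.column_stack(
                [starts, ends, dists]
            )[order]
    return truth


def _activity_intervals(rng, active_fraction, cycle_s, total_s):
    """Alternating on/off renewal process; returns (starts, ends) arrays."""
    if active_fraction >= 1.0:
        return np.array([0.0]), np.array([float(total_s)])
    if active_fraction <= 0.0:
        return np.array([]), np.array([])
    mean_on = max(active_fraction * cycle_s, 1.0)
    mean_off = max((1 - active_fraction) * cycle_s, 1.0)
    on = rng.random() < active_fraction
    t = 0.0
    starts, ends = [], []
    while t < total_s:
        dur = rng.exponential(mean_on if on else mean_off)
        if on:
            starts.append(t)
            ends.append(min(t + dur, total_s))
        t += dur
        on = not on
    return np.asarray(starts), np.asarray(ends)


def _on_at(starts: np.ndarray, ends: np.ndarray, t: np.ndarray) -> np.ndarray:
    if starts.size == 0:
        return np.zeros(t.shape, dtype=bool)
    idx = np.searchsorted(starts, t, side="right") - 1
    ok = idx >= 0
    out = np.zeros(t.shape, dtype=bool)
    out[ok] = t[ok] < ends[idx[ok]]
    return out


def observe(
    truth: ColocationTruth,
    params: SimulationParams,
    config: StudyConfig,
    modality: str,
    devices: DeviceTable | None = None,
    rng: np.random.Generator | None = None,
) -> list[ScanEvent]:
    """Observe the truth through one modality's devices.

    Each device gets an on/off activity renewal process matched to the
    modality's active-fraction distribution and scans on the 5-minute
    grid while on (apps with a per-slot probability reproducing the
    OS-stratified realised rate; badges at every slot while worn).  A
    scan detects a partner iff the dyad is in range for the modality, the
    partner's device is on, and a Bernoulli(detect_prob) succeeds; scans
    that find nothing are emitted as empty events.
    """
    if modality not in ("app", "badge"):
        raise ValidationError(f"unknown modality {modality!r}")
    if devices is None:
        devices = default_device_table(params)
    modal = devices.of_modality(modality)
    if len(modal) == 0:
        raise ValidationError(f"device table has no {modality} devices")
    if rng is None:
        rng = np.random.default_rng(
            [params.rng_seed, {"app": 1, "badge": 2}[modality]]
        )
    grid = build_grid(config)
    total_s = grid.total_office_seconds
    cycle_s = params.activity_cycle_hours * 3600.0
    detect_prob = (
        params.app_detect_prob_within_range
        if modality == "app"
        else params.badge_detect_prob_within_range
    )
    range_m = params.app_range_m if modality == "app" else params.badge_range_m
    af_mean, af_sd = (
        params.app_active_fraction
        if modality == "app"
        else params.badge_active_fraction
    )

    slot_times = np.arange(grid.n_bins) * grid.bin_seconds + 60.0  # within bin
    dev_list = list(modal)
    state = {}
    for d in dev_list:
        af = float(_truncnorm(rng, af_mean, af_sd, 0.02, 1.0))
        if modality == "app":
            r_mean, r_sd = (
                params.android_scan_rate_per_h
                if devices.get(d.device_id).os == "android"
                else params.ios_scan_rate_per_h
            )
            rate = float(
                _truncnorm(
                    rng, r_mean, r_sd, params.min_scan_rate_per_h,
                    SCHEDULED_SCANS_PER_HOUR,
                )
            )
            # a device cannot scan more often than its active slots allow;
            # frequent scanners are therefore also highly active
            af = max(af, rate / SCHEDULED_SCANS_PER_HOUR)
            q = rate / (SCHEDULED_SCANS_PER_HOUR * af)
        else:
            q = 1.0
        on_s, on_e = _activity_intervals(rng, af, cycle_s, total_s)
        on = _on_at(on_s, on_e, slot_times)
        scans = on & (rng.random(grid.n_bins) < q)
        state[d.device_id] = {"on": (on_s, on_e), "scan_times": slot_times[scans]}

    events: list[ScanEvent] = []
    for d in dev_list:
        times = state[d.device_id]["scan_times"]
        if times.size == 0:
            continue
        detected = {t: [] for t in times}
        for other in dev_list:
            if other.participant_id == d.participant_id:
                continue
            in_range = truth.in_range_at(
                d.participant_id, other.participant_id, times, range_m
            )
            o_on_s, o_on_e = state[other.device_id]["on"]
            partner_on = _on_at(o_on_s, o_on_e, times)
            hit = in_range & partner_on & (rng.random(times.size) < detect_prob)
            for t in times[hit]:
                detected[t].append(other.device_id)
        stamps = grid.timestamps_of(times)
        for t, ts in zip(times, stamps):
            ts = ts.floor("s")
            if detected[t]:
                for dev_id in detected[t]:
                    events.append(ScanEvent(d.device_id, ts, dev_id))
            else:
                events.append(ScanEvent(d.device_id, ts, None))
    events.sort(key=lambda e: (e.timestamp.value, e.scanner_id, e.detected_id or ""))
    return events


def survey_from_truth(
    truth: ColocationTruth,
    k: int = 5,
    range_m: float = 10.0,
) -> list[SurveyResponse]:
    """Name-generator responses: each ego nominates its top-k partners by
    total in-range co-location time (ties broken by token order)."""
    responses = []
    for ego in truth.participants:
        totals = []
        for other in truth.participants:
            if other == ego:
                continue
            t = truth.in_range_seconds(ego, other, range_m)
            if t > 0:
                totals.append((-t, other))
        totals.sort()
        responses.append(
            SurveyResponse(ego=ego, alters=tuple(o for _, o in totals[:k]))
        )
    return responses


@dataclass
class SimulatedStudy:
    params: SimulationParams
    config: StudyConfig
    devices: DeviceTable
    truth: ColocationTruth
    app_events: list[ScanEvent]
    badge_events: list[ScanEvent]
    survey: list[SurveyResponse]


def simulate_study(
    params: SimulationParams | None = None,
    config: StudyConfig | None = None,
) -> SimulatedStudy:
    """Generate one complete synthetic study, deterministically under
    ``params.rng_seed``."""
    params = params or SimulationParams()
    config = config or StudyConfig()
    devices = default_device_table(params)
    truth = simulate_colocation(params, config)
    app_events = observe(truth, params, config, "app", devices)
    badge_events = observe(truth, params, config, "badge", devices)
    survey = survey_from_truth(truth, k=5, range_m=params.app_range_m)
    return SimulatedStudy(
        params, config, devices, truth, app_events, badge_events, survey
    )
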