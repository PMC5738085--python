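"""Office-hours time grid and per-device activity reconstruction.

A device's active periods are not logged directly; they are reconstructed
retrospectively from evidence that it was operating: scans it initiated
(including scans that found nothing) and instants at which other devices
detected it.  Each evidence instant opens a window of width
``activity_gap`` centred on it; a time bin counts as active when it
intersects the union of these windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ScanEvent, StudyConfig, ValidationError, events_to_frame


class TimeGrid:
    """Half-open analysis bins covering the office hours of the study.

    Also exposes an "office-seconds" axis: office hours of consecutive
    office days concatenated into one continuous coordinate, which makes
    binning and simulation arithmetic trivial.
    """

    def __init__(self, config: StudyConfig):
        self.config = config
        self.dates = config.office_dates()
        self.bin_seconds = int(config.bin_width.total_seconds())
        self.day_seconds = int(config.office_day_length.total_seconds())
        self.bins_per_day = config.bins_per_day
        self.n_bins = len(self.dates) * self.bins_per_day
        self.tz = config.timezone
        offsets = pd.to_timedelta(
            np.arange(self.bins_per_day) * self.bin_seconds, unit="s"
        )
        starts = [
            pd.Timestamp.combine(d, config.office_start).tz_localize(self.tz) + offsets
            for d in self.dates
        ]
        self.bin_starts = starts[0].append(starts[1:]) if starts else pd.DatetimeIndex([])
        self._date_index = {d: i for i, d in enumerate(self.dates)}
        self._day_starts_utc = pd.DatetimeIndex(
            [
                pd.Timestamp.combine(d, config.office_start)
                .tz_localize(self.tz)
                .tz_convert("UTC")
                for d in self.dates
            ]
        )

    def __len__(self) -> int:
        return self.n_bins

    @property
    def total_office_seconds(self) -> int:
        return self.n_bins * self.bin_seconds

    @property
    def total_office_hours(self) -> float:
        return self.total_office_seconds / 3600.0

    def office_seconds_of(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """Concatenated office-axis coordinate of each instant; NaN outside
        office hours."""
        ts = pd.DatetimeIndex(timestamps)
        if ts.tz is None:
            raise ValidationError("timestamps must be tz-aware")
        local = ts.tz_convert(self.tz)
        out = np.full(len(ts), np.nan)
        if not len(ts):
            return out
        day_idx = np.array(
            [self._date_index.get(d, -1) for d in local.date], dtype=int
        )
        start = self.config.office_start
        secs = (
            (local.hour - start.hour) * 3600
            + (local.minute - start.minute) * 60
            + local.second
        ).to_numpy(dtype=float)
        ok = (day_idx >= 0) & (secs >= 0) & (secs < self.day_seconds)
        out[ok] = day_idx[ok] * self.day_seconds + secs[ok]
        return out

    def timestamps_of(self, office_seconds: np.ndarray) -> pd.DatetimeIndex:
        """Inverse of :meth:`office_seconds_of` (UTC instants)."""
        s = np.asarray(office_seconds)
        day = (s // self.day_seconds).astype(int)
        within = s - day * self.day_seconds
        return pd.DatetimeIndex(
            self._day_starts_utc[day] + pd.to_timedelta(within, unit="s")
        )

    def bin_of(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """Bin index per instant, -1 for instants outside the grid."""
        s = self.office_seconds_of(timestamps)
        out = np.full(len(s), -1, dtype=int)
        ok = ~np.isnan(s)
        out[ok] = (s[ok] // self.bin_seconds).astype(int)
        return out


def build_grid(config: StudyConfig) -> TimeGrid:
    """Construct the analysis grid (5-min bins over office hours by default)."""
    return TimeGrid(config)


@dataclass
class ActivityTimeline:
    """Boolean active/inactive vector for one device, aligned to a grid."""

    device_id: str
    active: np.ndarray
    grid: TimeGrid

    def __post_init__(self):
        self.active = np.asarray(self.active, dtype=bool)
        if self.active.shape != (self.grid.n_bins,):
            raise ValidationError("timeline length does not match grid")


def activity_timeline(
    events: list[ScanEvent] | pd.DataFrame,
    device_id: str,
    grid: TimeGrid,
    gap: pd.Timedelta | None = None,
) -> ActivityTimeline:
    """Reconstruct a device's active bins from scan-log evidence.

    Evidence instants are the device's own scans (empty or not) plus the
    instants it was detected by others.  Windows of width ``gap`` centred
    on evidence are clipped to the office day they fall in, so activity
    never spills across days.
    """
    if gap is None:
        gap = grid.config.activity_gap
    half = gap.total_seconds() / 2.0
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    mask = (frame["scanner_id"] == device_id) | (frame["detected_id"] == device_id)
    instants = pd.DatetimeIndex(frame.loc[mask, "timestamp"])
    active = np.zeros(grid.n_bins, dtype=bool)
    s = grid.office_seconds_of(instants)
    s = s[~np.isnan(s)]
    if s.size == 0:
        return ActivityTimeline(device_id, active, grid)
    day = s // grid.day_seconds
    lo = np.maximum(s - half, day * grid.day_seconds)
    hi = np.minimum(s + half, (day + 1) * grid.day_seconds)
    first = (lo // grid.bin_seconds).astype(int)
    # last bin whose start is strictly before hi
    last = np.ceil(hi / grid.bin_seconds).astype(int) - 1
    for f, l in zip(first, last):
        active[f : l + 1] = True
    return ActivityTimeline(device_id, active, grid)


def active_fraction(timeline: ActivityTimeline) -> float:
    """Fraction of office-hour bins in which the device was active."""
    return float(np.mean(timeline.active)) if timeline.active.size else 0.0


def both_active(a: ActivityTimeline, b: ActivityTimeline) -> np.ndarray:
    """Element-wise conjunction of two aligned timelines."""
    if a.grid.n_bins != b.grid.n_bins:
        raise ValidationError("timelines are on different grids")
    return a.active & b.active


def all_timelines(
    events, devices, grid: TimeGrid, gap: pd.Timedelta | None = None
) -> dict[str, ActivityTimeline]:
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    return {
        d.device_id: activity_timeline(frame, d.device_id, grid, gap) for d in devices
    }
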