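"""Pooled 2x2 concordance between two detection modalities.

Dyad-bin observations from two observers of the same co-location process
(e.g. smartphone app vs sociometric badge) are cross-classified into a
single pooled 2x2 table, whose association is summarised by the phi
coefficient, the odds ratio and an uncorrected Pearson chi-square test
(1 df).  Marginal odds — hits over misses for one modality, as a
percentage — measure how often each observer detects a dyad at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .activity import ActivityTimeline
from .datamodel import (
    DeviceTable,
    UndefinedStatisticError,
    ValidationError,
)
from .estimation import DetectionGrid


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Pooled hit/miss cross-classification of modalities A and B.

    a: both hit; b: A hit, B miss; c: A miss, B hit; d: both miss.
    """

    a: int
    b: int
    c: int
    d: int
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValidationError(f"cell {name}={v!r} is not a nonnegative integer")
        if self.n == 0:
            raise ValidationError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable2x2":
        """The same table with the modality labels exchanged."""
        return ContingencyTable2x2(
            self.a, self.c, self.b, self.d, self.label_b, self.label_a
        )

    def __add__(self, other: "ContingencyTable2x2") -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.a + other.a,
            self.b + other.b,
            self.c + other.c,
            self.d + other.d,
            self.label_a,
            self.label_b,
        )


def build_contingency(
    grid_a: DetectionGrid,
    grid_b: DetectionGrid,
    universe_mask: np.ndarray | None = None,
) -> ContingencyTable2x2:
    """Cross-classify dyad-bins of two aligned detection grids.

    ``universe_mask`` (dyads x bins, boolean) selects which dyad-bins
    enter the table — e.g. the bins sampled by modality A, or the bins in
    which both modalities' devices were active.  Defaults to A's sampled
    mask.
    """
    if grid_a.grid.n_bins != grid_b.grid.n_bins or grid_a.dyads != grid_b.dyads:
        raise ValidationError("detection grids are not aligned")
    if universe_mask is None:
        universe_mask = grid_a.sampled
    universe_mask = np.asarray(universe_mask, dtype=bool)
    if universe_mask.shape != grid_a.hits.shape:
        raise ValidationError("universe mask shape does not match the grids")
    ha = grid_a.hits[universe_mask]
    hb = grid_b.hits[universe_mask]
    return ContingencyTable2x2(
        a=int(np.sum(ha & hb)),
        b=int(np.sum(ha & ~hb)),
        c=int(np.sum(~ha & hb)),
        d=int(np.sum(~ha & ~hb)),
        label_a=grid_a.modality,
        label_b=grid_b.modality,
    )


def marginal_odds(table: ContingencyTable2x2, side: str) -> float:
    """Hits over misses for one side, as a percentage.

    Returns ``math.inf`` when the side has hits but no misses; 0 when it
    has neither.
    """
    if side in ("A", table.label_a):
        hits, misses = table.a + table.b, table.c + table.d
    elif side in ("B", table.label_b):
        hits, misses = table.a + table.c, table.b + table.d
    else:
        raise ValidationError(f"unknown side {side!r}")
    if misses == 0:
        return math.inf if hits > 0 else 0.0
    return 100.0 * hits / misses


def odds_ratio(table: ContingencyTable2x2) -> float:
    """(a*d)/(b*c); ``math.inf`` when b*c = 0 with a*d > 0."""
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        if num > 0:
            return math.inf
        raise UndefinedStatisticError("odds ratio 0/0 is undefined")
    return num / den


def _margins(table: ContingencyTable2x2) -> tuple[int, int, int, int]:
    return (
        table.a + table.b,
        table.c + table.d,
        table.a + table.c,
        table.b + table.d,
    )


def phi_coefficient(table: ContingencyTable2x2) -> float:
    """Pearson correlation of the two pooled binary indicators.

    The numerator a*d - b*c is formed in exact integer arithmetic before
    the square root.
    """
    m = _margins(table)
    if any(x == 0 for x in m):
        raise UndefinedStatisticError("phi undefined: a margin is zero")
    num = table.a * table.d - table.b * table.c
    return num / math.sqrt(math.prod(m))


def chi_square(table: ContingencyTable2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square (1 df) and its p-value.

    Satisfies chi2 = N * phi**2 identically.
    """
    phi = phi_coefficient(table)
    stat = table.n * phi * phi
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def sensitivity_specificity(
    table: ContingencyTable2x2, reference_side: str = "B"
) -> tuple[float, float]:
    """Sensitivity and specificity of the non-reference modality.

    With B (the badge, in the motivating study) as reference:
    sensitivity = a/(a+c), specificity = d/(b+d).
    """
    t = table
    if reference_side in ("A", table.label_a):
        t = table.swapped()
    elif reference_side not in ("B", table.label_b):
        raise ValidationError(f"unknown side {reference_side!r}")
    pos = t.a + t.c
    neg = t.b + t.d
    if pos == 0:
        raise UndefinedStatisticError("no reference positives")
    if neg == 0:
        raise UndefinedStatisticError("no reference negatives")
    return t.a / pos, t.d / neg


OS_PAIR_CLASSES = ("android-android", "ios-ios", "android-ios")


def os_pair_class(os_i: str, os_j: str) -> str:
    return "-".join(sorted((os_i, os_j)))


def os_subgroup_tables(
    grid_a: DetectionGrid,
    grid_b: DetectionGrid,
    devices: DeviceTable,
    universe_mask: np.ndarray | None = None,
) -> dict[str, ContingencyTable2x2 | None]:
    """Contingency tables restricted to dyads of each app-OS pair class.

    Classes with no dyads are reported as ``None``.  The cell-wise sum of
    non-empty classes equals the full table because the classes partition
    the dyads.
    """
    os_of = {
        d.participant_id: d.os for d in devices.of_modality("app")
    }
    if universe_mask is None:
        universe_mask = grid_a.sampled
    universe_mask = np.asarray(universe_mask, dtype=bool)
    out: dict[str, ContingencyTable2x2 | None] = {}
    for cls in OS_PAIR_CLASSES:
        rows = np.array(
            [
                os_pair_class(os_of.get(pi, "none"), os_of.get(pj, "none")) == cls
                for pi, pj in grid_a.dyads
            ]
        )
        mask = universe_mask.copy()
        mask[~rows, :] = False
        if not rows.any() or not mask.any():
            out[cls] = None
            continue
        out[cls] = build_contingency(grid_a, grid_b, mask)
    return out


def both_modalities_active_mask(
    grid_a: DetectionGrid,
    timelines_a: dict[str, ActivityTimeline],
    timelines_b: dict[str, ActivityTimeline],
    devices: DeviceTable,
) -> np.ndarray:
    """Dyad-bin mask: all four devices (both modalities, both participants)
    active."""
    app_dev = {d.participant_id: d.device_id for d in devices.of_modality("app")}
    badge_dev = {d.participant_id: d.device_id for d in devices.of_modality("badge")}
    mask = np.zeros(grid_a.hits.shape, dtype=bool)
    for k, (pi, pj) in enumerate(grid_a.dyads):
        if pi not in app_dev or pj not in app_dev:
            continue
        if pi not in badge_dev or pj not in badge_dev:
            continue
        mask[k] = (
            timelines_a[app_dev[pi]].active
            & timelines_a[app_dev[pj]].active
            & timelines_b[badge_dev[pi]].active
            & timelines_b[badge_dev[pj]].active
        )
    return mask
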