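"""Pooled 2x2 concordance statistics and their algebraic identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from proximnet.activity import build_grid
from proximnet.concordance import (
    ContingencyTable2x2,
    build_contingency,
    chi_square,
    marginal_odds,
    odds_ratio,
    os_pair_class,
    os_subgroup_tables,
    phi_coefficient,
    sensitivity_specificity,
)
from proximnet.datamodel import (
    UndefinedStatisticError,
    ValidationError,
    events_to_frame,
)
from proximnet.estimation import DetectionGrid, detection_grid

# pooled app-vs-badge detection counts of the motivating study:
# across all office hours, and restricted to both-devices-active intervals
OFFICE = ContingencyTable2x2(191, 6448, 264, 227270, "app", "badge")
ACTIVE = ContingencyTable2x2(191, 2327, 214, 29252, "app", "badge")

tables = st.tuples(
    st.integers(1, 10_000),
    st.integers(1, 10_000),
    st.integers(1, 10_000),
    st.integers(1, 10_000),
).map(lambda t: ContingencyTable2x2(*t))


class TestContingencyTable:
    def test_negative_or_fractional_cells_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 0, 0, 1)
        with pytest.raises(ValidationError):
            ContingencyTable2x2(1.5, 0, 0, 1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestBuildContingency:
    def _grid_pair(self, hits_a, hits_b):
        import datetime as dt

        from proximnet.datamodel import StudyConfig

        cfg = StudyConfig(
            study_start=dt.date(2015, 8, 17),
            study_end=dt.date(2015, 8, 17),
            office_start=dt.time(9, 0),
            office_end=dt.time(9, 20),
            timezone="UTC",
        )
        grid = build_grid(cfg)  # 4 bins
        hits_a = np.asarray(hits_a, bool)
        hits_b = np.asarray(hits_b, bool)
        dyads = [("P1", "P2"), ("P1", "P3"), ("P2", "P3")]
        sampled = np.ones_like(hits_a)
        ga = DetectionGrid("app", ("P1", "P2", "P3"), dyads, hits_a, sampled, grid)
        gb = DetectionGrid("badge", ("P1", "P2", "P3"), dyads, hits_b, sampled, grid)
        return ga, gb

    def test_identical_grids_have_no_disagreement(self):
        h = np.array([[1, 0, 1, 0], [0, 0, 0, 0], [1, 1, 0, 0]], bool)
        ga, gb = self._grid_pair(h, h)
        t = build_contingency(ga, gb, np.ones_like(h))
        assert t.b == t.c == 0
        assert t.a == 4 and t.d == 8

    def test_all_miss_reference(self):
        h = np.array([[1, 0, 1, 0], [0, 0, 0, 0], [1, 1, 0, 0]], bool)
        ga, gb = self._grid_pair(h, np.zeros_like(h))
        t = build_contingency(ga, gb, np.ones_like(h))
        assert t.a == 0 and t.c == 0
        assert t.b == 4 and t.d == 8

    def test_hand_cross_tabulation(self):
        """3 dyads x 4 bins cross-tabulated by hand."""
        ha = np.array([[1, 1, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1]], bool)
        hb = np.array([[1, 0, 0, 0], [1, 1, 0, 0], [0, 0, 0, 0]], bool)
        # cellwise: a = {(0,0),(1,1)} = 2; b = {(0,1),(2,3)} = 2;
        # c = {(1,0)} = 1; d = remaining 7
        ga, gb = self._grid_pair(ha, hb)
        t = build_contingency(ga, gb, np.ones_like(ha))
        assert (t.a, t.b, t.c, t.d) == (2, 2, 1, 7)

    def test_universe_mask_restricts_counts(self):
        ha = np.array([[1, 1, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1]], bool)
        hb = np.zeros_like(ha)
        ga, gb = self._grid_pair(ha, hb)
        mask = np.zeros_like(ha)
        mask[0] = True  # first dyad only
        t = build_contingency(ga, gb, mask)
        assert t.n == 4 and t.b == 2


class TestMarginalOdds:
    def test_reference_counts_office_hours(self):
        assert marginal_odds(OFFICE, "app") == pytest.approx(2.92, abs=0.005)
        assert marginal_odds(OFFICE, "badge") == pytest.approx(0.19, abs=0.005)

    def test_reference_counts_both_active(self):
        assert marginal_odds(ACTIVE, "app") == pytest.approx(8.55, abs=0.005)
        assert marginal_odds(ACTIVE, "badge") == pytest.approx(1.28, abs=0.005)

    def test_no_hits_is_zero(self):
        t = ContingencyTable2x2(0, 0, 1, 1)
        assert marginal_odds(t, "A") == 0.0

    def test_no_misses_is_infinite_signal(self):
        t = ContingencyTable2x2(1, 1, 0, 0)
        assert marginal_odds(t, "A") == math.inf


class TestOddsRatio:
    def test_arithmetic(self):
        assert odds_ratio(ContingencyTable2x2(2, 1, 1, 2)) == pytest.approx(4.0)

    def test_independence(self):
        assert odds_ratio(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_reference_counts(self):
        # (191 * 29252) / (2327 * 214) computed independently
        assert odds_ratio(ACTIVE) == pytest.approx(
            191 * 29252 / (2327 * 214), rel=1e-12
        )
        assert round(odds_ratio(ACTIVE), 2) == 11.22

    def test_zero_cells(self):
        assert odds_ratio(ContingencyTable2x2(1, 0, 1, 1)) == math.inf
        with pytest.raises(UndefinedStatisticError):
            odds_ratio(ContingencyTable2x2(0, 0, 1, 1))


class TestPhiAndChiSquare:
    def test_reference_values(self):
        assert round(phi_coefficient(OFFICE), 2) == 0.10
        assert round(phi_coefficient(ACTIVE), 2) == 0.17
        assert f"{chi_square(OFFICE)[0]:.1e}" == "2.5e+03"
        assert f"{chi_square(ACTIVE)[0]:.1e}" == "8.7e+02"
        assert chi_square(OFFICE)[1] < 1e-4
        assert chi_square(ACTIVE)[1] < 1e-4

    def test_perfect_diagonal(self):
        assert phi_coefficient(ContingencyTable2x2(10, 0, 0, 10)) == 1.0

    def test_balanced_table_is_null(self):
        t = ContingencyTable2x2(7, 7, 7, 7)
        assert phi_coefficient(t) == 0.0
        assert chi_square(t)[0] == 0.0

    def test_zero_margin_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            phi_coefficient(ContingencyTable2x2(1, 1, 0, 0))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(table=tables)
    def test_chi_square_equals_n_phi_squared(self, table):
        stat, _ = chi_square(table)
        phi = phi_coefficient(table)
        assert stat == pytest.approx(table.n * phi**2, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(table=tables)
    def test_phi_is_pearson_of_indicator_vectors(self, table):
        """Brute-force oracle: expand the table into paired 0/1 vectors."""
        x = np.repeat([1, 1, 0, 0], [table.a, table.b, table.c, table.d])
        y = np.repeat([1, 0, 1, 0], [table.a, table.b, table.c, table.d])
        expected = np.corrcoef(x, y)[0, 1]
        assert phi_coefficient(table) == pytest.approx(expected, rel=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(table=tables)
    def test_label_swap_leaves_association_invariant(self, table):
        sw = table.swapped()
        assert (sw.b, sw.c) == (table.c, table.b)
        assert phi_coefficient(sw) == pytest.approx(phi_coefficient(table))
        assert chi_square(sw)[0] == pytest.approx(chi_square(table)[0])

    def test_agrees_with_scipy_uncorrected(self):
        """Independent oracle: scipy's Pearson chi-square, no correction."""
        for t in (OFFICE, ACTIVE, ContingencyTable2x2(5, 9, 2, 30)):
            stat, p = chi_square(t)
            ref = chi2_contingency(
                [[t.a, t.b], [t.c, t.d]], correction=False
            )
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-300)


class TestSensitivitySpecificity:
    def test_perfect_agreement(self):
        assert sensitivity_specificity(ContingencyTable2x2(10, 0, 0, 10)) == (
            1.0,
            1.0,
        )

    def test_arithmetic(self):
        sens, spec = sensitivity_specificity(ContingencyTable2x2(0, 5, 5, 10))
        assert sens == 0.0
        assert spec == pytest.approx(10 / 15)

    def test_reference_counts(self):
        # 191/405 and 29252/31579 computed independently
        sens, spec = sensitivity_specificity(ACTIVE, reference_side="badge")
        assert sens == pytest.approx(191 / 405)
        assert spec == pytest.approx(29252 / 31579)
        assert (round(sens, 2), round(spec, 2)) == (0.47, 0.93)

    def test_no_reference_positives_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            sensitivity_specificity(ContingencyTable2x2(0, 5, 0, 10))


class TestOsSubgroups:
    def test_pair_class_labels(self):
        assert os_pair_class("android", "ios") == "android-ios"
        assert os_pair_class("ios", "android") == "android-ios"
        assert os_pair_class("ios", "ios") == "ios-ios"

    def test_partition_conservation(self, default_sim):
        """Subgroup tables sum cell-wise to the full table."""
        grid = build_grid(default_sim.config)
        ga = detection_grid(
            events_to_frame(default_sim.app_events),
            default_sim.devices,
            grid,
            "app",
        )
        gb = detection_grid(
            events_to_frame(default_sim.badge_events),
            default_sim.devices,
            grid,
            "badge",
        )
        full = build_contingency(ga, gb, ga.sampled)
        parts = os_subgroup_tables(ga, gb, default_sim.devices, ga.sampled)
        total = np.zeros(4, dtype=int)
        for t in parts.values():
            assert t is not None  # all three classes occur in the cohort
            total += np.array([t.a, t.b, t.c, t.d])
        assert tuple(total) == (full.a, full.b, full.c, full.d)

    def test_all_android_study_has_single_class(self, default_sim):
        from proximnet.datamodel import DeviceInfo, DeviceTable

        devices = DeviceTable(
            [
                DeviceInfo(f"P{i}-app", f"P{i}", "app", "android")
                for i in range(1, 4)
            ]
        )
        import datetime as dt

        from proximnet.datamodel import StudyConfig

        cfg = StudyConfig(
            study_start=dt.date(2015, 8, 17),
            study_end=dt.date(2015, 8, 17),
            timezone="UTC",
        )
        grid = build_grid(cfg)
        from conftest import ev

        events = [ev("P1-app", "09:02", "P2-app")]
        ga = detection_grid(events, devices, grid, "app")
        gb = detection_grid([], devices, grid, "app")
        gb = DetectionGrid("badge", gb.participants, gb.dyads, gb.hits, ga.sampled, grid)
        parts = os_subgroup_tables(ga, gb, devices, ga.sampled)
        assert parts["android-android"] is not None
        assert parts["ios-ios"] is None and parts["android-ios"] is None
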