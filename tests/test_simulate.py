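"""Properties of the synthetic study generator."""

import datetime as dt

import numpy as np
import pytest

from proximnet.activity import build_grid
from proximnet.datamodel import StudyConfig, events_to_frame
from proximnet.estimation import build_network, scan_stats
from proximnet.simulate import (
    SimulationParams,
    default_device_table,
    observe,
    simulate_colocation,
    simulate_study,
    survey_from_truth,
    ColocationTruth,
)


def short_config(days=5):
    return StudyConfig(
        study_start=dt.date(2015, 8, 17),
        study_end=dt.date(2015, 8, 17 + days - 1),
    )


class TestParams:
    def test_os_split_must_sum(self):
        with pytest.raises(Exception):
            SimulationParams(n_participants=21, n_android=5, n_ios=5)

    def test_badge_range_not_larger_than_app(self):
        with pytest.raises(Exception):
            SimulationParams(app_range_m=5.0, badge_range_m=10.0)


class TestColocation:
    def test_zero_session_rate_gives_empty_truth(self):
        params = SimulationParams(session_rate_per_hour=0.0, rng_seed=0)
        truth = simulate_colocation(params, short_config())
        assert truth.sessions == {}

    def test_sessions_lie_within_office_axis(self):
        params = SimulationParams(rng_seed=1)
        cfg = short_config()
        truth = simulate_colocation(params, cfg)
        total = build_grid(cfg).total_office_seconds
        for arr in truth.sessions.values():
            assert (arr[:, 0] >= 0).all() and (arr[:, 1] <= total).all()
            assert (arr[:, 1] >= arr[:, 0]).all()

    def test_default_colocation_is_sparse(self):
        """Pooled fraction of office-hour bins in range stays below 10%."""
        fractions = []
        for seed in range(5):
            params = SimulationParams(rng_seed=seed)
            cfg = short_config(10)
            grid = build_grid(cfg)
            truth = simulate_colocation(params, cfg)
            n_dyads = 21 * 20 // 2
            hit = sum(
                v.sum() for v in truth.in_range_bins(grid, params.app_range_m).values()
            )
            fractions.append(hit / (n_dyads * grid.n_bins))
        assert np.mean(fractions) < 0.10

    def test_in_range_time_merges_overlapping_sessions(self):
        truth = ColocationTruth(("P1", "P2"))
        truth.sessions[("P1", "P2")] = np.array(
            [[0.0, 100.0, 2.0], [50.0, 150.0, 2.0], [300.0, 400.0, 8.0]]
        )
        assert truth.in_range_seconds("P1", "P2", 10.0) == pytest.approx(250.0)
        assert truth.in_range_seconds("P1", "P2", 5.0) == pytest.approx(150.0)


class TestObserve:
    def test_determinism_byte_identical(self):
        a = simulate_study(SimulationParams(rng_seed=5), short_config())
        b = simulate_study(SimulationParams(rng_seed=5), short_config())
        assert a.app_events == b.app_events
        assert a.badge_events == b.badge_events
        assert a.survey == b.survey

    def test_zero_active_fraction_means_no_events(self):
        params = SimulationParams(
            app_active_fraction=(0.0, 0.0),
            android_scan_rate_per_h=(0.0, 0.0),
            ios_scan_rate_per_h=(0.0, 0.0),
            min_scan_rate_per_h=0.0,
            rng_seed=2,
        )
        truth = simulate_colocation(params, short_config())
        events = observe(truth, params, short_config(), "app")
        assert events == []

    def test_perfect_conditions_detect_every_scan(self):
        """detect_prob 1, always-active devices, one permanently in-range
        dyad: every scan by one partner detects the other."""
        cfg = short_config(2)
        grid = build_grid(cfg)
        params = SimulationParams(
            n_participants=2,
            n_android=2,
            n_ios=0,
            app_active_fraction=(1.0, 0.0),
            android_scan_rate_per_h=(12.0, 0.0),
            app_detect_prob_within_range=1.0,
            session_rate_per_hour=0.0,
            rng_seed=3,
        )
        truth = ColocationTruth(("P01", "P02"))
        truth.sessions[("P01", "P02")] = np.array(
            [[0.0, float(grid.total_office_seconds), 1.0]]
        )
        events = observe(truth, params, cfg, "app")
        assert events  # scans happened
        assert all(e.detected_id is not None for e in events)

    def test_range_gating_separates_modalities(self):
        """A dyad at 4 m is seen by the app (10 m range) and never by a
        3 m badge."""
        cfg = short_config(2)
        grid = build_grid(cfg)
        params = SimulationParams(
            n_participants=2,
            n_android=2,
            n_ios=0,
            app_active_fraction=(1.0, 0.0),
            badge_active_fraction=(1.0, 0.0),
            android_scan_rate_per_h=(12.0, 0.0),
            app_detect_prob_within_range=1.0,
            badge_detect_prob_within_range=1.0,
            badge_range_m=3.0,
            session_rate_per_hour=0.0,
            rng_seed=4,
        )
        truth = ColocationTruth(("P01", "P02"))
        truth.sessions[("P01", "P02")] = np.array(
            [[0.0, float(grid.total_office_seconds), 4.0]]
        )
        app_events = observe(truth, params, cfg, "app")
        badge_events = observe(truth, params, cfg, "badge")
        assert any(e.detected_id for e in app_events)
        assert not any(e.detected_id for e in badge_events)

    def test_scan_rate_calibration_over_replicates(self):
        """Realized scans/hour per OS match the configured means to within
        three Monte-Carlo standard errors over 20 replicates."""
        cfg = short_config(10)
        grid = build_grid(cfg)
        per_rep = {"android": [], "ios": []}
        for seed in range(20):
            params = SimulationParams(rng_seed=1000 + seed)
            devices = default_device_table(params)
            truth = simulate_colocation(params, cfg)
            events = observe(truth, params, cfg, "app", devices)
            stats = scan_stats(events_to_frame(events), devices, grid)
            for os_name in per_rep:
                rates = [
                    stats.scans_per_hour[p]
                    for p in stats.participants
                    if devices.device_of(p, "app").os == os_name
                ]
                per_rep[os_name].append(np.mean(rates))
        from scipy.stats import truncnorm

        for os_name, (mu, sd) in (
            ("android", (5.6, 3.8)),
            ("ios", (1.1, 0.8)),
        ):
            # devices draw rates from this truncated normal: its mean is
            # the configured target of the realized office-hour rate
            target = truncnorm.mean(
                (0.1 - mu) / sd, (12.0 - mu) / sd, loc=mu, scale=sd
            )
            reps = np.asarray(per_rep[os_name])
            se = reps.std(ddof=1) / np.sqrt(len(reps))
            assert abs(reps.mean() - target) < 3 * se


class TestSurveyFromTruth:
    def _truth(self, totals):
        """Truth with given per-partner in-range seconds for ego P1."""
        participants = tuple(sorted({"P1"} | set(totals)))
        truth = ColocationTruth(participants)
        for other, seconds in totals.items():
            key = tuple(sorted(("P1", other)))
            truth.sessions[key] = np.array([[0.0, float(seconds), 1.0]])
        return truth

    def test_isolated_ego_has_no_alters(self):
        truth = ColocationTruth(("P1", "P2"))
        (r1, _) = survey_from_truth(truth)
        assert r1.alters == ()

    def test_top_five_of_six_partners(self):
        totals = {f"P{i}": 100.0 * i for i in range(2, 8)}  # P2..P7
        truth = self._truth(totals)
        r1 = next(r for r in survey_from_truth(truth) if r.ego == "P1")
        assert set(r1.alters) == {"P3", "P4", "P5", "P6", "P7"}
        assert r1.alters[0] == "P7"  # strongest first

    def test_tie_broken_by_token_order(self):
        totals = {"P2": 500.0, "P3": 100.0, "P4": 100.0}
        truth = self._truth(totals)
        r1 = next(r for r in survey_from_truth(truth, k=2) if r.ego == "P1")
        assert r1.alters == ("P2", "P3")  # P3 < P4 at equal time


class TestStructureRecovery:
    def test_app_network_tracks_truth_better_at_higher_scan_rates(self):
        """Spearman(truth, estimate) grows with configured scan rate."""
        from scipy.stats import spearmanr

        cfg = short_config(10)
        grid = build_grid(cfg)

        def mean_rho(rate_scale, seeds):
            rhos = []
            for seed in seeds:
                params = SimulationParams(
                    android_scan_rate_per_h=(5.6 * rate_scale, 0.5),
                    ios_scan_rate_per_h=(1.1 * rate_scale, 0.2),
                    rng_seed=2000 + seed,
                )
                devices = default_device_table(params)
                truth = simulate_colocation(params, cfg)
                events = observe(truth, params, cfg, "app", devices)
                net = build_network(
                    events_to_frame(events), devices, grid, "app",
                    scheme="eq1_strength",
                )
                tw = np.zeros_like(net.weights)
                for i, pi in enumerate(net.nodes):
                    for j in range(i + 1, len(net.nodes)):
                        tw[i, j] = truth.in_range_seconds(
                            pi, net.nodes[j], params.app_range_m
                        )
                iu = np.triu_indices(len(net.nodes), 1)
                rhos.append(spearmanr(net.weights[iu], tw[iu]).statistic)
            return float(np.mean(rhos)), rhos

        low, _ = mean_rho(0.2, range(6))
        high, highs = mean_rho(1.0, range(6))
        assert min(highs) > 0
        assert high > low
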