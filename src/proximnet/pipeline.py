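"""One-command end-to-end run and the printed-table entry point.

The pipeline executes the full analysis in dependency order —
simulate (or ingest) -> activity reconstruction -> detection grids and
networks -> pooled concordance -> cross-modality comparison -> scan-rate
bias curve — writing CSV artifacts plus a JSON report whose every number
is regenerable from the config and seed.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import active_fraction, all_timelines, build_grid
from .comparison import backbone_at_density, collapse_directed, edge_overlap, mantel
from .concordance import (
    ContingencyTable2x2,
    both_modalities_active_mask,
    build_contingency,
    chi_square,
    marginal_odds,
    odds_ratio,
    os_subgroup_tables,
    phi_coefficient,
    sensitivity_specificity,
)
from .datamodel import StudyConfig, ValidationError, events_to_frame
from .estimation import build_network, detection_grid, scan_stats
from .io import (
    read_devices,
    read_scan_log,
    read_survey,
    write_devices,
    write_network,
    write_scan_log,
    write_survey,
)
from .resampling import curve_frame, resample_curve
from .simulate import SimulationParams, simulate_study

logger = logging.getLogger(__name__)

DEFAULT_ANALYSIS = {
    "n_perm": 1000,
    "n_boot": 500,
    "resample_counts": [10, 50, 100, 250, 500],
    "resample_reps": 100,
}


def table_statistics(table: ContingencyTable2x2) -> dict:
    """All concordance statistics of one pooled 2x2 table."""
    stat, p = chi_square(table)
    sens, spec = sensitivity_specificity(table, reference_side="B")
    return {
        "counts": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "n": table.n,
        "phi": phi_coefficient(table),
        "chi_square": stat,
        "p_value": p,
        "odds_ratio": odds_ratio(table),
        "marginal_odds_pct_A": marginal_odds(table, "A"),
        "marginal_odds_pct_B": marginal_odds(table, "B"),
        "sensitivity": sens,
        "specificity": spec,
    }


def reproduce_tables(path_to_counts=None) -> dict:
    """Recompute the concordance statistics from printed 2x2 counts.

    ``path_to_counts`` is a CSV ``table,a,b,c,d``; by default the
    reference counts bundled with the package (pooled app-vs-badge
    detection tables over all office hours and over both-devices-active
    intervals of the motivating 21-participant study) are used.
    """
    if path_to_counts is None:
        src = resources.files("proximnet").joinpath("data/contingency_tables.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path_to_counts)
    out = {}
    for row in df.itertuples(index=False):
        cells = {}
        for cell in "abcd":
            v = getattr(row, cell)
            if float(v) != int(v):
                raise ValidationError(f"non-integer count {cell}={v!r}")
            cells[cell] = int(v)
        table = ContingencyTable2x2(**cells, label_a="app", label_b="badge")
        out[str(row.table)] = table_statistics(table)
    return out


def _load_pipeline_config(config_path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("simulate", True)
    cfg.setdefault("seed", 0)
    analysis = dict(DEFAULT_ANALYSIS)
    analysis.update(cfg.get("analysis") or {})
    cfg["analysis"] = analysis
    return cfg


def run_pipeline(config_path, output_dir=None) -> dict:
    """Execute the full pipeline described by a YAML config.

    Returns the report dict (also written to ``report.json``).  All
    randomness is fanned out from the single configured seed, so the same
    config produces byte-identical outputs.
    """
    cfg = _load_pipeline_config(config_path)
    out_dir = Path(output_dir or cfg.get("output_dir") or "proximnet-out")
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    study = StudyConfig.from_dict({**(cfg.get("study") or {}), "rng_seed": seed})
    grid = build_grid(study)

    if cfg["simulate"]:
        sim_kwargs = dict(cfg.get("simulation") or {})
        sim_kwargs["rng_seed"] = seed
        params = SimulationParams(**sim_kwargs)
        sim = simulate_study(params, study)
        devices = sim.devices
        app_events, badge_events, survey = (
            sim.app_events,
            sim.badge_events,
            sim.survey,
        )
        write_devices(devices, out_dir / "devices.csv")
        write_scan_log(app_events, out_dir / "app_log.csv")
        write_scan_log(badge_events, out_dir / "badge_log.csv")
        write_survey(survey, out_dir / "survey.csv")
    else:
        inputs = cfg.get("inputs") or {}
        required = ["devices", "app_log", "badge_log", "survey"]
        missing = [k for k in required if k not in inputs]
        if missing:
            raise ValidationError(
                f"simulate is false but inputs lack {missing}"
            )
        devices = read_devices(inputs["devices"])
        app_events = read_scan_log(inputs["app_log"], devices)
        badge_events = read_scan_log(inputs["badge_log"], devices)
        survey = read_survey(inputs["survey"])

    app_frame = events_to_frame(app_events)
    badge_frame = events_to_frame(badge_events)

    # --- activity -----------------------------------------------------
    tl_app = all_timelines(app_frame, devices.of_modality("app"), grid)
    tl_badge = all_timelines(badge_frame, devices.of_modality("badge"), grid)
    fractions = pd.DataFrame(
        [
            {
                "device_id": dev_id,
                "participant_id": devices.get(dev_id).participant_id,
                "modality": devices.get(dev_id).modality,
                "active_fraction": active_fraction(tl),
            }
            for dev_id, tl in {**tl_app, **tl_badge}.items()
        ]
    ).sort_values(["modality", "device_id"])
    fractions.to_csv(out_dir / "active_fractions.csv", index=False)

    stats_app = scan_stats(app_frame, devices, grid)

    # --- networks -----------------------------------------------------
    nets = {}
    for modality, frame, tls in (
        ("app", app_frame, tl_app),
        ("badge", badge_frame, tl_badge),
    ):
        for restriction in ("office_hours", "both_active"):
            net = build_network(
                frame,
                devices,
                grid,
                modality,
                scheme="time_fraction",
                restriction=restriction,
                timelines=tls,
            )
            nets[(modality, restriction)] = net
            write_network(net, out_dir / f"net_{modality}_{restriction}.csv")
    app_eq1 = build_network(
        app_frame, devices, grid, "app", scheme="eq1_strength"
    )
    write_network(app_eq1, out_dir / "net_app_eq1.csv")

    # --- concordance --------------------------------------------------
    grid_app = detection_grid(app_frame, devices, grid, "app")
    grid_badge = detection_grid(badge_frame, devices, grid, "badge")
    table_office = build_contingency(grid_app, grid_badge, grid_app.sampled)
    ba_mask = both_modalities_active_mask(grid_app, tl_app, tl_badge, devices)
    table_active = build_contingency(
        grid_app, grid_badge, grid_app.sampled & ba_mask
    )
    subgroup = os_subgroup_tables(
        grid_app, grid_badge, devices, grid_app.sampled & ba_mask
    )
    concordance_report = {
        "office_hours": table_statistics(table_office),
        "both_active": table_statistics(table_active),
        "os_subgroups": {
            cls: (None if t is None else table_statistics(t))
            for cls, t in subgroup.items()
        },
    }

    # --- comparison ---------------------------------------------------
    analysis = cfg["analysis"]
    nodes = nets[("app", "office_hours")].nodes
    survey_net = collapse_directed(survey, nodes)
    backbones = {}
    target = survey_net.density()
    for modality in ("app", "badge"):
        if target > 0:
            bb = backbone_at_density(nets[(modality, "office_hours")], target)
            backbones[modality] = bb
            write_network(bb.network, out_dir / f"backbone_{modality}.csv")

    def _mantel(x, y, salt):
        return mantel(
            x,
            y,
            n_perm=int(analysis["n_perm"]),
            n_boot=int(analysis["n_boot"]),
            seed=np.random.default_rng([seed, salt]),
        )

    comparisons = {}
    m_ab = _mantel(
        nets[("app", "office_hours")], nets[("badge", "office_hours")], 21
    )
    comparisons["app_badge_weighted"] = _mantel_dict(m_ab)
    if backbones:
        m_as = _mantel(backbones["app"].network, survey_net, 22)
        m_bs = _mantel(backbones["badge"].network, survey_net, 23)
        comparisons["app_survey_backbone"] = _mantel_dict(m_as)
        comparisons["badge_survey_backbone"] = _mantel_dict(m_bs)
        comparisons["edge_overlap"] = {
            "app_vs_survey": edge_overlap(backbones["app"].network, survey_net),
            "badge_vs_survey": edge_overlap(
                backbones["badge"].network, survey_net
            ),
        }
        comparisons["backbone"] = {
            mod: {
                "alpha_used": bb.alpha_used,
                "achieved_density": bb.achieved_density,
                "target_density": bb.target_density,
            }
            for mod, bb in backbones.items()
        }

    # --- resampling bias curve ---------------------------------------
    curve = resample_curve(
        app_frame,
        devices,
        grid,
        nets[("badge", "office_hours")],
        survey_net,
        counts=tuple(int(m) for m in analysis["resample_counts"]),
        n_rep=int(analysis["resample_reps"]),
        seed=seed,
    )
    curve_frame(curve).to_csv(out_dir / "resample_curve.csv", index=False)

    report = {
        "version": __version__,
        "seed": seed,
        "config": {
            "study": study.to_dict(),
            "simulate": bool(cfg["simulate"]),
            "analysis": analysis,
        },
        "outputs": {
            "active_fractions": "active_fractions.csv",
            "networks": sorted(
                f"net_{m}_{r}.csv" for (m, r) in nets
            )
            + ["net_app_eq1.csv"],
            "resample_curve": "resample_curve.csv",
        },
        "activity": {
            "mean_active_fraction": {
                mod: float(
                    fractions.loc[
                        fractions["modality"] == mod, "active_fraction"
                    ].mean()
                )
                for mod in ("app", "badge")
            }
        },
        "scanning": {
            "mean_scans_per_hour": {
                os_name: float(
                    np.mean(
                        [
                            stats_app.scans_per_hour[p]
                            for p in stats_app.participants
                            if devices.device_of(p, "app").os == os_name
                        ]
                    )
                )
                for os_name in ("android", "ios")
            },
            "dyad_rate_ge_1_per_h": stats_app.dyad_rate_fraction_at_least(1.0),
            "dyad_rate_ge_4_per_h": stats_app.dyad_rate_fraction_at_least(4.0),
        },
        "concordance": concordance_report,
        "comparisons": comparisons,
        "network_density": {
            "app_weighted": nets[("app", "office_hours")].density(),
            "badge_weighted": nets[("badge", "office_hours")].density(),
            "survey": survey_net.density(),
        },
        "resample_curve": {
            "m": curve.sample_counts,
            "n_nodes": curve.n_nodes,
            "rho_app_badge_median": [
                d["median"] for d in curve.rho_app_badge
            ],
        },
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return report


def _mantel_dict(m) -> dict:
    return {
        "rho": m.rho,
        "p": m.p,
        "n_perm": m.n_perm,
        "ci95": list(m.ci95),
        "n_boot": m.n_boot,
    }
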