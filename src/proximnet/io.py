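"""Readers and writers for the on-disk CSV/YAML formats.

Scan logs are CSV with header ``scanner_id,timestamp,detected_id`` and
ISO-8601 UTC timestamps; ``detected_id`` is empty for a scan that found
nothing.  Surveys are CSV ``ego,alter1..alter5``.  Networks are written as
a labelled square matrix with a one-line ``# weight_kind:`` sidecar header
so the round trip is lossless.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    DeviceInfo,
    DeviceTable,
    ParseError,
    ScanEvent,
    StudyConfig,
    SurveyResponse,
    ValidationError,
    WeightedNetwork,
)

logger = logging.getLogger(__name__)

SCAN_LOG_COLUMNS = ["scanner_id", "timestamp", "detected_id"]


def read_scan_log(path, device_table: DeviceTable | None = None) -> list[ScanEvent]:
    """Parse a scan-log CSV into events, preserving row order.

    Detections of devices absent from ``device_table`` are retained but
    flagged ``unknown_device`` (real logs contain non-participant devices,
    which the analysis drops later).  A malformed timestamp raises a
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCAN_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"scan log {path} lacks columns {missing}", line=1)
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: 1-based lines and the header row
        raise ParseError(
            f"malformed timestamp {df['timestamp'].iloc[bad[0]]!r}",
            line=int(bad[0]) + 2,
        )
    events = []
    n_unknown = 0
    for scanner, t, det in zip(df["scanner_id"], ts, df["detected_id"]):
        det = det if det != "" else None
        unknown = False
        if device_table is not None:
            unknown = (scanner not in device_table) or (
                det is not None and det not in device_table
            )
            n_unknown += unknown
        events.append(
            ScanEvent(
                scanner_id=scanner, timestamp=t, detected_id=det, unknown_device=unknown
            )
        )
    if n_unknown:
        logger.info("%s: %d events reference unknown devices", path, n_unknown)
    return events


def write_scan_log(events, path) -> None:
    rows = [
        {
            "scanner_id": e.scanner_id,
            "timestamp": e.timestamp.tz_convert("UTC").isoformat(),
            "detected_id": e.detected_id or "",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=SCAN_LOG_COLUMNS).to_csv(path, index=False)


def read_survey(path) -> list[SurveyResponse]:
    """Parse a name-generator survey CSV.

    Blank alter cells are dropped; a self-nomination is removed with a
    logged warning rather than rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "ego" not in df.columns:
        raise ParseError(f"survey {path} lacks an 'ego' column", line=1)
    alter_cols = [c for c in df.columns if c.startswith("alter")]
    extra = alter_cols[5:]
    if extra and (df[extra] != "").any().any():
        raise ValidationError(
            f"survey {path} has more than five populated alter columns"
        )
    responses = []
    for idx, row in df.iterrows():
        alters = [row[c] for c in alter_cols[:5] if row[c] != ""]
        if row["ego"] in alters:
            logger.warning(
                "survey row %d: ego %s nominated themselves; dropped",
                idx + 2,
                row["ego"],
            )
            alters = [a for a in alters if a != row["ego"]]
        # keep first occurrence of duplicate nominations
        alters = list(dict.fromkeys(alters))
        responses.append(SurveyResponse(ego=row["ego"], alters=tuple(alters)))
    return responses


def write_survey(responses, path) -> None:
    cols = ["ego"] + [f"alter{i}" for i in range(1, 6)]
    rows = []
    for r in responses:
        alters = list(r.alters) + [""] * (5 - len(r.alters))
        rows.append([r.ego] + alters)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_devices(path) -> DeviceTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["device_id", "participant_id", "modality", "os"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"device table {path} lacks columns {missing}", line=1)
    return DeviceTable(
        DeviceInfo(
            device_id=r.device_id,
            participant_id=r.participant_id,
            modality=r.modality,
            os=r.os or "none",
        )
        for r in df.itertuples(index=False)
    )


def write_devices(table: DeviceTable, path) -> None:
    pd.DataFrame(
        [
            {
                "device_id": d.device_id,
                "participant_id": d.participant_id,
                "modality": d.modality,
                "os": d.os,
            }
            for d in table
        ]
    ).to_csv(path, index=False)


def write_network(net: WeightedNetwork, path) -> None:
    """Write a network as `# weight_kind: <kind>` plus a labelled matrix."""
    path = Path(path)
    df = pd.DataFrame(net.weights, index=list(net.nodes), columns=list(net.nodes))
    with open(path, "w") as fh:
        fh.write(f"# weight_kind: {net.weight_kind}\n")
        df.to_csv(fh, float_format="%.17g")


def read_network(path) -> WeightedNetwork:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# weight_kind:"):
            raise ParseError(f"{path} lacks the weight_kind header", line=1)
        kind = header.split(":", 1)[1].strip()
        df = pd.read_csv(fh, index_col=0, float_precision="round_trip")
    nodes = [str(n) for n in df.index]
    if nodes != [str(c) for c in df.columns]:
        raise ValidationError(f"{path}: row and column labels differ")
    return WeightedNetwork(nodes, df.to_numpy(dtype=float), kind)


def read_config(path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return StudyConfig.from_dict(data)


def write_config(config: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
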