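import datetime as dt

import pandas as pd
import pytest

from proximnet.datamodel import DeviceInfo, DeviceTable, ScanEvent, StudyConfig
from proximnet.simulate import SimulationParams, simulate_study


@pytest.fixture
def one_day_config() -> StudyConfig:
    """Single office day in UTC so fixture timestamps read literally."""
    return StudyConfig(
        study_start=dt.date(2015, 8, 17),
        study_end=dt.date(2015, 8, 17),
        timezone="UTC",
    )


@pytest.fixture
def three_apps() -> DeviceTable:
    return DeviceTable(
        [
            DeviceInfo("P1-app", "P1", "app", "android"),
            DeviceInfo("P2-app", "P2", "app", "ios"),
            DeviceInfo("P3-app", "P3", "app", "ios"),
        ]
    )


def ev(scanner: str, hhmm: str, detected: str | None = None) -> ScanEvent:
    """Scan event on the fixture day 2015-08-17 (UTC office hours)."""
    return ScanEvent(
        scanner_id=scanner,
        timestamp=pd.Timestamp(f"2015-08-17 {hhmm}:00", tz="UTC"),
        detected_id=detected,
    )


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic study at the default 21-participant conditions."""
    return simulate_study(SimulationParams(rng_seed=123))
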