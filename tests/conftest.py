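import numpy as np
import pandas as pd
import pytest

from svadetect import PipelineConfig, SynthConfig, generate_site
from svadetect.ec_io import SiteSeries, apply_filters
from svadetect.eve_templates import default_library

#: VWC_RH80 values of the compact template library used across tests.
LIBRARY_VALUES = [2.31, 4.20, 8.08, 11.0]


@pytest.fixture(scope="session")
def library():
    return default_library(LIBRARY_VALUES)


@pytest.fixture(scope="session")
def pipe_cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def synthetic_site():
    """One default synthetic site plus ground truth (seed fixed)."""
    return generate_site(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_site():
    """Synthetic site with all flux noise and dew disabled."""
    cfg = SynthConfig(seed=7, night_noise_sd=0.0, day_noise_sd=0.0, dew_enabled=False)
    return generate_site(cfg)


def make_series(rha, vwc, le, night=True, site_id="T") -> SiteSeries:
    """Minimal valid series from parallel arrays, for classifier unit tests."""
    n = len(rha)
    ts = pd.date_range("2015-01-01", periods=n, freq="30min")
    df = pd.DataFrame(
        {
            "timestamp": ts,
            "le": np.asarray(le, float),
            "le_qc": 0,
            "vpd": 0.5,
            "ta": 15.0,
            "vwc": np.asarray(vwc, float),
            "precip": 0.0,
            "night": night,
            "rha": np.asarray(rha, float),
            "valid": True,
            "invalid_reason": "",
        }
    )
    return SiteSeries(site_id=site_id, records=df)


@pytest.fixture()
def filtered_synthetic(synthetic_site):
    series, truth = synthetic_site
    flagged, report = apply_filters(series)
    return flagged, truth, report
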