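import numpy as np
import pandas as pd
import pytest

from noctidip import CircadianHRSpec, generate_rr_series
from noctidip.hrv import CircadianProfile


def make_series_1hz(start="2021-03-01 00:00", hours=48.0, rr_ms=1000.0, patient_id="p1"):
    """Gap-free series with constant RR, built directly (no generator)."""
    from noctidip.ingest import BeatSeries

    n = int(hours * 3600_000 / rr_ms)
    t0 = np.datetime64(pd.Timestamp(start), "ns")
    times = t0 + (np.arange(n) * int(rr_ms * 1e6)).astype("timedelta64[ns]")
    return BeatSeries(patient_id, times, np.full(n, rr_ms), np.full(n, "N", dtype="U1"))


def make_profile(values, counts=None, patient_id="p1", metric="hr"):
    values = np.asarray(values, dtype=float)
    if counts is None:
        counts = np.where(np.isnan(values), 0, 12).astype(int)
    return CircadianProfile(patient_id, metric, values, np.asarray(counts, dtype=int))


@pytest.fixture(scope="session")
def quiet_spec():
    """Noise-free, oscillation-free circadian spec (pure dip structure)."""
    return CircadianHRSpec(
        baseline_day_hr=70.0,
        dip_fraction=0.10,
        lf_amplitude_ms=0.0,
        hf_amplitude_ms=0.0,
        noise_sd_ms=0.0,
    )


@pytest.fixture(scope="session")
def quiet_series_48h(quiet_spec):
    return generate_rr_series(quiet_spec, "2021-03-01 08:00", 48.0, seed=11)
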