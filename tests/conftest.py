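import numpy as np
import pandas as pd
import pytest

from coastnoise.band_analysis import TolSeries, tol_bands
from coastnoise.io_calibration import CalibratedRecording, StationGeometry

T0 = pd.Timestamp("2016-08-15T08:00:00")


@pytest.fixture
def geom():
    """Shore station 47 m up, recorder a short way offshore."""
    return StationGeometry(
        station_lat=56.10,
        station_lon=10.54,
        eye_height=47.0,
        recorder_lat=56.0983,
        recorder_lon=10.54,
        recorder_depth=7.5,
        water_depth=9.0,
    )


@pytest.fixture
def analysis_bands():
    return tol_bands(63.0, 125_000.0)


def make_recording(samples, fs, clip_db=172.0, start=T0):
    return CalibratedRecording(
        samples=np.asarray(samples, dtype=float),
        sample_rate=fs,
        start_time=start,
        clip_level_db=clip_db,
    )


def sine_recording(freq_hz, level_db_rms, fs, dur_s, clip_db=172.0):
    """Pure tone at an exact RMS level in dB re 1 µPa."""
    t = np.arange(int(round(fs * dur_s))) / fs
    amp = 10.0 ** (level_db_rms / 20.0) * np.sqrt(2.0)
    return make_recording(amp * np.sin(2 * np.pi * freq_hz * t), fs, clip_db)


def make_tol_series(levels, centres=(125.0, 2000.0, 16000.0), start=T0):
    """TolSeries from a (n_epochs, n_bands) array at the analysis bands."""
    levels = np.atleast_2d(np.asarray(levels, dtype=float))
    all_bands = tol_bands(min(centres), max(centres))
    bands = [b for b in all_bands if any(np.isclose(b.nominal_centre, c) for c in centres)]
    assert len(bands) == len(centres)
    epochs = pd.date_range(start, periods=levels.shape[0], freq="1s")
    return TolSeries(epochs, bands, levels)
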