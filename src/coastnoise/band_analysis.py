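"""Third-octave (decidecade) band levels, spectrograms, M-weighting and
ambient statistics.

Levels follow underwater-acoustics convention: dB re 1 µPa for sound
pressure levels, dB re 1 µPa²/Hz for spectral densities. Bands are base-10
third octaves (decidecades), exact centre 10^(n/10)·1 kHz with the standard
preferred-number nominal centres (63, 80, 100, 125, ... Hz).

TOLs are computed by FFT band-energy summation per non-overlapping window:
Parseval ties the band sum exactly to the mean-square pressure, which makes
the computation directly checkable against analytic tone and white-noise
levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .io_calibration import CalibratedRecording, ConfigError

logger = logging.getLogger(__name__)

#: R10 preferred numbers: nominal decidecade centres within one decade.
_PREFERRED = (1.0, 1.25, 1.6, 2.0, 2.5, 3.15, 4.0, 5.0, 6.3, 8.0)

#: Level assigned to zero band power (digital silence); far below any
#: physical ambient level, used as the "below floor" flag value.
SILENCE_FLOOR_DB = -np.inf

#: Recorder self-noise (dB re 1 µPa RMS) at the three analysis bands,
#: kept as a QC floor only — levels are flagged, never clipped.
SELF_NOISE_FLOOR_DB = {125.0: 66.0, 2000.0: 60.0, 16000.0: 66.0}


@dataclass(frozen=True)
class BandSpec:
    """One decidecade band: nominal centre plus exact edges."""

    nominal_centre: float
    exact_centre: float
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (self.f_low < self.exact_centre < self.f_high):
            raise ValueError("band edges must bracket the exact centre")

    @property
    def bandwidth(self) -> float:
        return self.f_high - self.f_low


def tol_bands(f_min: float, f_max: float) -> list[BandSpec]:
    """All decidecade bands whose *nominal* centre lies in [f_min, f_max].

    Exact centres are 10^(n/10) Hz for integer band number n; nominal
    centres follow the preferred series (…, 63, 80, 100, 125, … Hz);
    edges are exact_centre·10^(±1/20).
    """
    if f_min > f_max:
        raise ValueError("f_min must not exceed f_max")
    if f_min <= 0:
        raise ValueError("f_min must be positive")
    bands = []
    n_lo = int(np.floor(10 * np.log10(f_min))) - 1
    n_hi = int(np.ceil(10 * np.log10(f_max))) + 1
    for n in range(n_lo, n_hi + 1):
        decade, pos = divmod(n, 10)
        nominal = _PREFERRED[pos] * 10.0**decade
        if f_min <= nominal <= f_max:
            centre = 10.0 ** (n / 10.0)
            half = 10.0 ** (1.0 / 20.0)
            bands.append(BandSpec(nominal, centre, centre / half, centre * half))
    return bands


def find_band(bands: list[BandSpec], centre: float) -> BandSpec:
    """Select a band by nominal (or exact) centre frequency."""
    for b in bands:
        if np.isclose(b.nominal_centre, centre, rtol=1e-6) or np.isclose(
            b.exact_centre, centre, rtol=1e-6
        ):
            return b
    raise KeyError(f"no band with centre {centre} Hz")


@dataclass
class TolSeries:
    """Per-second third-octave levels: epochs × bands, dB re 1 µPa RMS."""

    epoch_times: pd.DatetimeIndex
    bands: list[BandSpec]
    levels: np.ndarray  # (n_epochs, n_bands)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.shape != (len(self.epoch_times), len(self.bands)):
            raise ValueError("levels shape does not match epochs × bands")

    def band_index(self, centre: float) -> int:
        return self.bands.index(find_band(self.bands, centre))

    def band_levels(self, centre: float) -> np.ndarray:
        return self.levels[:, self.band_index(centre)]

    def below_floor(self) -> np.ndarray:
        """Boolean mask of level cells flagged below the silence floor."""
        return ~np.isfinite(self.levels)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: epoch_time, band_centre_hz, level_db."""
        n_e, n_b = self.levels.shape
        return pd.DataFrame(
            {
                "epoch_time": np.repeat(self.epoch_times.values, n_b),
                "band_centre_hz": np.tile([b.nominal_centre for b in self.bands], n_e),
                "level_db": self.levels.ravel(),
            }
        )


@dataclass
class WeightedLevelSeries:
    """Sliding-window weighted broadband levels, dB re 1 µPa RMS."""

    epoch_times: pd.DatetimeIndex
    levels: np.ndarray
    window_s: float
    passband: tuple[float, float]
    weighting_name: str = "M_hf_cetacean"


def _window_mean_square_spectrum(x: np.ndarray, n_win: int, n_samp: int):
    """Mean-square contributions per rfft bin for each window.

    Returns (n_win, n_bins) array whose row sums equal the mean-square
    pressure of that window (Parseval, one-sided with DC/Nyquist handling).
    """
    frames = x[: n_win * n_samp].reshape(n_win, n_samp)
    spec = np.fft.rfft(frames, axis=1)
    power = (np.abs(spec) ** 2) / (n_samp * n_samp)
    power[:, 1:] *= 2.0
    if n_samp % 2 == 0:
        power[:, -1] /= 2.0
    return power


def compute_tol_series(
    rec: CalibratedRecording, bands: list[BandSpec], window_s: float = 1.0
) -> TolSeries:
    """Band RMS levels per non-overlapping window (default 1 s).

    A trailing partial window is dropped. Zero band power (digital silence)
    is flagged below-floor as −inf rather than raising.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    nyquist = rec.sample_rate / 2.0
    for b in bands:
        if b.f_high > nyquist:
            raise ConfigError(
                f"band {b.nominal_centre} Hz upper edge {b.f_high:.1f} Hz exceeds Nyquist {nyquist:.1f} Hz"
            )
    n_samp = int(round(window_s * rec.sample_rate))
    n_win = rec.samples.size // n_samp
    if n_win == 0:
        raise ValueError("recording shorter than one analysis window")
    power = _window_mean_square_spectrum(rec.samples, n_win, n_samp)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / rec.sample_rate)
    band_ms = np.empty((n_win, len(bands)))
    for j, b in enumerate(bands):
        sel = (freqs >= b.f_low) & (freqs < b.f_high)
        band_ms[:, j] = power[:, sel].sum(axis=1)
    with np.errstate(divide="ignore"):
        levels = 10.0 * np.log10(band_ms)
    epochs = rec.start_time + pd.to_timedelta(np.arange(n_win) * window_s, unit="s")
    return TolSeries(pd.DatetimeIndex(epochs), list(bands), levels)


def psd_spectrogram(rec: CalibratedRecording, window_s: float = 1.0, overlap: float = 0.5):
    """Power spectral density spectrogram, dB re 1 µPa²/Hz.

    Hann window; ``overlap`` is the fractional window overlap. Returns
    (freqs_hz, times_s, psd_db) with per-1-Hz density normalisation.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    nperseg = int(round(window_s * rec.sample_rate))
    if nperseg > rec.samples.size:
        raise ValueError("window longer than recording")
    noverlap = int(round(overlap * nperseg))
    f, t, sxx = sps.spectrogram(
        rec.samples,
        fs=rec.sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        scaling="density",
        mode="psd",
    )
    with np.errstate(divide="ignore"):
        psd_db = 10.0 * np.log10(sxx)
    return f, t, psd_db


# --- M-weighting (high-frequency cetaceans) --------------------------------

#: Corner frequencies (Hz) of the high-frequency-cetacean M-weighting,
#: the functional hearing group containing the harbour porpoise.
M_HF_LOW_CORNER = 200.0
M_HF_HIGH_CORNER = 180_000.0


def m_weighting_gain_db(
    f, low_corner: float = M_HF_LOW_CORNER, high_corner: float = M_HF_HIGH_CORNER
):
    """M-weighting gain in dB at frequency f (array-friendly).

    Two-pole high-pass at ``low_corner`` and two-pole low-pass at
    ``high_corner``; gain is normalised so the plateau maximum is 0 dB and
    is therefore ≤ 0 everywhere.
    """
    f = np.asarray(f, dtype=float)
    a2, b2 = low_corner**2, high_corner**2

    def raw(fr):
        fr2 = fr**2
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(b2 * fr2 / ((fr2 + a2) * (fr2 + b2)))

    peak = raw(np.sqrt(low_corner * high_corner))  # maximum of the response
    return raw(f) - peak


def m_weighted_level(
    rec: CalibratedRecording,
    f_lo: float = 25.0,
    f_hi: float = 80_000.0,
    window_s: float = 30.0,
    hop_s: float = 1.0,
    low_corner: float = M_HF_LOW_CORNER,
    high_corner: float = M_HF_HIGH_CORNER,
) -> WeightedLevelSeries:
    """M-weighted broadband level over sliding windows.

    The passband [f_lo, f_hi] is applied as a hard band limit, the
    M-weighting as a spectral gain, and the RMS taken over ``window_s``
    sliding windows advanced by ``hop_s``.
    """
    nyq = rec.sample_rate / 2.0
    if not (0 <= f_lo < f_hi <= nyq):
        raise ValueError(f"passband [{f_lo}, {f_hi}] invalid for Nyquist {nyq}")
    n_hop = int(round(hop_s * rec.sample_rate))
    n_hops = rec.samples.size // n_hop
    hops_per_window = int(round(window_s / hop_s))
    if n_hops < hops_per_window:
        warnings.warn("recording shorter than one weighting window; empty series")
        return WeightedLevelSeries(
            pd.DatetimeIndex([]), np.empty(0), window_s, (f_lo, f_hi)
        )
    power = _window_mean_square_spectrum(rec.samples, n_hops, n_hop)
    freqs = np.fft.rfftfreq(n_hop, d=1.0 / rec.sample_rate)
    weight = 10.0 ** (m_weighting_gain_db(freqs, low_corner, high_corner) / 10.0)
    weight[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    hop_ms = power @ weight  # weighted mean square per hop segment
    kernel = np.ones(hops_per_window) / hops_per_window
    win_ms = np.convolve(hop_ms, kernel, mode="valid")
    with np.errstate(divide="ignore"):
        levels = 10.0 * np.log10(win_ms)
    starts = rec.start_time + pd.to_timedelta(np.arange(win_ms.size) * hop_s, unit="s")
    return WeightedLevelSeries(pd.DatetimeIndex(starts), levels, window_s, (f_lo, f_hi))


# --- Ambient statistics ----------------------------------------------------


def ambient_level(tols: TolSeries, band_centre: float, percentile: float = 5.0) -> float:
    """Ambient level of a band: 5th percentile (95% exceedance) of its TOLs.

    Linear interpolation between order statistics. Below-floor epochs are
    excluded; fewer than 20 finite epochs triggers a warning.
    """
    x = tols.band_levels(band_centre)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite levels in band; cannot estimate ambient")
    if x.size < 20:
        warnings.warn(f"only {x.size} epochs for ambient estimate; result is unstable")
    return float(np.percentile(x, percentile, method="linear"))


def band_correlation(tols: TolSeries, centre_a: float, centre_b: float) -> float:
    """Pearson correlation of per-second levels in two bands.

    Returns NaN (with a warning) when either band has zero variance.
    """
    a = tols.band_levels(centre_a)
    b = tols.band_levels(centre_b)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired finite epochs")
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        warnings.warn("zero variance in one band; correlation undefined")
        return float("nan")
    r, _ = spstats.pearsonr(a, b)
    return float(r)


def cutoff_frequency(
    depth_m: float, c_water_mps: float = 1500.0, c_bottom_mps: float = np.inf
) -> float:
    """Lowest propagating-mode frequency of an ideal shallow-water waveguide.

    f0 = c_w / (4·h·√(1 − (c_w/c_b)²)); in the rigid-bottom limit
    (c_b → ∞) this is c_w/(4·h). Below f0 sound leaks into the seabed and
    the water column acts as a high-pass filter. Returns NaN when
    c_bottom ≤ c_water (no total internal reflection, hence no modal
    cutoff in this model).
    """
    if depth_m <= 0:
        raise ValueError("depth must be positive")
    if c_water_mps <= 0:
        raise ValueError("water sound speed must be positive")
    if c_bottom_mps <= c_water_mps:
        warnings.warn("bottom speed <= water speed: no modal cutoff in this model")
        return float("nan")
    ratio = c_water_mps / c_bottom_mps  # 0 in the rigid-bottom limit
    return c_water_mps / (4.0 * depth_m * np.sqrt(1.0 - ratio**2))
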