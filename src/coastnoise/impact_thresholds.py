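"""Porpoise noise-exposure thresholds, event detection and attribution.

Three published behavioural-response thresholds are built in:

- ``dyndo``: M-weighted broadband (25 Hz–80 kHz) level > 123 dB re 1 µPa
  (RMS, 30-s window) — porpoising behaviour.
- ``tougaard``: sensation level > 45 dB above the hearing threshold —
  generalised negative phonotaxis.
- ``wisniewska``: third-octave level at 16 kHz > 96 dB re 1 µPa (RMS) —
  reduced foraging.

Contiguous above-threshold seconds form noise events; each event is then
attributed to the vessel-presence categories observed during its span,
yielding lower (exclusive) and upper (exclusive + ambiguous) bounds on the
fraction of events each vessel type can account for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .band_analysis import TolSeries, WeightedLevelSeries, m_weighting_gain_db
from .io_calibration import ConfigError

ATTRIBUTIONS = ("only_AIS", "only_nonAIS_motor", "both_present", "sail_only", "no_vessels")


@dataclass
class Audiogram:
    """Hearing thresholds (dB re 1 µPa) at increasing frequencies (Hz)."""

    frequencies: np.ndarray
    hearing_threshold: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.hearing_threshold = np.asarray(self.hearing_threshold, dtype=float)
        if self.frequencies.shape != self.hearing_threshold.shape:
            raise ValueError("frequency/threshold length mismatch")
        if not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.hearing_threshold)):
            raise ValueError("thresholds must be finite")

    def threshold_at(self, f) -> np.ndarray:
        """Hearing threshold interpolated linearly in log-frequency."""
        f = np.asarray(f, dtype=float)
        return np.interp(np.log10(f), np.log10(self.frequencies), self.hearing_threshold)

    @property
    def f_min(self) -> float:
        return float(self.frequencies[0])

    @property
    def f_max(self) -> float:
        return float(self.frequencies[-1])


def default_audiogram() -> Audiogram:
    """Bundled synthetic porpoise audiogram (stand-in data, see the YAML)."""
    with resources.files("coastnoise.data").joinpath(
        "porpoise_audiogram_synthetic.yaml"
    ).open() as fh:
        raw = yaml.safe_load(fh)
    return Audiogram(raw["frequencies_hz"], raw["threshold_db"])


@dataclass
class ThresholdSpec:
    """A porpoise response threshold and how to evaluate it."""

    name: str
    kind: str  # weighted_broadband | band_tol | sensation_level
    level: float  # dB (exceeded strictly)
    window_s: float = 1.0
    band_centre: float | None = None  # band_tol only
    passband: tuple[float, float] | None = None  # weighted_broadband only
    audiogram: Audiogram | None = None  # sensation_level only

    def __post_init__(self) -> None:
        if not np.isfinite(self.level):
            raise ValueError("threshold level must be finite")
        kinds = {"weighted_broadband", "band_tol", "sensation_level"}
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind == "band_tol" and self.band_centre is None:
            raise ValueError("band_tol threshold needs band_centre")
        if self.kind == "weighted_broadband" and self.passband is None:
            raise ValueError("weighted_broadband threshold needs passband")


def builtin_thresholds(audiogram: Audiogram | None = None) -> dict[str, ThresholdSpec]:
    """The three built-in porpoise response thresholds."""
    if audiogram is None:
        audiogram = default_audiogram()
    return {
        "dyndo": ThresholdSpec(
            name="dyndo",
            kind="weighted_broadband",
            level=123.0,
            window_s=30.0,
            passband=(25.0, 80_000.0),
        ),
        "tougaard": ThresholdSpec(
            name="tougaard", kind="sensation_level", level=45.0, audiogram=audiogram
        ),
        "wisniewska": ThresholdSpec(
            name="wisniewska", kind="band_tol", level=96.0, band_centre=16_000.0
        ),
    }


def sensation_level_series(tols: TolSeries, audiogram: Audiogram) -> np.ndarray:
    """Per-epoch sensation level: max over bands of (TOL − hearing threshold).

    The audiogram is interpolated in log-frequency at each band's exact
    centre; bands outside the audiogram's frequency support are skipped.
    """
    centres = np.array([b.exact_centre for b in tols.bands])
    covered = (centres >= audiogram.f_min) & (centres <= audiogram.f_max)
    if not covered.any():
        raise ConfigError("audiogram covers none of the analysed bands")
    thr = audiogram.threshold_at(centres[covered])
    sl = tols.levels[:, covered] - thr[np.newaxis, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmax(np.where(np.isfinite(sl), sl, -np.inf), axis=1)


def weighted_broadband_from_tols(
    tols: TolSeries,
    passband: tuple[float, float] = (25.0, 80_000.0),
    window_s: float = 30.0,
) -> WeightedLevelSeries:
    """M-weighted broadband level approximated from band levels.

    Sums band powers weighted by the M-weighting gain at each exact band
    centre (adequate because the weighting varies slowly across one
    decidecade), then applies a sliding mean over ``window_s``. Lets the
    broadband threshold run on archived TOLs when raw audio is gone.
    """
    centres = np.array([b.exact_centre for b in tols.bands])
    sel = (centres >= passband[0]) & (centres <= passband[1])
    if not sel.any():
        raise ConfigError("no bands inside the requested passband")
    w = 10.0 ** (m_weighting_gain_db(centres[sel]) / 10.0)
    lin = 10.0 ** (tols.levels[:, sel] / 10.0)
    lin[~np.isfinite(tols.levels[:, sel])] = 0.0
    total = lin @ w
    k = max(1, int(round(window_s)))
    if total.size >= k:
        kernel = np.ones(k) / k
        total = np.convolve(total, kernel, mode="valid")
        epochs = tols.epoch_times[: total.size]
    else:
        warnings.warn("series shorter than the averaging window; empty result")
        total = np.empty(0)
        epochs = tols.epoch_times[:0]
    with np.errstate(divide="ignore"):
        levels = 10.0 * np.log10(total)
    return WeightedLevelSeries(epochs, levels, window_s, passband)


def threshold_level_series(
    spec: ThresholdSpec, tols: TolSeries
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """The per-second level series a threshold is compared against."""
    if spec.kind == "band_tol":
        return tols.epoch_times, tols.band_levels(spec.band_centre)
    if spec.kind == "sensation_level":
        return tols.epoch_times, sensation_level_series(tols, spec.audiogram)
    wls = weighted_broadband_from_tols(tols, spec.passband, spec.window_s)
    return wls.epoch_times, wls.levels


@dataclass
class NoiseEvent:
    """A contiguous above-threshold interval."""

    threshold_name: str
    start: pd.Timestamp
    end: pd.Timestamp  # inclusive last above-threshold epoch
    peak_level: float
    category_set: frozenset[int] = frozenset()
    attribution: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("event start must not exceed end")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds() + 1.0


def detect_events(
    epoch_times: pd.DatetimeIndex,
    levels: np.ndarray,
    threshold_level: float,
    threshold_name: str = "",
    merge_gap_s: float = 10.0,
    min_dur_s: float = 1.0,
) -> list[NoiseEvent]:
    """Maximal runs of epochs with level strictly above the threshold.

    Runs separated by gaps of at most ``merge_gap_s`` seconds are merged;
    merged runs shorter than ``min_dur_s`` are dropped. Requires a uniform
    1-s series.
    """
    levels = np.asarray(levels, dtype=float)
    above = levels > threshold_level
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    # split where the gap between consecutive above-threshold epochs
    # exceeds merge_gap_s (+1 because adjacent epochs are 1 s apart)
    breaks = np.flatnonzero(np.diff(idx) > merge_gap_s + 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    events = []
    for s, e in zip(starts, ends):
        if (e - s + 1) < min_dur_s:
            continue
        events.append(
            NoiseEvent(
                threshold_name=threshold_name,
                start=epoch_times[s],
                end=epoch_times[e],
                peak_level=float(np.nanmax(levels[s : e + 1])),
            )
        )
    return events


def _attribution_from_categories(cats: frozenset[int]) -> str:
    non_trivial = cats - {5}
    if not non_trivial:
        return "no_vessels"
    if non_trivial <= {1}:
        return "only_AIS"
    if non_trivial <= {3}:
        return "only_nonAIS_motor"
    if non_trivial <= {4}:
        return "sail_only"
    if 2 in non_trivial or {1, 3} <= non_trivial:
        return "both_present"
    if 1 in non_trivial:
        return "only_AIS" if 4 not in non_trivial else "both_present"
    if 3 in non_trivial:
        return "only_nonAIS_motor"
    return "sail_only"


def attribute_events(
    events: list[NoiseEvent], classified: pd.DataFrame
) -> tuple[list[NoiseEvent], dict]:
    """Attribute each event to the vessel categories seen during its span.

    The summary reports, per vessel type, an exclusive fraction (events
    where only that type was present) and an upper bound adding events
    where both types were present — the "up to" construction. Events whose
    span is not fully covered by the classification are flagged
    unattributable and left out of the summary fractions.
    """
    attributed: list[NoiseEvent] = []
    counts = {a: 0 for a in ATTRIBUTIONS}
    n_unattributable = 0
    for ev in events:
        span = pd.date_range(ev.start, ev.end, freq="1s")
        present = classified.index.get_indexer(span)
        if (present < 0).any():
            attributed.append(
                NoiseEvent(ev.threshold_name, ev.start, ev.end, ev.peak_level, frozenset(), None)
            )
            n_unattributable += 1
            continue
        cats = frozenset(classified["category"].to_numpy()[present].tolist())
        attr = _attribution_from_categories(cats)
        counts[attr] += 1
        attributed.append(
            NoiseEvent(ev.threshold_name, ev.start, ev.end, ev.peak_level, cats, attr)
        )
    n = sum(counts.values())
    summary: dict = {
        "n_events": n,
        "n_unattributable": n_unattributable,
        "fractions_pct": {a: (100.0 * c / n if n else 0.0) for a, c in counts.items()},
    }
    if n:
        f = summary["fractions_pct"]
        summary["nonais_bounds_pct"] = (
            f["only_nonAIS_motor"],
            f["only_nonAIS_motor"] + f["both_present"],
        )
        summary["ais_bounds_pct"] = (f["only_AIS"], f["only_AIS"] + f["both_present"])
    return attributed, summary


def rate_per_hour(n_events: int, duration_h: float) -> tuple[float, int]:
    """Events per hour, exact and rounded to the nearest integer."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    rate = n_events / duration_h
    return rate, int(np.floor(rate + 0.5))


def run_thresholds(
    tols: TolSeries,
    classified: pd.DataFrame,
    thresholds: dict[str, ThresholdSpec] | None = None,
    merge_gap_s: float = 10.0,
    min_dur_s: float = 1.0,
) -> dict[str, dict]:
    """Detect and attribute events for every threshold; one summary each."""
    if thresholds is None:
        thresholds = builtin_thresholds()
    out = {}
    for name, spec in thresholds.items():
        epochs, levels = threshold_level_series(spec, tols)
        events = detect_events(
            epochs, levels, spec.level, name, merge_gap_s=merge_gap_s, min_dur_s=min_dur_s
        )
        attributed, summary = attribute_events(events, classified)
        duration_h = len(tols.epoch_times) / 3600.0
        summary["rate_per_hour"] = rate_per_hour(summary["n_events"], duration_h) if duration_h else (0.0, 0)
        out[name] = {"events": attributed, "summary": summary}
    return out
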