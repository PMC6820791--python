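"""Calibrated audio input, clock-drift correction and track-feed readers.

The recorder writes PCM WAV; calibration maps digital full scale to an
absolute peak pressure level (the "clipping level", dB re 1 µPa), so samples
come back in linear µPa. Vessel feeds arrive as decoded CSVs: AIS position
reports and shore-station theodolite fixes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

logger = logging.getLogger(__name__)

THEODOLITE_VESSEL_TYPES = frozenset(
    {
        "recreational_motor",
        "sailboat_sails",
        "sailboat_motoring",
        "fishing",
        "navy",
        "other",
    }
)

AIS_CSV_COLUMNS = ["vessel_id", "timestamp", "lat", "lon", "sog_knots", "cog_deg", "vessel_class"]
THEODOLITE_CSV_COLUMNS = ["timestamp", "bearing_deg", "vertical_angle_deg", "vessel_label", "vessel_type"]


class SchemaError(ValueError):
    """A CSV is missing required columns or is otherwise malformed."""


class ConfigError(ValueError):
    """Invalid configuration (degenerate model, bad geometry, ...)."""


@dataclass
class CalibratedRecording:
    """Single-channel audio in absolute pressure units.

    samples are linear µPa; ``clip_level_db`` is the peak pressure level
    (dB re 1 µPa) that a full-scale digital sample maps to.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: pd.Timestamp
    clip_level_db: float
    channel_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def clip_pressure_upa(self) -> float:
        return 10.0 ** (self.clip_level_db / 20.0)


@dataclass
class ClockDriftModel:
    """Two-point linear map from device time to reference (UTC) time.

    With equal endpoints the map is the identity. A linear model is the
    minimal strictly monotone correction for a recorder clock that runs
    uniformly fast or slow between two synchronisation points.
    """

    ref_time_start: pd.Timestamp
    ref_time_end: pd.Timestamp
    device_time_start: pd.Timestamp
    device_time_end: pd.Timestamp

    def __post_init__(self) -> None:
        for name in ("ref_time_start", "ref_time_end", "device_time_start", "device_time_end"):
            setattr(self, name, pd.Timestamp(getattr(self, name)))
        dev_span = (self.device_time_end - self.device_time_start).total_seconds()
        ref_span = (self.ref_time_end - self.ref_time_start).total_seconds()
        if dev_span == 0.0 and ref_span == 0.0:
            # identity anchored at a single instant
            return
        if dev_span <= 0.0:
            raise ConfigError("device time span must be positive")
        if ref_span <= 0.0:
            raise ConfigError("reference time span must be positive (mapping must increase)")

    @property
    def rate(self) -> float:
        """Reference seconds elapsed per device second."""
        dev_span = (self.device_time_end - self.device_time_start).total_seconds()
        if dev_span == 0.0:
            return 1.0
        ref_span = (self.ref_time_end - self.ref_time_start).total_seconds()
        return ref_span / dev_span

    @classmethod
    def identity(cls, anchor: pd.Timestamp | str = "2000-01-01") -> "ClockDriftModel":
        t = pd.Timestamp(anchor)
        return cls(t, t, t, t)


def apply_clock_drift(t, model: ClockDriftModel):
    """Map device timestamps to reference (UTC) timestamps.

    Linear interpolation between the model's anchor points; timestamps
    outside the anchored span are extrapolated on the same line.
    Accepts a scalar timestamp or anything ``pd.to_datetime`` handles.
    """
    times = pd.to_datetime(t)
    scalar = isinstance(times, pd.Timestamp)
    idx = pd.DatetimeIndex([times]) if scalar else pd.DatetimeIndex(times)
    dev_secs = (idx - model.device_time_start).total_seconds()
    ref_secs = np.asarray(dev_secs, dtype=float) * model.rate
    out = model.ref_time_start + pd.to_timedelta(ref_secs, unit="s")
    return out[0] if scalar else out


@dataclass
class AisRecord:
    vessel_id: str
    timestamp: pd.Timestamp
    lat: float
    lon: float
    sog: float  # speed over ground, knots
    cog: float  # course over ground, degrees true
    vessel_class: str = ""

    def valid(self) -> bool:
        return (
            abs(self.lat) <= 90.0
            and abs(self.lon) <= 180.0
            and self.sog >= 0.0
            and math.isfinite(self.lat)
            and math.isfinite(self.lon)
        )


@dataclass
class TheodoliteFix:
    timestamp: pd.Timestamp
    horizontal_bearing: float  # degrees true, clockwise from north
    vertical_angle: float  # degrees below the horizontal
    vessel_label: str
    vessel_type: str = "other"

    def valid(self) -> bool:
        return 0.0 <= self.horizontal_bearing < 360.0 and self.vertical_angle > 0.0


@dataclass
class StationGeometry:
    """Shore-station and recorder geometry for theodolite positioning."""

    station_lat: float
    station_lon: float
    eye_height: float  # theodolite eye height above sea level, m
    recorder_lat: float
    recorder_lon: float
    recorder_depth: float  # m below surface
    water_depth: float  # m

    def __post_init__(self) -> None:
        if self.eye_height <= 0:
            raise ConfigError("eye_height must be positive")
        if self.water_depth < self.recorder_depth:
            raise ConfigError("water_depth must be at least recorder_depth")


def read_wav_calibrated(
    path,
    clip_level_db: float,
    start_time=None,
    channel_id: str = "",
) -> CalibratedRecording:
    """Read a PCM WAV file and scale samples to µPa.

    A full-scale digital sample maps to ``clip_level_db`` interpreted as a
    *peak* pressure level (dB re 1 µPa); this matches the manufacturer
    convention for autonomous recorders that state a "clipping level". An
    RMS-full-scale convention would subtract 20·log10(√2) from the clip
    level before calling this function.
    """
    if not math.isfinite(clip_level_db):
        raise ValueError("clip_level_db must be finite")
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise OSError(f"only single-channel WAV is supported, got shape {data.shape}")
    if data.size == 0:
        raise ValueError(f"empty WAV file: {path}")
    if data.dtype == np.int16:
        full_scale = 2.0**15
    elif data.dtype == np.int32:
        full_scale = 2.0**31
    elif data.dtype == np.uint8:
        data = data.astype(np.int16) - 128
        full_scale = 128.0
    elif data.dtype in (np.float32, np.float64):
        full_scale = 1.0
    else:
        raise OSError(f"unsupported WAV sample format: {data.dtype}")
    scale = 10.0 ** (clip_level_db / 20.0) / full_scale
    samples = data.astype(float) * scale
    if start_time is None:
        start_time = pd.Timestamp("2000-01-01T00:00:00")
    return CalibratedRecording(
        samples=samples,
        sample_rate=float(fs),
        start_time=pd.Timestamp(start_time),
        clip_level_db=float(clip_level_db),
        channel_id=channel_id,
    )


def write_wav_calibrated(path, rec: CalibratedRecording) -> None:
    """Write a recording as 16-bit PCM, inverse of :func:`read_wav_calibrated`."""
    peak = rec.clip_pressure_upa
    x = np.clip(rec.samples / peak, -1.0, 1.0)
    wavfile.write(path, int(round(rec.sample_rate)), (x * (2.0**15 - 1)).astype(np.int16))


def _read_csv_checked(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_ais_csv(path) -> list[AisRecord]:
    """Read decoded AIS position reports; rows violating invariants are dropped."""
    df = _read_csv_checked(path, AIS_CSV_COLUMNS)
    records: list[AisRecord] = []
    for i, row in df.iterrows():
        rec = AisRecord(
            vessel_id=str(row["vessel_id"]),
            timestamp=pd.Timestamp(row["timestamp"]),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            sog=float(row["sog_knots"]),
            cog=float(row["cog_deg"]),
            vessel_class=str(row["vessel_class"]),
        )
        if rec.valid():
            records.append(rec)
        else:
            logger.warning("%s: dropping AIS row %d (invariant violation)", path, i)
    return records


def read_theodolite_csv(path) -> list[TheodoliteFix]:
    """Read theodolite fixes; rows violating invariants are dropped."""
    df = _read_csv_checked(path, THEODOLITE_CSV_COLUMNS)
    fixes: list[TheodoliteFix] = []
    for i, row in df.iterrows():
        vtype = str(row["vessel_type"])
        if vtype not in THEODOLITE_VESSEL_TYPES:
            logger.warning("%s: row %d unknown vessel_type %r, using 'other'", path, i, vtype)
            vtype = "other"
        fix = TheodoliteFix(
            timestamp=pd.Timestamp(row["timestamp"]),
            horizontal_bearing=float(row["bearing_deg"]),
            vertical_angle=float(row["vertical_angle_deg"]),
            vessel_label=str(row["vessel_label"]),
            vessel_type=vtype,
        )
        if fix.valid():
            fixes.append(fix)
        else:
            logger.warning("%s: dropping theodolite row %d (invariant violation)", path, i)
    return fixes


def load_station_yaml(path) -> StationGeometry:
    """Load station/recorder geometry from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        return StationGeometry(
            station_lat=float(cfg["station"]["lat"]),
            station_lon=float(cfg["station"]["lon"]),
            eye_height=float(cfg["station"]["eye_height_m"]),
            recorder_lat=float(cfg["recorder"]["lat"]),
            recorder_lon=float(cfg["recorder"]["lon"]),
            recorder_depth=float(cfg["recorder"]["depth_m"]),
            water_depth=float(cfg["recorder"]["water_depth_m"]),
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: missing config key {exc}") from exc
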