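"""Data model and file formats for ex vivo intestinal motility recordings.

One recording bundles the channels produced by a tissue-bath experiment:
intraluminal pressure (cmH2O, typically sampled every 2 ms), four edge-width
diameter channels ``ew1``..``ew4`` (mm, oral to aboral, every 50 ms), one
longitudinal-position channel (mm, every 50 ms), the segment geometry used
for volume reconstruction, and the droplet-discharge events captured by a
drop counter at the aboral outflow.

Times are seconds everywhere inside the package; minutes appear only at
report boundaries (discharge durations, flow rates).

File formats
------------
Trace CSV
    Header ``time_s,<channel columns>`` where channel columns are drawn from
    ``pressure_cmH2O, ew1_mm .. ew4_mm, longitudinal_mm, volume_mm3``.
    Channels sampled at different rates live in separate CSVs referenced from
    a JSON config.
Drops CSV
    Header ``time_s,volume_ul``; strictly increasing times.
JSON config
    Geometry (``h_mm``, ``total_length_mm``), ``afterload_cmH2O``, ``Ds_min``,
    ``inflow_ml_min``, ``ul_per_drop``, the trace/drop file references and any
    analysis thresholds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

#: channel id -> required unit
CHANNEL_UNITS = {
    "pressure": "cmH2O",
    "ew1": "mm",
    "ew2": "mm",
    "ew3": "mm",
    "ew4": "mm",
    "longitudinal": "mm",
    "volume": "mm3",
}

REQUIRED_CHANNELS = ("pressure", "ew1", "ew2", "ew3", "ew4", "longitudinal")

#: CSV column name <-> channel id
_COLUMN_OF = {
    "pressure": "pressure_cmH2O",
    "ew1": "ew1_mm",
    "ew2": "ew2_mm",
    "ew3": "ew3_mm",
    "ew4": "ew4_mm",
    "longitudinal": "longitudinal_mm",
    "volume": "volume_mm3",
}
_CHANNEL_OF = {v: k for k, v in _COLUMN_OF.items()}


@dataclass(frozen=True)
class TimeSeriesChannel:
    """A uniformly sampled scalar trace.

    Parameters
    ----------
    channel_id : str
        One of ``pressure, ew1..ew4, longitudinal, volume``.
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sampling interval, seconds (> 0).
    values : numpy.ndarray
        Sample values; finite, length >= 2.
    units : str
        Must match the channel id (pressure -> cmH2O, ew*/longitudinal -> mm,
        volume -> mm3).
    """

    channel_id: str
    t0: float
    dt: float
    values: np.ndarray
    units: str | None = None

    def __post_init__(self):
        if self.channel_id not in CHANNEL_UNITS:
            raise FormatError(f"unknown channel id {self.channel_id!r}")
        expected = CHANNEL_UNITS[self.channel_id]
        units = self.units if self.units is not None else expected
        if units != expected:
            raise FormatError(
                f"channel {self.channel_id!r} requires units {expected!r}, got {units!r}"
            )
        object.__setattr__(self, "units", units)
        if not (self.dt > 0):
            raise FormatError(f"channel {self.channel_id!r}: dt must be > 0")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise FormatError(
                f"channel {self.channel_id!r}: need a 1-d trace of length >= 2"
            )
        if not np.all(np.isfinite(values)):
            raise FormatError(f"channel {self.channel_id!r}: values must be finite")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    # -- derived geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def end(self) -> float:
        """Time just past the last sample (half-open window convention)."""
        return self.t0 + self.n * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def slice(self, start: float, end: float) -> tuple[np.ndarray, np.ndarray]:
        """Samples with t in [start, end); returns (times, values)."""
        if not (end > start):
            raise ParameterError("empty window: end must exceed start")
        i0 = max(0, int(math.ceil((start - self.t0) / self.dt - 1e-9)))
        i1 = min(self.n, int(math.ceil((end - self.t0) / self.dt - 1e-9)))
        if i1 <= i0:
            raise ParameterError(
                f"window [{start}, {end}) contains no samples of {self.channel_id!r}"
            )
        t = self.t0 + self.dt * np.arange(i0, i1)
        return t, self.values[i0:i1]


@dataclass(frozen=True)
class SegmentGeometry:
    """Axial geometry of the mounted segment.

    ``h`` holds the four per-tracker lengths (mm), each covering the tracker
    plus half the gap to its neighbours; used by the volume formula.
    """

    h: tuple[float, float, float, float]
    total_length: float

    def __post_init__(self):
        h = tuple(float(x) for x in self.h)
        if len(h) != 4:
            raise FormatError("geometry needs exactly four tracker lengths")
        if any(x <= 0 for x in h):
            raise FormatError("all tracker lengths h_i must be > 0")
        if sum(h) > self.total_length * (1 + 1e-9):
            raise FormatError("sum of tracker lengths exceeds total segment length")
        object.__setattr__(self, "h", h)

    @classmethod
    def uniform(cls, total_length: float) -> "SegmentGeometry":
        """Equal per-tracker lengths covering the whole segment."""
        return cls(h=(total_length / 4,) * 4, total_length=total_length)


@dataclass(frozen=True, order=True)
class DropEvent:
    """One droplet discharge at the aboral end."""

    time: float  # s
    volume: float  # microliters

    def __post_init__(self):
        if not (self.volume > 0):
            raise FormatError("drop volume must be > 0")


@dataclass
class MotilityRecording:
    """One experiment's aligned multichannel traces, geometry and drop events."""

    channels: dict[str, TimeSeriesChannel]
    geometry: SegmentGeometry
    drops: list[DropEvent] = field(default_factory=list)
    afterload: float = 1.5  # cmH2O
    standard_duration_Ds: float = 0.77  # minutes, tubing-only reference interval
    inflow_rate: float = 0.065  # ml/min

    def __post_init__(self):
        for name, ch in self.channels.items():
            if name != ch.channel_id:
                raise FormatError(
                    f"channel keyed {name!r} carries id {ch.channel_id!r}"
                )
        for name in REQUIRED_CHANNELS:
            if name not in self.channels:
                raise FormatError(f"required channel {name} absent")
        start, end = self.common_window()
        if not (end > start):
            raise FormatError("channels do not share a common time window")
        times = [d.time for d in self.drops]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise FormatError("drop events must be strictly increasing in time")
        if self.afterload < 0:
            raise FormatError("afterload must be >= 0")
        if not (self.standard_duration_Ds > 0):
            raise FormatError("standard duration Ds must be > 0")

    def channel(self, channel_id: str) -> TimeSeriesChannel:
        try:
            return self.channels[channel_id]
        except KeyError:
            raise FormatError(f"required channel {channel_id} absent") from None

    def common_window(self) -> tuple[float, float]:
        """Largest [start, end) covered by every channel."""
        start = max(ch.t0 for ch in self.channels.values())
        end = min(ch.end for ch in self.channels.values())
        return start, end

    def with_channel(self, ch: TimeSeriesChannel) -> "MotilityRecording":
        channels = dict(self.channels)
        channels[ch.channel_id] = ch
        return replace(self, channels=channels)


def align_to_common_grid(rec: MotilityRecording, dt_target: float = 0.05) -> MotilityRecording:
    """Resample all channels onto one grid by within-bin block averaging.

    ``dt_target`` must be at least the coarsest native interval; upsampling is
    refused because it would have to invent samples. The common window is the
    intersection of all channel windows; trailing partial bins are dropped.
    The input recording is left untouched.
    """
    native = max(ch.dt for ch in rec.channels.values())
    if dt_target < native * (1 - 1e-9):
        raise ParameterError(
            f"dt_target {dt_target} s is finer than the coarsest native rate "
            f"{native} s; upsampling is refused"
        )
    start, end = rec.common_window()
    n_bins = int(math.floor((end - start) / dt_target + 1e-9))
    if n_bins < 2:
        raise ParameterError("common window too short for the requested grid")
    out = {}
    for name, ch in rec.channels.items():
        t, v = ch.slice(start, start + n_bins * dt_target)
        idx = np.floor((t - start) / dt_target + 1e-9).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        sums = np.bincount(idx, weights=v, minlength=n_bins)
        counts = np.bincount(idx, minlength=n_bins)
        if np.any(counts == 0):
            raise ParameterError(
                f"channel {name!r}: grid bin without samples (dt_target too close "
                "to the native rate with incommensurate phase)"
            )
        out[name] = TimeSeriesChannel(
            channel_id=name, t0=start, dt=dt_target, values=sums / counts
        )
    return replace(rec, channels=out)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------


def _read_trace_csv(path: Path) -> dict[str, TimeSeriesChannel]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path.name}: missing required column time_s")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path.name}: need at least two samples")
    diffs = np.diff(t)
    if np.any(diffs <= 0):
        raise FormatError(f"{path.name}: non-monotone timestamps")
    dt = float(np.median(diffs))
    # missing samples are not interpolated: a gap > 2*dt fails validation
    if np.any(diffs > 2 * dt) or np.any(diffs < 0.5 * dt):
        raise FormatError(f"{path.name}: non-uniform sampling (gap beyond 2*dt)")
    channels = {}
    for col in df.columns:
        if col == "time_s":
            continue
        if col not in _CHANNEL_OF:
            raise FormatError(f"{path.name}: unit mismatch or unknown column {col!r}")
        cid = _CHANNEL_OF[col]
        channels[cid] = TimeSeriesChannel(
            channel_id=cid, t0=float(t[0]), dt=dt,
            values=df[col].to_numpy(dtype=float),
        )
    if not channels:
        raise FormatError(f"{path.name}: no channel columns found")
    return channels


def _read_drops_csv(path: Path, ul_per_drop: float) -> list[DropEvent]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path.name}: missing required column time_s")
    if "volume_ul" in df.columns:
        volumes = df["volume_ul"].to_numpy(dtype=float)
    else:
        # drop-count files without calibrated volumes: constant calibration
        volumes = np.full(len(df), float(ul_per_drop))
    return [DropEvent(float(t), float(v)) for t, v in zip(df["time_s"], volumes)]


def read_recording(path: str | Path, config: dict | None = None) -> MotilityRecording:
    """Read a recording from a JSON config or a single trace CSV.

    A JSON config references one or more trace CSVs (``trace_csv`` or
    ``traces: [{path: ...}, ...]``, relative to the config file) plus an
    optional ``drops_csv``, and supplies geometry, afterload, Ds and inflow.
    A bare CSV needs ``config`` to supply whatever the file lacks.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    cfg = dict(config or {})
    base = path.parent
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            file_cfg = json.load(fh)
        file_cfg.update(cfg)  # explicit config overrides file header
        cfg = file_cfg
        trace_paths = []
        if "trace_csv" in cfg:
            trace_paths.append(base / cfg["trace_csv"])
        for entry in cfg.get("traces", []):
            trace_paths.append(base / (entry["path"] if isinstance(entry, dict) else entry))
        if not trace_paths:
            raise FormatError(f"{path.name}: config references no trace files")
    else:
        trace_paths = [path]

    channels: dict[str, TimeSeriesChannel] = {}
    for tp in trace_paths:
        if not tp.exists():
            raise FormatError(f"no such trace file: {tp}")
        for cid, ch in _read_trace_csv(tp).items():
            if cid in channels:
                raise FormatError(f"channel {cid} defined in more than one file")
            channels[cid] = ch

    drops: list[DropEvent] = []
    if cfg.get("drops_csv"):
        dp = base / cfg["drops_csv"]
        if not dp.exists():
            raise FormatError(f"no such drops file: {dp}")
        drops = _read_drops_csv(dp, cfg.get("ul_per_drop", 50.0))

    geo_cfg = cfg.get("geometry")
    if geo_cfg is None:
        raise FormatError("config must supply segment geometry")
    if "h_mm" in geo_cfg:
        geometry = SegmentGeometry(tuple(geo_cfg["h_mm"]), float(geo_cfg["total_length_mm"]))
    else:
        geometry = SegmentGeometry.uniform(float(geo_cfg["total_length_mm"]))

    return MotilityRecording(
        channels=channels,
        geometry=geometry,
        drops=drops,
        afterload=float(cfg.get("afterload_cmH2O", 1.5)),
        standard_duration_Ds=float(cfg.get("Ds_min", 0.77)),
        inflow_rate=float(cfg.get("inflow_ml_min", 0.065)),
    )


def write_recording(rec: MotilityRecording, out_dir: str | Path,
                    stem: str = "recording") -> Path:
    """Write a recording as per-rate trace CSVs, a drops CSV and a JSON config.

    Returns the path of the JSON config, which :func:`read_recording` accepts.
    Values are written with 17 significant digits so a read/write round trip
    is value-identical to float precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # group channels sharing (t0, dt) into one CSV
    groups: dict[tuple[float, float, int], list[TimeSeriesChannel]] = {}
    for ch in rec.channels.values():
        groups.setdefault((ch.t0, ch.dt, ch.n), []).append(ch)
    traces = []
    for gi, ((t0, dt, n), chans) in enumerate(sorted(groups.items())):
        df = pd.DataFrame({"time_s": t0 + dt * np.arange(n)})
        for ch in sorted(chans, key=lambda c: c.channel_id):
            df[_COLUMN_OF[ch.channel_id]] = ch.values
        name = f"{stem}_traces_{gi}.csv"
        df.to_csv(out_dir / name, index=False, float_format="%.17g")
        traces.append({"path": name})
    cfg = {
        "traces": traces,
        "geometry": {"h_mm": list(rec.geometry.h),
                     "total_length_mm": rec.geometry.total_length},
        "afterload_cmH2O": rec.afterload,
        "Ds_min": rec.standard_duration_Ds,
        "inflow_ml_min": rec.inflow_rate,
    }
    if rec.drops:
        dname = f"{stem}_drops.csv"
        pd.DataFrame(
            {"time_s": [d.time for d in rec.drops],
             "volume_ul": [d.volume for d in rec.drops]}
        ).to_csv(out_dir / dname, index=False, float_format="%.17g")
        cfg["drops_csv"] = dname
    cfg_path = out_dir / f"{stem}.json"
    with open(cfg_path, "w") as fh:
        json.dump(cfg, fh, indent=1)
    return cfg_path
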