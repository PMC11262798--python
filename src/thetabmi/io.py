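"""Containers and on-disk formats for continuous signals, spikes, events, and tracks.

The on-disk dialect is deliberately minimal and open:

* continuous signals: raw little-endian ``float64`` sample block (``.lfp``)
  plus a plain-text sidecar header (``.lfp.hdr``) carrying sampling rate,
  region, start time and an optional scale;
* spike trains, event logs and position tracks: tab-delimited text with a
  header row.

Time is seconds as 64-bit floats throughout.  Epochs are half-open sample
index intervals ``[start, end)``; event-time to sample-index conversion
rounds toward negative infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("mPFC", "HPC", "VMT", "other")

EVENT_KINDS = (
    "trial_start",
    "door_open",
    "beam_break",
    "choice_entry",
    "choice_exit",
    "reward",
    "session_start",
)


@dataclass
class ContinuousSignal:
    """One recording site's LFP: samples (µV), rate (Hz), region, start time (s)."""

    samples: np.ndarray
    sampling_rate: float
    region: str = "other"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError("invalid sampling rate")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def time_to_index(self, t: float) -> int:
        """Sample index of time ``t`` (seconds), rounding toward -inf."""
        return math.floor((t - self.start_time) * self.sampling_rate)

    def copy(self) -> "ContinuousSignal":
        return replace(self, samples=self.samples.copy())


@dataclass
class SpikeTrain:
    """Spike timestamps (seconds, strictly increasing after dedup) for one unit."""

    timestamps: np.ndarray
    unit_id: str = "unit0"
    region: str = "other"

    def __post_init__(self) -> None:
        ts = np.unique(np.asarray(self.timestamps, dtype=np.float64))
        self.timestamps = ts
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")

    @property
    def n_spikes(self) -> int:
        return self.timestamps.size


@dataclass
class EventLog:
    """Time-ordered session events with a closed kind vocabulary."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["time", "kind", "payload"])
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        if "payload" not in df.columns:
            df["payload"] = [{} for _ in range(len(df))]
        bad = set(df["kind"]) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds {sorted(bad)}")
        if len(df) and (np.diff(df["time"].to_numpy(dtype=float)) < 0).any():
            raise ValueError("event times must be non-decreasing")
        self.records = df.reset_index(drop=True)

    def append(self, time: float, kind: str, **payload) -> None:
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        if len(self.records) and time < float(self.records["time"].iloc[-1]):
            raise ValueError("event times must be non-decreasing")
        self.records.loc[len(self.records)] = [float(time), kind, dict(payload)]

    def times_of(self, kind: str) -> np.ndarray:
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        sel = self.records[self.records["kind"] == kind]
        return sel["time"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class BehaviorTrack:
    """2-D position track: x, y (cm, or native units) sampled at times t (s)."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    scale_cm_per_unit: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.t = np.asarray(self.t, dtype=np.float64)
        if not (self.x.size == self.y.size == self.t.size):
            raise ValueError("x, y, t must have equal lengths")
        if self.t.size >= 2 and (np.diff(self.t) <= 0).any():
            raise ValueError("t must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.t.size


# ---------------------------------------------------------------------------
# Continuous-signal format: raw float64 block + sidecar text header


def write_signal(signal: ContinuousSignal, path: str | Path) -> None:
    path = Path(path)
    signal.samples.astype("<f8").tofile(path)
    hdr = path.with_suffix(path.suffix + ".hdr")
    hdr.write_text(
        "format thetabmi-lfp-1\n"
        f"sampling_rate {signal.sampling_rate!r}\n"
        f"region {signal.region}\n"
        f"start_time {signal.start_time!r}\n"
        f"n_samples {signal.n_samples}\n"
        "dtype <f8\n"
    )


def read_signal(path: str | Path) -> ContinuousSignal:
    path = Path(path)
    hdr = path.with_suffix(path.suffix + ".hdr")
    if not hdr.exists():
        raise FileNotFoundError(f"missing sidecar header {hdr}")
    fields: dict[str, str] = {}
    for line in hdr.read_text().splitlines():
        if line.strip():
            key, _, value = line.partition(" ")
            fields[key] = value.strip()
    if fields.get("format") != "thetabmi-lfp-1":
        raise ValueError("malformed header: bad format tag")
    rate = float(fields["sampling_rate"])
    if rate <= 0:
        raise ValueError("invalid sampling rate")
    samples = np.fromfile(path, dtype="<f8")
    n = int(fields["n_samples"])
    if samples.size != n:
        raise ValueError(f"sample block holds {samples.size} values, header says {n}")
    return ContinuousSignal(
        samples=samples,
        sampling_rate=rate,
        region=fields.get("region", "other"),
        start_time=float(fields.get("start_time", 0.0)),
    )


# ---------------------------------------------------------------------------
# Delimited-text formats


def write_spikes(train: SpikeTrain, path: str | Path) -> None:
    df = pd.DataFrame({"timestamp": train.timestamps})
    df.insert(0, "unit_id", train.unit_id)
    df.insert(1, "region", train.region)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_spikes(path: str | Path) -> SpikeTrain:
    df = pd.read_csv(path, sep="\t")
    unit = str(df["unit_id"].iloc[0]) if len(df) else "unit0"
    region = str(df["region"].iloc[0]) if len(df) else "other"
    return SpikeTrain(df["timestamp"].to_numpy(dtype=float), unit_id=unit, region=region)


def write_events(log: EventLog, path: str | Path) -> None:
    df = log.records.copy()
    df["payload"] = df["payload"].map(
        lambda d: ";".join(f"{k}={v}" for k, v in sorted(d.items()))
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _parse_payload(s: object) -> dict:
    if not isinstance(s, str) or not s:
        return {}
    out = {}
    for item in s.split(";"):
        k, _, v = item.partition("=")
        out[k] = v
    return out


def read_events(path: str | Path) -> EventLog:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["time"] = df["time"].astype(float)
    df["payload"] = df["payload"].map(_parse_payload)
    return EventLog(df)


def write_track(track: BehaviorTrack, path: str | Path) -> None:
    df = pd.DataFrame({"t": track.t, "x": track.x, "y": track.y})
    if track.scale_cm_per_unit is not None:
        df.attrs["scale"] = track.scale_cm_per_unit
    header = ""
    if track.scale_cm_per_unit is not None:
        header = f"# scale_cm_per_unit {track.scale_cm_per_unit!r}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_track(path: str | Path) -> BehaviorTrack:
    scale = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# scale_cm_per_unit"):
            scale = float(first.split()[-1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    return BehaviorTrack(df["x"], df["y"], df["t"], scale_cm_per_unit=scale)


# ---------------------------------------------------------------------------
# Epoch extraction


@dataclass
class EpochReport:
    """Outcome of epoch extraction: kept epochs plus skipped event times."""

    epochs: list[np.ndarray]
    event_times: np.ndarray
    skipped_times: np.ndarray


def extract_epochs(
    signal: ContinuousSignal,
    events: EventLog,
    kind: str,
    window: tuple[float, float],
) -> EpochReport:
    """Cut one fixed-length sample block per ``kind`` event.

    ``window = (pre, post)`` in seconds; each epoch spans the half-open index
    interval ``[floor((t-pre)·fs), floor((t-pre)·fs) + round((pre+post)·fs))``.
    Events whose window would run off either record edge are skipped and
    reported, never silently dropped.
    """
    pre, post = window
    if pre < 0 or post < 0:
        raise ValueError("window margins must be non-negative")
    times = events.times_of(kind)
    n_len = int(round((pre + post) * signal.sampling_rate))
    kept: list[np.ndarray] = []
    kept_t: list[float] = []
    skipped: list[float] = []
    for t in times:
        start = signal.time_to_index(t - pre)
        end = start + n_len
        if start < 0 or end > signal.n_samples:
            skipped.append(t)
            continue
        kept.append(signal.samples[start:end].copy())
        kept_t.append(t)
    return EpochReport(
        epochs=kept,
        event_times=np.asarray(kept_t, dtype=float),
        skipped_times=np.asarray(skipped, dtype=float),
    )
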