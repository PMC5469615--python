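"""Session data model and readers/writers for photometry + spike sessions.

A *session* bundles a continuous fluorescence :class:`Recording`, an
:class:`EventStream` of behavioral events, optionally a list of sorted
:class:`SpikeUnit` objects and a video-tracking :class:`PositionTrace`.
Two interchange formats are supported:

``csv``
    A directory with ``meta.json`` plus one CSV per modality
    (``trace.csv``, ``events.csv``, ``position.csv``,
    ``units/<id>_spikes.csv`` / ``<id>_waveform.csv``).  Comma-separated,
    mandatory header row, UTF-8, ``.`` decimal.
``hdf5``
    One container file with one group per modality: ``/photometry``,
    ``/events``, ``/units/<id>``, ``/position``; sampling rates and units
    live in attributes.

Time is in seconds everywhere; sampling rates are stored explicitly and
never inferred from timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

log = logging.getLogger("habpipe")

__all__ = [
    "Recording",
    "EventStream",
    "SpikeUnit",
    "PositionTrace",
    "Session",
    "SchemaError",
    "ValidationError",
    "read_session",
    "write_session",
]


class SchemaError(ValueError):
    """A required column/dataset is missing from an input file."""


class ValidationError(ValueError):
    """Input data violates a type invariant (e.g. non-monotone timestamps)."""


def _as_f64(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass
class Recording:
    """Continuous fluorescence trace with an explicit sampling rate.

    Parameters
    ----------
    trace : array
        Fluorescence samples in arbitrary units.
    rate : float
        Sampling frequency in Hz (the acquisition system digitizes at 500 Hz).
    t0 : float
        Time of the first sample, seconds.
    channel_label : str
        Free-text channel name (e.g. ``"gcamp"``).
    """

    trace: np.ndarray
    rate: float
    t0: float = 0.0
    channel_label: str = "gcamp"

    def __post_init__(self) -> None:
        self.trace = _as_f64(self.trace)
        if self.trace.ndim != 1 or self.trace.size < 1:
            raise ValidationError("trace must be a non-empty 1-D array")
        if not self.rate > 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.rate}")
        self.rate = float(self.rate)
        self.t0 = float(self.t0)

    @property
    def times(self) -> np.ndarray:
        """Sample times t0 + i/rate, strictly increasing by construction."""
        return self.t0 + np.arange(self.trace.size) / self.rate

    @property
    def duration(self) -> float:
        return self.trace.size / self.rate

    def __eq__(self, other) -> bool:  # field-by-field, for round-trip tests
        return (
            isinstance(other, Recording)
            and np.array_equal(self.trace, other.trace)
            and self.rate == other.rate
            and self.t0 == other.t0
            and self.channel_label == other.channel_label
        )


@dataclass
class EventStream:
    """Ordered behavioral events as (onset s, label, duration s).

    Durations are explicit (a 2 s cue, a 0.5 s infusion) rather than paired
    on/off markers.  Onsets must be non-decreasing and durations >= 0.
    """

    onsets: np.ndarray
    labels: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = _as_f64(self.onsets)
        self.durations = _as_f64(self.durations)
        self.labels = np.asarray(self.labels, dtype=object)
        n = self.onsets.size
        if not (self.labels.size == n and self.durations.size == n):
            raise ValidationError("onsets, labels, durations must have equal length")
        if n:
            bad = np.nonzero(np.diff(self.onsets) < 0)[0]
            if bad.size:
                raise ValidationError(
                    f"event onsets must be non-decreasing; first violation at index {bad[0] + 1}"
                )
            if np.any(self.durations < 0):
                i = int(np.nonzero(self.durations < 0)[0][0])
                raise ValidationError(f"negative event duration at index {i}")

    def __len__(self) -> int:
        return int(self.onsets.size)

    def select(self, label: str) -> "EventStream":
        """Events whose label equals ``label``."""
        m = self.labels == label
        return EventStream(self.onsets[m], self.labels[m], self.durations[m])

    @property
    def vocabulary(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset": self.onsets, "label": self.labels.astype(str), "duration": self.durations}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventStream":
        for col in ("onset", "label", "duration"):
            if col not in df.columns:
                raise SchemaError(f"events table is missing required column '{col}'")
        return cls(df["onset"].to_numpy(), df["label"].to_numpy(dtype=object), df["duration"].to_numpy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventStream)
            and np.array_equal(self.onsets, other.onsets)
            and np.array_equal(self.durations, other.durations)
            and list(self.labels) == list(other.labels)
        )


@dataclass
class SpikeUnit:
    """A sorted single unit: spike times, mean waveform, optional light pulses.

    ``waveform_mean`` is channels x samples (µV), e.g. the four tetrode wires.
    ``light_pulses`` holds pulse onsets (s) for optogenetic tagging with a
    common ``pulse_width`` (the tagging protocol uses 5 ms pulses at 10 Hz).
    ``t_start``/``t_stop`` bound the recording epoch; when omitted they are
    inferred from the data.  ``waveform_evoked`` optionally carries the mean
    light-evoked waveform for waveform-correlation checks.
    """

    spike_times: np.ndarray
    waveform_mean: np.ndarray
    unit_id: str = "u0"
    light_pulses: np.ndarray = field(default_factory=lambda: np.empty(0))
    pulse_width: float = 0.005
    t_start: float | None = None
    t_stop: float | None = None
    waveform_evoked: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spike_times = _as_f64(self.spike_times)
        self.light_pulses = _as_f64(self.light_pulses)
        self.waveform_mean = np.atleast_2d(_as_f64(self.waveform_mean))
        if self.waveform_evoked is not None:
            self.waveform_evoked = np.atleast_2d(_as_f64(self.waveform_evoked))
        if self.spike_times.size:
            bad = np.nonzero(np.diff(self.spike_times) <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"spike times must be strictly increasing; first violation at index {bad[0] + 1}"
                )
        if not np.all(np.isfinite(self.waveform_mean)):
            raise ValidationError("waveform_mean contains non-finite samples")
        if self.light_pulses.size and not self.pulse_width > 0:
            raise ValidationError("pulse_width must be > 0 when light pulses are present")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def epoch(self) -> tuple[float, float]:
        """Recording epoch, inferred from data when not set explicitly."""
        lo_cands = [0.0]
        hi_cands = [0.0]
        if self.spike_times.size:
            lo_cands.append(float(self.spike_times[0]))
            hi_cands.append(float(self.spike_times[-1]))
        if self.light_pulses.size:
            lo_cands.append(float(self.light_pulses[0]))
            hi_cands.append(float(self.light_pulses[-1]) + self.pulse_width)
        lo = self.t_start if self.t_start is not None else min(lo_cands)
        hi = self.t_stop if self.t_stop is not None else max(hi_cands)
        return float(lo), float(hi)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeUnit):
            return False
        ev_eq = (self.waveform_evoked is None) == (other.waveform_evoked is None) and (
            self.waveform_evoked is None
            or np.array_equal(self.waveform_evoked, other.waveform_evoked)
        )
        return (
            np.array_equal(self.spike_times, other.spike_times)
            and np.array_equal(self.waveform_mean, other.waveform_mean)
            and np.array_equal(self.light_pulses, other.light_pulses)
            and self.unit_id == other.unit_id
            and self.pulse_width == other.pulse_width
            and self.t_start == other.t_start
            and self.t_stop == other.t_stop
            and ev_eq
        )


@dataclass
class PositionTrace:
    """Planar animal position from video tracking: times (s) and xy (cm)."""

    times: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_f64(self.times)
        self.xy = _as_f64(self.xy)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValidationError("xy must be an (n, 2) array")
        if self.times.size != self.xy.shape[0]:
            raise ValidationError("times and xy must have equal length")
        if self.times.size:
            bad = np.nonzero(np.diff(self.times) <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"position times must be strictly increasing; first violation at index {bad[0] + 1}"
                )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PositionTrace)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.xy, other.xy)
        )


@dataclass
class Session:
    """A full recording session: trace + events [+ units] [+ position]."""

    recording: Recording | None = None
    events: EventStream | None = None
    units: list[SpikeUnit] = field(default_factory=list)
    position: PositionTrace | None = None

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Session)
            and self.recording == other.recording
            and self.events == other.events
            and self.units == other.units
            and self.position == other.position
        )


# ---------------------------------------------------------------------------
# CSV directory format
# ---------------------------------------------------------------------------

def _write_csv(session: Session, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {"format": "habpipe-session", "version": 1}
    if session.recording is not None:
        rec = session.recording
        meta["photometry"] = {"rate": rec.rate, "t0": rec.t0, "channel_label": rec.channel_label}
        pd.DataFrame({"value": rec.trace}).to_csv(path / "trace.csv", index=False, float_format="%.17g")
    if session.events is not None:
        session.events.to_frame().to_csv(path / "events.csv", index=False, float_format="%.17g")
    if session.units:
        udir = path / "units"
        udir.mkdir(exist_ok=True)
        meta["units"] = []
        for u in session.units:
            meta["units"].append(
                {
                    "unit_id": u.unit_id,
                    "pulse_width": u.pulse_width,
                    "t_start": u.t_start,
                    "t_stop": u.t_stop,
                    "n_channels": int(u.waveform_mean.shape[0]),
                }
            )
            pd.DataFrame({"spike_time": u.spike_times}).to_csv(
                udir / f"{u.unit_id}_spikes.csv", index=False, float_format="%.17g"
            )
            wf = pd.DataFrame(u.waveform_mean.T)
            wf.columns = [f"ch{i}" for i in range(u.waveform_mean.shape[0])]
            wf.to_csv(udir / f"{u.unit_id}_waveform.csv", index=False, float_format="%.17g")
            if u.waveform_evoked is not None:
                wfe = pd.DataFrame(u.waveform_evoked.T)
                wfe.columns = [f"ch{i}" for i in range(u.waveform_evoked.shape[0])]
                wfe.to_csv(udir / f"{u.unit_id}_waveform_evoked.csv", index=False, float_format="%.17g")
            if u.light_pulses.size:
                pd.DataFrame({"pulse_onset": u.light_pulses}).to_csv(
                    udir / f"{u.unit_id}_pulses.csv", index=False, float_format="%.17g"
                )
    if session.position is not None:
        pd.DataFrame(
            {"time": session.position.times, "x": session.position.xy[:, 0], "y": session.position.xy[:, 1]}
        ).to_csv(path / "position.csv", index=False, float_format="%.17g")
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _require_cols(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{what} is missing required column '{c}'")


def _read_csv(path: Path) -> Session:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SchemaError(f"no meta.json in session directory {path}")
    meta = json.loads(meta_path.read_text())
    session = Session()
    if (path / "trace.csv").exists():
        df = pd.read_csv(path / "trace.csv", float_precision="round_trip")
        _require_cols(df, ["value"], "trace.csv")
        pm = meta.get("photometry")
        if pm is None or "rate" not in pm:
            raise SchemaError("meta.json is missing required column 'photometry.rate'")
        session.recording = Recording(
            df["value"].to_numpy(), pm["rate"], pm.get("t0", 0.0), pm.get("channel_label", "gcamp")
        )
    if (path / "events.csv").exists():
        session.events = EventStream.from_frame(pd.read_csv(path / "events.csv", float_precision="round_trip"))
    for um in meta.get("units", []):
        uid = um["unit_id"]
        sp = pd.read_csv(path / "units" / f"{uid}_spikes.csv", float_precision="round_trip")
        _require_cols(sp, ["spike_time"], f"{uid}_spikes.csv")
        wf = pd.read_csv(path / "units" / f"{uid}_waveform.csv", float_precision="round_trip").to_numpy().T
        ppath = path / "units" / f"{uid}_pulses.csv"
        pulses = (
            pd.read_csv(ppath, float_precision="round_trip")["pulse_onset"].to_numpy() if ppath.exists() else np.empty(0)
        )
        epath = path / "units" / f"{uid}_waveform_evoked.csv"
        wfe = pd.read_csv(epath, float_precision="round_trip").to_numpy().T if epath.exists() else None
        session.units.append(
            SpikeUnit(
                sp["spike_time"].to_numpy(),
                wf,
                unit_id=uid,
                light_pulses=pulses,
                pulse_width=um.get("pulse_width", 0.005),
                t_start=um.get("t_start"),
                t_stop=um.get("t_stop"),
                waveform_evoked=wfe,
            )
        )
    if (path / "position.csv").exists():
        df = pd.read_csv(path / "position.csv", float_precision="round_trip")
        _require_cols(df, ["time", "x", "y"], "position.csv")
        session.position = PositionTrace(df["time"].to_numpy(), df[["x", "y"]].to_numpy())
    return session


# ---------------------------------------------------------------------------
# HDF5 container format
# ---------------------------------------------------------------------------

def _write_hdf5(session: Session, path: Path) -> Path:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "habpipe-session"
        f.attrs["version"] = 1
        if session.recording is not None:
            g = f.create_group("photometry")
            g.create_dataset("trace", data=session.recording.trace)
            g.attrs["rate"] = session.recording.rate
            g.attrs["t0"] = session.recording.t0
            g.attrs["channel_label"] = session.recording.channel_label
            g.attrs["units"] = "a.u."
        if session.events is not None:
            g = f.create_group("events")
            g.create_dataset("onset", data=session.events.onsets)
            g.create_dataset("duration", data=session.events.durations)
            g.create_dataset(
                "label", data=np.array([str(s) for s in session.events.labels], dtype="S64")
            )
        for u in session.units:
            g = f.create_group(f"units/{u.unit_id}")
            g.create_dataset("spike_times", data=u.spike_times)
            g.create_dataset("waveform_mean", data=u.waveform_mean)
            g.create_dataset("light_pulses", data=u.light_pulses)
            if u.waveform_evoked is not None:
                g.create_dataset("waveform_evoked", data=u.waveform_evoked)
            g.attrs["pulse_width"] = u.pulse_width
            if u.t_start is not None:
                g.attrs["t_start"] = u.t_start
            if u.t_stop is not None:
                g.attrs["t_stop"] = u.t_stop
        if session.position is not None:
            g = f.create_group("position")
            g.create_dataset("times", data=session.position.times)
            g.create_dataset("xy", data=session.position.xy)
            g.attrs["units"] = "cm"
    return path


def _read_hdf5(path: Path) -> Session:
    session = Session()
    with h5py.File(path, "r") as f:
        if "photometry" in f:
            g = f["photometry"]
            if "trace" not in g:
                raise SchemaError("group /photometry is missing required dataset 'trace'")
            if "rate" not in g.attrs:
                raise SchemaError("group /photometry is missing required attribute 'rate'")
            session.recording = Recording(
                g["trace"][...],
                float(g.attrs["rate"]),
                float(g.attrs.get("t0", 0.0)),
                str(g.attrs.get("channel_label", "gcamp")),
            )
        if "events" in f:
            g = f["events"]
            for name in ("onset", "label", "duration"):
                if name not in g:
                    raise SchemaError(f"group /events is missing required dataset '{name}'")
            session.events = EventStream(
                g["onset"][...],
                np.array([s.decode() for s in g["label"][...]], dtype=object),
                g["duration"][...],
            )
        if "units" in f:
            for uid in f["units"]:
                g = f["units"][uid]
                wfe = g["waveform_evoked"][...] if "waveform_evoked" in g else None
                session.units.append(
                    SpikeUnit(
                        g["spike_times"][...],
                        g["waveform_mean"][...],
                        unit_id=uid,
                        light_pulses=g["light_pulses"][...],
                        pulse_width=float(g.attrs.get("pulse_width", 0.005)),
                        t_start=float(g.attrs["t_start"]) if "t_start" in g.attrs else None,
                        t_stop=float(g.attrs["t_stop"]) if "t_stop" in g.attrs else None,
                        waveform_evoked=wfe,
                    )
                )
        if "position" in f:
            g = f["position"]
            session.position = PositionTrace(g["times"][...], g["xy"][...])
    return session


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

_FORMATS = ("csv", "hdf5")


def write_session(session: Session, path, format: str = "hdf5") -> Path:
    """Write a session to ``path`` in the given format; returns the path.

    The file is re-readable by :func:`read_session` with loss only from
    declared float precision (none: both formats store float64 exactly;
    CSV uses full ``repr`` precision).
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    path = Path(path)
    log.info("writing %s session to %s", format, path)
    return _write_csv(session, path) if format == "csv" else _write_hdf5(session, path)


def read_session(path, format: str | None = None) -> Session:
    """Read a session written by :func:`write_session`.

    ``format`` is inferred from the path when omitted (directory -> csv,
    file -> hdf5).  All type invariants are validated on load; sessions
    violating them are rejected, never silently repaired.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.is_dir() else "hdf5"
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {_FORMATS}")
    return _read_csv(path) if format == "csv" else _read_hdf5(path)
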