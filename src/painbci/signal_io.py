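"""Recording/event/decoder-artifact I/O and deterministic playback streaming.

Recordings are channels x samples matrices with a sampling rate and a
modality tag (``EEG`` in microvolts, ``SC`` in microsiemens).  On disk a
recording is either an EDF file (16-bit, EEG-oriented) or a plain CSV
matrix (one row per channel) accompanied by a small JSON sidecar holding
the sampling rate, channel labels and modality.  Event tables follow the
BIDS events convention (TSV with ``onset``, ``duration``, ``trial_type``,
``event_id``).
"""

from __future__ import annotations

import io as _stdio
import json
import pickle
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import _edf

VALID_LABELS = ("P", "NP", "R")
VALID_MODALITIES = ("EEG", "SC")


class FormatError(ValueError):
    """A file on disk could not be parsed into a domain object."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Uniformly sampled multichannel signal.

    Parameters
    ----------
    data:
        ``(n_channels, n_samples)`` real matrix; microvolts for EEG,
        microsiemens for SC.
    fs:
        Sampling rate in Hz, strictly positive.
    channel_names:
        Ordered channel labels, one per row of ``data``.
    modality:
        ``"EEG"`` or ``"SC"``.  SC recordings carry exactly one channel.
    t0:
        Start time in seconds (default 0).
    meta:
        Free-form annotations (e.g. filter transient extent); never
        required for correctness.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    modality: str
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_names = list(self.channel_names)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")
        if self.modality not in VALID_MODALITIES:
            raise ValidationError(
                f"modality must be one of {VALID_MODALITIES}, got {self.modality!r}"
            )
        if self.data.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError("recording contains non-finite samples")
        if self.modality == "SC" and self.data.shape[0] != 1:
            raise ValidationError("SC recordings must have exactly 1 channel")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.fs, list(self.channel_names),
            self.modality, self.t0, dict(self.meta),
        )


# ---------------------------------------------------------------------------
# EventTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    event_id: int
    onset: float
    duration: float
    label: str


@dataclass
class EventTable:
    """Ordered condition markers (onset/duration seconds, label P/NP/R)."""

    events: list[Event]

    def __post_init__(self) -> None:
        evs = [e if isinstance(e, Event) else Event(*e) for e in self.events]
        self.events = evs
        onsets = [e.onset for e in evs]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("event onsets must be non-decreasing")
        if any(e.duration <= 0 for e in evs):
            raise ValidationError("event durations must be > 0")
        ids = [e.event_id for e in evs]
        if len(set(ids)) != len(ids):
            raise ValidationError("event ids must be unique")
        bad = sorted({e.label for e in evs} - set(VALID_LABELS))
        if bad:
            raise ValidationError(
                f"unknown labels {bad}; allowed labels are {list(VALID_LABELS)}"
            )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def select(self, labels: Sequence[str]) -> "EventTable":
        keep = set(labels)
        return EventTable([e for e in self.events if e.label in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": [e.onset for e in self.events],
                "duration": [e.duration for e in self.events],
                "trial_type": [e.label for e in self.events],
                "event_id": [e.event_id for e in self.events],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        required = {"onset", "duration", "trial_type", "event_id"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"event table missing columns: {sorted(missing)}")
        return cls(
            [
                Event(int(r.event_id), float(r.onset), float(r.duration),
                      str(r.trial_type))
                for r in df.itertuples()
            ]
        )


def read_events(path: str | Path) -> EventTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such events file: {path}")
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        return EventTable([])
    return EventTable.from_frame(df)


def write_events(path: str | Path, table: EventTable) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Recording round-trip (CSV + sidecar, EDF)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(path: str | Path, rec: Recording, format: str | None = None) -> None:
    """Write a recording as ``csv`` (+ JSON sidecar) or ``edf``."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        np.savetxt(path, rec.data, delimiter=",", fmt="%.17g")
        sidecar = {
            "fs": rec.fs,
            "channel_names": rec.channel_names,
            "modality": rec.modality,
            "t0": rec.t0,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    elif fmt == "edf":
        _edf.write_edf(path, rec.data, rec.fs, rec.channel_names,
                       physical_dim="uV" if rec.modality == "EEG" else "uS",
                       recording_id=f"modality={rec.modality} t0={rec.t0}")
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None,
                   modality: str | None = None) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such recording file: {path}")
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "csv":
        side = _sidecar_path(path)
        if not side.exists():
            raise FormatError(f"missing sidecar metadata file: {side}")
        meta = json.loads(side.read_text())
        data = _read_csv_matrix(path)
        return Recording(data, float(meta["fs"]), meta["channel_names"],
                         modality or meta["modality"], float(meta.get("t0", 0.0)))
    if fmt == "edf":
        data, fs, names, rec_id = _edf.read_edf(path)
        mod = modality
        if mod is None:
            mod = "EEG"
            for tok in rec_id.split():
                if tok.startswith("modality="):
                    mod = tok.split("=", 1)[1]
        t0 = 0.0
        for tok in rec_id.split():
            if tok.startswith("t0="):
                t0 = float(tok.split("=", 1)[1])
        return Recording(data, fs, names, mod, t0)
    raise ValueError(f"unknown recording format {fmt!r}")


def _read_csv_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            vals = []
            for j, cell in enumerate(line.split(","), start=1):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at row {i}, column {j}"
                    ) from None
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty recording file")
    if len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path}: ragged rows")
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------------
# Decoder artifact
# ---------------------------------------------------------------------------

@dataclass
class DecoderArtifact:
    """Everything needed to classify one preprocessed window.

    ``scaler_mean``/``scaler_sd`` are the per-feature z-scoring statistics
    estimated on the training table; ``svm`` is a fitted probabilistic
    RBF-SVM classifier.
    """

    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    svm: object
    classes: list[str]
    modality: str
    feature_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scaler_mean = np.asarray(self.scaler_mean, dtype=float)
        self.scaler_sd = np.asarray(self.scaler_sd, dtype=float)
        if len(self.scaler_mean) != len(self.feature_names):
            raise ValidationError("scaler length does not match feature names")
        if len(self.scaler_sd) != len(self.feature_names):
            raise ValidationError("scaler length does not match feature names")
        if np.any(self.scaler_sd <= 0):
            raise ValidationError("scaler SDs must be > 0")
        if self.modality not in VALID_MODALITIES:
            raise ValidationError(f"bad modality {self.modality!r}")
        if len(self.classes) not in (2, 3):
            raise ValidationError("classes must have 2 or 3 members")

    def save(self, path: str | Path) -> None:
        """Serialize as a zip of JSON metadata + numeric arrays + model."""
        path = Path(path)
        meta = {
            "classes": self.classes,
            "modality": self.modality,
            "feature_names": self.feature_names,
            "meta": self.meta,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=2))
            for name, arr in (("scaler_mean", self.scaler_mean),
                              ("scaler_sd", self.scaler_sd)):
                buf = _stdio.BytesIO()
                np.save(buf, arr)
                zf.writestr(f"{name}.npy", buf.getvalue())
            zf.writestr("svm.pkl", pickle.dumps(self.svm))

    @classmethod
    def load(cls, path: str | Path) -> "DecoderArtifact":
        with zipfile.ZipFile(Path(path)) as zf:
            meta = json.loads(zf.read("meta.json"))
            mean = np.load(_stdio.BytesIO(zf.read("scaler_mean.npy")))
            sd = np.load(_stdio.BytesIO(zf.read("scaler_sd.npy")))
            svm = pickle.loads(zf.read("svm.pkl"))
        return cls(mean, sd, svm, meta["classes"], meta["modality"],
                   meta["feature_names"], meta.get("meta", {}))


# ---------------------------------------------------------------------------
# Playback streaming
# ---------------------------------------------------------------------------

def playback_stream(rec: Recording, chunk_s: float):
    """Yield contiguous ``(chunk_start_s, chunk)`` pairs emulating live capture.

    Chunks are half-open ``[start, start + chunk_s)`` slices of the
    recording; a final remainder shorter than ``chunk_s`` is dropped.
    """
    if chunk_s <= 0:
        raise ValidationError(f"chunk_s must be > 0, got {chunk_s}")
    n_chunk_f = chunk_s * rec.fs
    n_chunk = int(round(n_chunk_f))
    if abs(n_chunk_f - n_chunk) > 1e-6 * max(1.0, n_chunk_f):
        raise ValidationError(
            f"chunk of {chunk_s} s is not an integer number of samples at "
            f"{rec.fs} Hz"
        )
    if n_chunk == 0:
        raise ValidationError("chunk shorter than one sample")
    n_chunks = rec.n_samples // n_chunk
    for k in range(n_chunks):
        start = k * n_chunk
        yield rec.t0 + start / rec.fs, rec.data[:, start:start + n_chunk]
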