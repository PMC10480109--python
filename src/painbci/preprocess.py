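"""Band-pass filtering, channel selection, windowing and artifact rejection.

Defaults mirror the offline processing used for decoder training: EEG is
band-passed 3-40 Hz with an order-2000 Hamming-windowed sinc FIR filter
(applied one-pass with group-delay compensation so windows stay aligned
to events), skin conductance 0.05-2 Hz with a Chebyshev type-I filter of
order 3.  Observation windows of fixed length are cut from within each
event epoch (never across epoch boundaries) and tagged with the epoch's
label and event id; windows whose peak-to-peak amplitude exceeds a
modality-specific threshold on any channel are rejected as artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import EventTable, Recording, ValidationError

logger = logging.getLogger(__name__)

EEG_CHANNELS_DEFAULT = ["Cz", "C3", "C4", "CPz", "CP1", "CP2"]

EEG_FILTER_DEFAULTS = dict(family="fir_hamming_sinc", low_hz=3.0, high_hz=40.0,
                           order=2000)
SC_FILTER_DEFAULTS = dict(family="cheby1", low_hz=0.05, high_hz=2.0, order=3,
                          ripple_db=0.5)

EEG_PTP_THRESHOLD = 150.0  # uV
SC_PTP_THRESHOLD = 10.0    # uS


@dataclass(frozen=True)
class FilterSpec:
    family: str                 # "fir_hamming_sinc" | "cheby1"
    low_hz: float
    high_hz: float
    order: int                  # FIR taps - 1, or IIR poles
    ripple_db: float = 0.5      # cheby1 only

    def validate(self, fs: float) -> None:
        if self.family not in ("fir_hamming_sinc", "cheby1"):
            raise ValidationError(f"unknown filter family {self.family!r}")
        if not (0 <= self.low_hz < self.high_hz):
            raise ValidationError("need 0 <= low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ValidationError(
                f"high edge {self.high_hz} Hz >= Nyquist {fs / 2} Hz"
            )
        if self.order <= 0:
            raise ValidationError("filter order must be > 0")

    @classmethod
    def eeg_default(cls) -> "FilterSpec":
        return cls(**EEG_FILTER_DEFAULTS)

    @classmethod
    def sc_default(cls) -> "FilterSpec":
        return cls(**SC_FILTER_DEFAULTS)


@dataclass(frozen=True)
class WindowSpec:
    length_s: float
    overlap_frac: float = 0.0
    ptp_reject_threshold: float = np.inf

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValidationError("window length must be > 0")
        if not (0 <= self.overlap_frac < 1):
            raise ValidationError("overlap_frac must lie in [0, 1)")

    def n_samples(self, fs: float) -> int:
        """Window length in samples; the windowing routine's size rule."""
        n = self.length_s * fs
        n_int = int(round(n))
        if abs(n - n_int) > 1e-6 * max(1.0, n):
            raise ValidationError(
                f"window of {self.length_s} s is not an integer number of "
                f"samples at {fs} Hz"
            )
        return n_int

    def step_samples(self, fs: float) -> int:
        step = self.length_s * (1.0 - self.overlap_frac) * fs
        step_int = max(1, int(round(step)))
        return step_int


@dataclass(frozen=True)
class Window:
    window_id: int
    event_id: int          # group key for fold assignment
    start_s: float
    label: str
    data: np.ndarray       # channels x samples


@dataclass
class WindowSet:
    windows: list[Window]
    fs: float
    channel_names: list[str] = field(default_factory=list)
    modality: str = "EEG"

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def labels(self) -> list[str]:
        return [w.label for w in self.windows]

    def groups(self) -> list[int]:
        return [w.event_id for w in self.windows]

    def stacked(self) -> np.ndarray:
        """windows x channels x samples array (requires uniform shape)."""
        return np.stack([w.data for w in self.windows])


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def design_filter(spec: FilterSpec, fs: float):
    """Return ``("fir", taps)`` or ``("sos", sections)`` for the given rate."""
    spec.validate(fs)
    if spec.family == "fir_hamming_sinc":
        taps = sps.firwin(spec.order + 1, [spec.low_hz, spec.high_hz],
                          pass_zero=False, window="hamming", fs=fs)
        return "fir", taps
    sos = sps.cheby1(spec.order, spec.ripple_db,
                     [spec.low_hz, spec.high_hz], btype="bandpass",
                     output="sos", fs=fs)
    return "sos", sos


def bandpass(rec: Recording, spec: FilterSpec) -> Recording:
    """Filter each channel; FIR output is compensated for group delay.

    The FIR path convolves and shifts by ``order/2`` samples so filtered
    features stay time-aligned with the event table; the first and last
    ``order/2`` samples are transient-affected and flagged in
    ``meta["filter_transient_s"]``.
    """
    kind, coef = design_filter(spec, rec.fs)
    out = rec.copy()
    if kind == "fir":
        delay = spec.order // 2
        full = sps.fftconvolve(rec.data, coef[None, :], mode="full", axes=1)
        out.data = full[:, delay:delay + rec.n_samples]
        out.meta["filter_transient_s"] = delay / rec.fs
    else:
        out.data = sps.sosfilt(coef, rec.data, axis=1)
        out.meta["filter_transient_s"] = spec.order / spec.low_hz / 50.0
    out.meta["filter"] = spec
    return out


class StreamingFilter:
    """Causal per-channel filter that keeps state across playback chunks.

    Feeding the same signal chunk-by-chunk or in one call yields identical
    output, so chunk boundaries introduce no discontinuity.
    """

    def __init__(self, spec: FilterSpec, fs: float, n_channels: int):
        self.kind, self.coef = design_filter(spec, fs)
        if self.kind == "fir":
            zi = sps.lfilter_zi(self.coef, [1.0])
        else:
            zi = sps.sosfilt_zi(self.coef)
        self._zi = (np.repeat(zi[None, :], n_channels, axis=0)
                    if self.kind == "fir"
                    else np.repeat(zi[:, None, :], n_channels, axis=1)) * 0.0

    def process(self, chunk: np.ndarray) -> np.ndarray:
        chunk = np.atleast_2d(chunk)
        if self.kind == "fir":
            out, self._zi = sps.lfilter(self.coef, [1.0], chunk, axis=1,
                                        zi=self._zi)
        else:
            out, self._zi = sps.sosfilt(self.coef, chunk, axis=1, zi=self._zi)
        return out


# ---------------------------------------------------------------------------
# Channel selection
# ---------------------------------------------------------------------------

def select_channels(rec: Recording, names: Sequence[str]) -> Recording:
    """Sub-recording with rows reordered to ``names``."""
    missing = [n for n in names if n not in rec.channel_names]
    if missing:
        raise ValidationError(
            f"channels {missing} not present; available: {rec.channel_names}"
        )
    idx = [rec.channel_names.index(n) for n in names]
    out = rec.copy()
    out.data = rec.data[idx]
    out.channel_names = list(names)
    return out


# ---------------------------------------------------------------------------
# Windowing and artifact rejection
# ---------------------------------------------------------------------------

def window_count(duration_n: int, length_n: int, step_n: int) -> int:
    """Closed-form number of windows fitting in an epoch."""
    if duration_n < length_n:
        return 0
    return (duration_n - length_n) // step_n + 1


def extract_windows(rec: Recording, events: EventTable,
                    spec: WindowSpec) -> WindowSet:
    """Cut fixed-size windows from within each event epoch.

    Windows start at the epoch onset and advance by
    ``length * (1 - overlap)`` while they still fit inside the epoch; each
    inherits the epoch's label and event id (the grouping key for
    cross-validation).
    """
    length_n = spec.n_samples(rec.fs)
    step_n = spec.step_samples(rec.fs)
    windows: list[Window] = []
    wid = 0
    for ev in events:
        onset_n = int(round((ev.onset - rec.t0) * rec.fs))
        dur_n = int(round(ev.duration * rec.fs))
        if onset_n < 0 or onset_n + dur_n > rec.n_samples:
            raise ValidationError(
                f"event {ev.event_id} ({ev.onset}s +{ev.duration}s) does not "
                f"fit inside the recording ({rec.duration:.3f}s)"
            )
        k = window_count(dur_n, length_n, step_n)
        if k == 0:
            logger.info("event %d shorter than window; skipped", ev.event_id)
        for i in range(k):
            s = onset_n + i * step_n
            windows.append(Window(wid, ev.event_id, rec.t0 + s / rec.fs,
                                  ev.label, rec.data[:, s:s + length_n]))
            wid += 1
    return WindowSet(windows, rec.fs, list(rec.channel_names), rec.modality)


def peak_to_peak(data: np.ndarray) -> float:
    """Max over channels of within-window max minus min."""
    data = np.atleast_2d(data)
    return float((data.max(axis=1) - data.min(axis=1)).max())


def reject_artifacts(ws: WindowSet, threshold: float):
    """Partition windows into (kept, rejected) by the peak-to-peak rule.

    A window is rejected iff any channel's peak-to-peak amplitude exceeds
    ``threshold``.
    """
    if threshold <= 0:
        raise ValidationError("artifact threshold must be > 0")
    kept, rejected = [], []
    for w in ws:
        (rejected if peak_to_peak(w.data) > threshold else kept).append(w)
    mk = lambda lst: WindowSet(lst, ws.fs, list(ws.channel_names), ws.modality)
    return mk(kept), mk(rejected)
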