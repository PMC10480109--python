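"""Simulated real-time detection engines and trigger evaluation.

The healthy-subject engine replays an EEG and an SC recording on a
half-second tick: each tick the EEG classifier consumes one 0.5-s chunk
and the SC classifier the last 2 s of signal, each emitting a pain
probability.  Every second the most recent classifications (up to two
per modality) are merged by a weighted mean of posteriors; a fused
probability strictly above threshold releases the intervention, which
then holds for a refractory period.  The patient engine classifies 1-s
windows, smooths with a majority vote over the last three labels, and
marks 6-s chunks (aligned to block starts) as released iff any smoothed
pain label falls inside them.

A painful event counts as detected iff at least one trigger falls in the
response window from its onset through 4 s past its end; non-painful and
rest events count as correct iff that window contains no trigger.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Protocol

import numpy as np

from . import decode, features, preprocess
from .signal_io import DecoderArtifact, EventTable, Recording, ValidationError


@dataclass(frozen=True)
class EngineConfig:
    eeg_chunk_s: float = 0.5
    sc_chunk_s: float = 2.0
    decision_period_s: float = 1.0
    fusion_window_n: int = 4
    eeg_weight: float = 0.5
    sc_weight: float = 0.5
    trigger_threshold: float = 0.5
    grace_s: float = 4.0
    intervention_s: float = 10.0        # refractory after a trigger
    eeg_ptp_threshold: float = preprocess.EEG_PTP_THRESHOLD
    sc_ptp_threshold: float = preprocess.SC_PTP_THRESHOLD
    patient_row_s: float = 1.0
    patient_vote_n: int = 3
    patient_chunk_s: float = 6.0

    def __post_init__(self) -> None:
        if min(self.eeg_chunk_s, self.sc_chunk_s, self.decision_period_s,
               self.grace_s) <= 0:
            raise ValidationError("engine durations must be > 0")
        w = self.eeg_weight + self.sc_weight
        if self.eeg_weight < 0 or self.sc_weight < 0 or abs(w - 1) > 1e-9:
            raise ValidationError("modality weights must be >= 0 and sum to 1")
        if self.patient_vote_n % 2 != 1:
            raise ValidationError("patient_vote_n must be odd")


@dataclass(frozen=True)
class Classification:
    id: int
    t: float
    modality: str
    p_pain: float
    label: str
    no_decision: bool = False


@dataclass(frozen=True)
class FusedDecision:
    t: float
    p_pain: float
    trigger: bool
    member_ids: tuple


@dataclass
class DecisionLog:
    classifications: list = field(default_factory=list)
    fused: list = field(default_factory=list)
    trigger_times: list = field(default_factory=list)

    def add_classification(self, t, modality, p_pain, label,
                           no_decision=False) -> Classification:
        c = Classification(len(self.classifications), round(t, 6), modality,
                           float(p_pain), label, no_decision)
        self.classifications.append(c)
        return c

    def recent(self, modality: str, t: float, span: float, limit: int):
        """Most recent <= limit classifications of a modality in (t-span, t]."""
        eps = 1e-9
        picked = [c for c in self.classifications
                  if c.modality == modality and t - span - eps < c.t <= t + eps]
        return picked[-limit:]

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in self.classifications:
                fh.write(json.dumps({"kind": "classification", **asdict(c)}) + "\n")
            for f in self.fused:
                d = asdict(f)
                d["member_ids"] = list(f.member_ids)
                fh.write(json.dumps({"kind": "fused", **d}) + "\n")
            for t in self.trigger_times:
                fh.write(json.dumps({"kind": "trigger", "t": t}) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "DecisionLog":
        log = cls()
        for line in Path(path).read_text().splitlines():
            d = json.loads(line)
            kind = d.pop("kind")
            if kind == "classification":
                d.pop("id")
                log.add_classification(**d)
            elif kind == "fused":
                log.fused.append(FusedDecision(d["t"], d["p_pain"],
                                               d["trigger"],
                                               tuple(d["member_ids"])))
            else:
                log.trigger_times.append(d["t"])
        return log


# ---------------------------------------------------------------------------
# Chunk classifiers
# ---------------------------------------------------------------------------

class ChunkClassifier(Protocol):
    modality: str

    def push(self, samples: np.ndarray) -> None: ...
    def classify(self, t: float): ...


class OnlineClassifier:
    """Stateful chunk classifier around a trained decoder artifact.

    Incoming raw samples are passed through the same causal band-pass
    filter used offline (state kept across chunks); classification runs
    on the trailing window of filtered signal.  Windows failing the
    peak-to-peak artifact check yield a no-decision that carries the
    previous valid probability forward (0 before any valid window).
    """

    def __init__(self, artifact: DecoderArtifact, fs: float, window_s: float,
                 filter_spec: preprocess.FilterSpec, ptp_threshold: float,
                 channel_names=None, feature_cfg=None):
        self.artifact = artifact
        self.modality = artifact.modality
        self.fs = fs
        self.window_n = int(round(window_s * fs))
        self.ptp_threshold = ptp_threshold
        self.channel_names = channel_names
        self.feature_cfg = feature_cfg or features.FeatureConfig()
        n_ch = len(channel_names) if channel_names else 1
        self._filter = preprocess.StreamingFilter(filter_spec, fs, n_ch)
        self._buffer = np.empty((n_ch, 0))
        self._raw = np.empty((n_ch, 0))
        self._last_p = 0.0
        self._not_pain = next(c for c in artifact.classes if c != "P")

    def push(self, samples: np.ndarray) -> None:
        samples = np.atleast_2d(samples)
        filtered = self._filter.process(samples)
        keep = self.window_n + 8
        self._buffer = np.concatenate([self._buffer, filtered],
                                      axis=1)[:, -keep:]
        self._raw = np.concatenate([self._raw, samples], axis=1)[:, -keep:]

    def classify(self, t: float):
        """Return ``(p_pain, label, no_decision)`` or None during warm-up."""
        if self._buffer.shape[1] < self.window_n:
            return None
        window = self._buffer[:, -self.window_n:]
        # immediate artifact screen on the raw (unfiltered) window: the
        # causal filter would smear and delay a spike out of this chunk
        if preprocess.peak_to_peak(self._raw[:, -self.window_n:]) > self.ptp_threshold:
            p = self._last_p
            return p, ("P" if p > 0.5 else self._not_pain), True
        if self.modality == "EEG":
            row = features.eeg_feature_vector(window, self.fs,
                                              self.channel_names,
                                              self.feature_cfg)
        else:
            row = features.sc_feature_vector(window, self.fs)
        p = float(decode.p_pain(self.artifact, row.to_numpy()[None, :])[0])
        self._last_p = p
        return p, ("P" if p > 0.5 else self._not_pain), False


class OracleClassifier:
    """Test double emitting posterior 1 for the true condition of a chunk."""

    def __init__(self, modality: str, events: EventTable, window_s: float):
        self.modality = modality
        self.window_s = window_s
        self._pain = [(e.onset, e.onset + e.duration) for e in events
                      if e.label == "P"]
        self._n_pushed = 0.0

    def push(self, samples: np.ndarray) -> None:
        pass

    def classify(self, t: float):
        a, b = t - self.window_s, t
        pain = any(a < hi and b > lo for lo, hi in self._pain)
        p = 1.0 if pain else 0.0
        return p, ("P" if pain else "R"), False


def classify_chunk(clf: ChunkClassifier, chunk: np.ndarray, t: float):
    """Feed one chunk to a stateful classifier and classify at its end."""
    clf.push(chunk)
    return clf.classify(t)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def fuse_recent(log: DecisionLog, t: float, cfg: EngineConfig):
    """Weighted mean of each modality's recent posteriors at decision time t.

    Takes the most recent <= 2 EEG and <= 2 SC classifications within the
    last decision period; a missing modality renormalizes the weights.
    Returns None when no classifications are available.
    """
    per_mod = cfg.fusion_window_n // 2
    eeg = log.recent("EEG", t, cfg.decision_period_s, per_mod)
    sc = log.recent("SC", t, cfg.decision_period_s, per_mod)
    members = eeg + sc
    if not members:
        return None
    num = 0.0
    den = 0.0
    for group, w in ((eeg, cfg.eeg_weight), (sc, cfg.sc_weight)):
        if group:
            num += w * float(np.mean([c.p_pain for c in group]))
            den += w
    p = num / den
    return FusedDecision(round(t, 6), p, p > cfg.trigger_threshold,
                         tuple(c.id for c in members))


# ---------------------------------------------------------------------------
# Engines
# ---------------------------------------------------------------------------

def run_healthy_engine(eeg: Recording, sc: Recording,
                       decoders: dict, events: EventTable | None = None,
                       cfg: EngineConfig | None = None) -> DecisionLog:
    """Replay a dual-modality session through the fusion engine.

    ``decoders`` maps modality to a :class:`ChunkClassifier`
    (:class:`OnlineClassifier` for real artifacts, or an oracle).
    """
    cfg = cfg or EngineConfig()
    log = DecisionLog()
    tick = cfg.eeg_chunk_s
    n_ticks = int(math.floor(eeg.duration / tick + 1e-9))
    eeg_chunks = preprocess_playback(eeg, tick)
    sc_clf = decoders.get("SC")
    eeg_clf = decoders.get("EEG")
    sc_fed = 0
    next_decision = cfg.decision_period_s
    refractory_until = -np.inf
    for k in range(n_ticks):
        t = (k + 1) * tick
        if eeg_clf is not None:
            res = classify_chunk(eeg_clf, eeg_chunks[k][1], t)
            if res is not None:
                log.add_classification(t, "EEG", res[0], res[1], res[2])
        if sc_clf is not None:
            upto = int(round(t * sc.fs))
            upto = min(upto, sc.n_samples)
            if upto > sc_fed:
                sc_clf.push(sc.data[:, sc_fed:upto])
                sc_fed = upto
            res = sc_clf.classify(t)
            if res is not None:
                log.add_classification(t, "SC", res[0], res[1], res[2])
        if t + 1e-9 >= next_decision:
            fd = fuse_recent(log, next_decision, cfg)
            if fd is not None:
                trig = fd.trigger and next_decision > refractory_until
                fd = FusedDecision(fd.t, fd.p_pain, trig, fd.member_ids)
                log.fused.append(fd)
                if trig:
                    log.trigger_times.append(fd.t)
                    refractory_until = fd.t + cfg.intervention_s
            next_decision += cfg.decision_period_s
    return log


def preprocess_playback(rec: Recording, chunk_s: float):
    from .signal_io import playback_stream
    return list(playback_stream(rec, chunk_s))


def run_patient_engine(eeg: Recording, decoder: ChunkClassifier,
                       blocks: EventTable,
                       cfg: EngineConfig | None = None) -> DecisionLog:
    """Majority-vote patient pipeline over 1-s windows and 6-s chunks.

    The smoothed label at second ``t`` is the majority of the last
    ``patient_vote_n`` raw labels (no output until that many exist).  A
    6-s chunk, aligned to its block start, is released iff any smoothed
    pain label falls at a time inside it; releases are logged as
    triggers at the chunk's first pain decision.
    """
    cfg = cfg or EngineConfig()
    log = DecisionLog()
    row = cfg.patient_row_s
    n_ticks = int(math.floor(eeg.duration / row + 1e-9))
    chunks = preprocess_playback(eeg, row)
    raw_labels: list[str] = []
    finals: list[tuple[float, str]] = []
    for k in range(n_ticks):
        t = (k + 1) * row
        res = classify_chunk(decoder, chunks[k][1], t)
        if res is None:
            continue
        p, label, nd = res
        log.add_classification(t, "EEG", p, label, nd)
        raw_labels.append(label)
        if len(raw_labels) >= cfg.patient_vote_n:
            last = raw_labels[-cfg.patient_vote_n:]
            n_pain = sum(1 for x in last if x == "P")
            final = "P" if n_pain > cfg.patient_vote_n // 2 else "R"
            finals.append((t, final))
            log.fused.append(FusedDecision(t, n_pain / cfg.patient_vote_n,
                                           final == "P", ()))
    # chunk bookkeeping: release iff any smoothed pain decision inside
    for ev in blocks:
        n_chunks = int(round(ev.duration / cfg.patient_chunk_s))
        for c in range(n_chunks):
            a = ev.onset + c * cfg.patient_chunk_s
            b = a + cfg.patient_chunk_s
            hits = [t for (t, lab) in finals if a < t <= b + 1e-9 and lab == "P"]
            if hits:
                log.trigger_times.append(hits[0])
    return log


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class TriggerReport:
    """Per-class trigger correctness for the healthy closed-loop rule."""

    per_class_correct: dict
    per_class_total: dict
    trigger_rate: dict          # fraction of events with >= 1 trigger

    def rate(self, cls: str) -> float:
        tot = self.per_class_total.get(cls, 0)
        return self.per_class_correct.get(cls, 0) / tot if tot else 0.0

    def to_dict(self) -> dict:
        return {
            "correct": self.per_class_correct,
            "total": self.per_class_total,
            "trigger_rate": self.trigger_rate,
            "rates": {c: self.rate(c) for c in self.per_class_total},
        }


def evaluate_triggers(log: DecisionLog, events: EventTable,
                      cfg: EngineConfig | None = None,
                      mode: str = "healthy"):
    """Score triggers against events.

    Healthy mode: an event's response window is ``(onset, end + grace]``;
    P events are correct iff it holds >= 1 trigger, NP/R events iff it
    holds none.  Patient mode: 6-s chunks inherit their block's label,
    are predicted painful iff released, and are scored as a confusion
    matrix (precision/recall over chunks).
    """
    cfg = cfg or EngineConfig()
    trig = np.asarray(sorted(log.trigger_times), dtype=float)
    if mode == "patient":
        y_true, y_pred = [], []
        for ev in events:
            n_chunks = int(round(ev.duration / cfg.patient_chunk_s))
            for c in range(n_chunks):
                a = ev.onset + c * cfg.patient_chunk_s
                b = a + cfg.patient_chunk_s
                released = bool(np.any((trig > a) & (trig <= b + 1e-9)))
                y_true.append(ev.label)
                y_pred.append("P" if released else "R")
        return decode.classification_metrics(y_true, y_pred, ["P", "R"])

    correct: dict = {}
    total: dict = {}
    triggered: dict = {}
    for ev in events:
        a = ev.onset
        b = ev.onset + ev.duration + cfg.grace_s
        hit = bool(np.any((trig > a + 1e-9) & (trig <= b + 1e-9)))
        ok = hit if ev.label == "P" else not hit
        total[ev.label] = total.get(ev.label, 0) + 1
        correct[ev.label] = correct.get(ev.label, 0) + int(ok)
        triggered[ev.label] = triggered.get(ev.label, 0) + int(hit)
    rate = {c: triggered[c] / total[c] for c in total}
    return TriggerReport(correct, total, rate)


def modality_contribution(log: DecisionLog, events: EventTable,
                          cfg: EngineConfig | None = None):
    """(eeg_frac, sc_frac) posterior shares over correct pain triggers.

    For every fused decision that triggered inside some P event's
    response window, a modality's contribution is the sum of its members'
    pain posteriors over the sum of all members'; fractions are averaged
    across those decisions and sum to 1.
    """
    cfg = cfg or EngineConfig()
    windows = [(e.onset, e.onset + e.duration + cfg.grace_s)
               for e in events if e.label == "P"]
    by_id = {c.id: c for c in log.classifications}
    fracs = []
    for fd in log.fused:
        if not fd.trigger:
            continue
        if not any(a < fd.t <= b for a, b in windows):
            continue
        members = [by_id[i] for i in fd.member_ids]
        tot = sum(c.p_pain for c in members)
        if tot <= 0 or not members:
            continue
        eeg = sum(c.p_pain for c in members if c.modality == "EEG")
        fracs.append(eeg / tot)
    if not fracs:
        return float("nan"), float("nan")
    eeg_frac = float(np.mean(fracs))
    return eeg_frac, 1.0 - eeg_frac


# ---------------------------------------------------------------------------
# Intervention pulse-width envelope
# ---------------------------------------------------------------------------

@dataclass
class WaveTrajectory:
    t: np.ndarray                       # seconds
    height: np.ndarray                  # wave height, >= 0
    contact_intervals: list             # [(start_s, end_s), ...]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if (self.height < 0).any():
            raise ValidationError("wave height must be >= 0")
        lo, hi = self.t[0], self.t[-1]
        for a, b in self.contact_intervals:
            if not (lo <= a < b <= hi + 1e-9):
                raise ValidationError("contact interval outside trajectory")


STIMULATION_FREQ_HZ = 50.0  # biphasic pulse rate; fixed metadata


def pulse_width_envelope(traj: WaveTrajectory, pw_max: float,
                         sigma_frac: float = 0.25) -> np.ndarray:
    """Gaussian pulse-width course tracking the wave within each contact.

    Inside a contact interval the pulse width follows
    ``pw_max * exp(-(t - t_peak)^2 / (2 sigma^2))`` with ``t_peak`` at the
    maximum wave height and ``sigma = sigma_frac * interval length``;
    outside contact the stimulation is off (width 0).
    """
    pw = np.zeros_like(traj.t)
    for a, b in traj.contact_intervals:
        mask = (traj.t >= a) & (traj.t <= b)
        if not mask.any():
            continue
        seg_t = traj.t[mask]
        t_peak = seg_t[int(np.argmax(traj.height[mask]))]
        sigma = sigma_frac * (b - a)
        pw[mask] = pw_max * np.exp(-((seg_t - t_peak) ** 2) / (2 * sigma ** 2))
    return pw
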