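"""Synthetic EEG / skin-conductance sessions with pain-like structure.

Two protocols are emulated: a "healthy" session of 12 painful (P), 12
non-painful (NP) and 12 rest (R) events in seeded random order (4 s
stimulation, 8 s inter-stimulus interval) and a "patient" session of six
minutes of alternating 30-s rest / focus-on-pain blocks.

The EEG generator is pink background noise plus alpha (10 Hz) and beta
(22 Hz) oscillators plus white noise; during P epochs the oscillator
amplitudes shrink and the white-noise floor grows, which lowers
narrow-band and total power/RMS while raising entropy and fractal
dimension.  The SC generator is a tonic level with slow drift plus a
stimulus-locked double-exponential phasic response (large for P, small
for NP, none for R).  Effect sizes are calibration choices made so that
default decoding accuracy is in a plausible range, not a reproduction of
any measured data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .signal_io import Event, EventTable, Recording

EEG_CHANNEL_NAMES = ["Cz", "C3", "C4", "CPz", "CP1", "CP2"]


@dataclass(frozen=True)
class SynthConfig:
    fs_eeg: float = 500.0
    fs_sc: float = 5.0
    n_channels: int = 6
    channel_names: tuple = tuple(EEG_CHANNEL_NAMES)
    # EEG background / oscillators (amplitudes in uV)
    pink_sigma: float = 5.0
    white_sigma: float = 0.6
    alpha_freq: float = 10.0
    alpha_amp: float = 1.5
    beta_freq: float = 22.0
    beta_amp: float = 0.9
    # pain-condition effects
    alpha_reduction: float = 0.4
    beta_reduction: float = 0.3
    broadband_noise_gain: float = 1.3
    # artifacts
    artifact_rate_per_min: float = 0.0
    artifact_amp: float = 300.0
    # skin conductance (uS)
    scr_latency_s: float = 1.5
    scr_rise_tau: float = 0.75
    scr_decay_tau: float = 2.0
    scr_amp_p: float = 1.0
    scr_amp_np: float = 0.1
    sc_tonic: float = 2.0
    sc_drift_amp: float = 0.15
    sc_noise_sigma: float = 0.2
    tail_s: float = 8.0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha_reduction < 1 and 0 <= self.beta_reduction < 1):
            raise ValueError("reductions must lie in [0, 1)")
        if self.fs_eeg <= 0 or self.fs_sc <= 0:
            raise ValueError("sampling rates must be > 0")
        if min(self.alpha_amp, self.beta_amp, self.pink_sigma,
               self.white_sigma) < 0:
            raise ValueError("amplitudes must be >= 0")

    def null(self) -> "SynthConfig":
        """Copy with every condition effect switched off."""
        return replace(self, alpha_reduction=0.0, beta_reduction=0.0,
                       broadband_noise_gain=1.0, scr_amp_p=0.0,
                       scr_amp_np=0.0)


@dataclass(frozen=True)
class ProtocolSpec:
    mode: str = "healthy"          # "healthy" | "patient"
    n_per_class: int = 12
    stimulation_s: float = 4.0
    isi_s: float = 8.0
    patient_total_s: float = 360.0
    patient_block_s: float = 30.0

    def __post_init__(self) -> None:
        if self.mode not in ("healthy", "patient"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.n_per_class <= 0 or self.stimulation_s <= 0:
            raise ValueError("counts and durations must be > 0")


def make_event_schedule(spec: ProtocolSpec, seed: int = 0) -> EventTable:
    """Seeded event schedule for either protocol.

    Healthy: ``3 * n_per_class`` events in shuffled order, onset
    ``k * (ST + ISI)``, duration ST.  Patient: alternating 30-s R/P
    blocks covering the total duration.
    """
    if spec.mode == "healthy":
        labels = ["P", "NP", "R"] * spec.n_per_class
        rng = np.random.default_rng(seed)
        rng.shuffle(labels)
        period = spec.stimulation_s + spec.isi_s
        return EventTable([
            Event(k, k * period, spec.stimulation_s, lab)
            for k, lab in enumerate(labels)
        ])
    n_blocks = int(round(spec.patient_total_s / spec.patient_block_s))
    return EventTable([
        Event(k, k * spec.patient_block_s, spec.patient_block_s,
              "R" if k % 2 == 0 else "P")
        for k in range(n_blocks)
    ])


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape, fs: float) -> np.ndarray:
    """1/f-power noise via spectral shaping, unit variance per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    return pink / np.where(sd > 0, sd, 1.0)


def _epoch_mask(schedule: EventTable, labels, n: int, fs: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for ev in schedule:
        if ev.label in labels:
            a = int(round(ev.onset * fs))
            b = int(round((ev.onset + ev.duration) * fs))
            mask[a:min(b, n)] = True
    return mask


def synth_eeg(schedule: EventTable, cfg: SynthConfig | None = None,
              seed: int = 0) -> Recording:
    """Multichannel EEG with pain-condition spectral effects during P epochs."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    fs = cfg.fs_eeg
    span = (schedule.events[-1].onset + schedule.events[-1].duration
            if len(schedule) else 0.0)
    n = int(round((span + cfg.tail_s) * fs))
    t = np.arange(n) / fs
    nch = cfg.n_channels

    pain = _epoch_mask(schedule, {"P"}, n, fs)
    alpha_env = np.where(pain, 1.0 - cfg.alpha_reduction, 1.0)
    beta_env = np.where(pain, 1.0 - cfg.beta_reduction, 1.0)
    noise_env = np.where(pain, cfg.broadband_noise_gain, 1.0)

    data = cfg.pink_sigma * _pink_noise(rng, (nch, n), fs)
    for amp, freq, env in ((cfg.alpha_amp, cfg.alpha_freq, alpha_env),
                           (cfg.beta_amp, cfg.beta_freq, beta_env)):
        phases = rng.uniform(0, 2 * np.pi, size=nch)
        # slow random amplitude modulation keeps oscillations non-stationary
        am = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.05, 0.2, nch)[:, None]
                                * t[None, :] + rng.uniform(0, 2 * np.pi,
                                                           nch)[:, None])
        data += amp * env[None, :] * am * np.sin(
            2 * np.pi * freq * t[None, :] + phases[:, None])
    data += cfg.white_sigma * noise_env[None, :] * rng.standard_normal((nch, n))

    if cfg.artifact_rate_per_min > 0:
        n_art = rng.poisson(cfg.artifact_rate_per_min * (n / fs) / 60.0)
        for _ in range(n_art):
            pos = rng.integers(0, max(1, n - 50))
            ch = rng.integers(0, nch)
            data[ch, pos:pos + 50] += cfg.artifact_amp * np.hanning(50)

    names = list(cfg.channel_names[:nch])
    names += [f"ch{i}" for i in range(len(names), nch)]
    return Recording(data, fs, names, "EEG")


# ---------------------------------------------------------------------------
# Skin conductance
# ---------------------------------------------------------------------------

def scr_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unnormalized double-exponential phasic response shape (0 for t < 0)."""
    out = np.zeros_like(t, dtype=float)
    pos = t >= 0
    out[pos] = np.exp(-t[pos] / decay_tau) - np.exp(-t[pos] / rise_tau)
    return out


def scr_peak_value(rise_tau: float, decay_tau: float) -> float:
    """Closed-form maximum of the double-exponential kernel."""
    tp = (np.log(decay_tau / rise_tau)
          * rise_tau * decay_tau / (decay_tau - rise_tau))
    return float(np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau))


def synth_sc(schedule: EventTable, cfg: SynthConfig | None = None,
             seed: int = 0) -> Recording:
    """Single-channel skin conductance with event-locked phasic responses."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    fs = cfg.fs_sc
    span = (schedule.events[-1].onset + schedule.events[-1].duration
            if len(schedule) else 0.0)
    n = int(round((span + cfg.tail_s) * fs))
    t = np.arange(n) / fs

    sig = np.full(n, cfg.sc_tonic, dtype=float)
    if cfg.sc_drift_amp > 0:
        sig += cfg.sc_drift_amp * np.sin(2 * np.pi * 0.01 * t
                                         + rng.uniform(0, 2 * np.pi))
    amp_of = {"P": cfg.scr_amp_p, "NP": cfg.scr_amp_np, "R": 0.0}
    peak = scr_peak_value(cfg.scr_rise_tau, cfg.scr_decay_tau)
    for ev in schedule:
        amp = amp_of[ev.label]
        if amp == 0.0:
            continue
        jitter = rng.normal(0, 0.1)
        shape = scr_kernel(t - ev.onset - cfg.scr_latency_s - jitter,
                           cfg.scr_rise_tau, cfg.scr_decay_tau)
        sig += amp / peak * shape * rng.uniform(0.8, 1.2)
    sig += cfg.sc_noise_sigma * rng.standard_normal(n)
    return Recording(sig[None, :], fs, ["SC"], "SC")


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    subject_id: int
    seed: int
    eeg: Recording
    sc: Recording
    events: EventTable


def subject_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def make_dataset(n_subjects: int, spec: ProtocolSpec | None = None,
                 cfg: SynthConfig | None = None, seed: int = 0,
                 subject_jitter: float = 0.15) -> list[SubjectData]:
    """Per-subject recordings with jittered effect sizes and derived seeds."""
    spec = spec or ProtocolSpec()
    cfg = cfg or SynthConfig()
    out = []
    for sid, sseed in enumerate(subject_seeds(seed, n_subjects)):
        rng = np.random.default_rng(sseed)
        jit = lambda v, lo=0.0, hi=0.95: float(np.clip(
            v * (1.0 + subject_jitter * rng.standard_normal()), lo, hi))
        sub_cfg = replace(
            cfg,
            alpha_reduction=jit(cfg.alpha_reduction),
            beta_reduction=jit(cfg.beta_reduction),
            scr_amp_p=jit(cfg.scr_amp_p, 0.0, np.inf),
        )
        schedule = make_event_schedule(spec, seed=sseed)
        eeg = synth_eeg(schedule, sub_cfg, seed=sseed)
        sc = synth_sc(schedule, sub_cfg, seed=sseed + 1)
        out.append(SubjectData(sid, sseed, eeg, sc, schedule))
    return out


def write_manifest(path: str | Path, dataset: list[SubjectData],
                   seed: int) -> None:
    manifest = {
        "master_seed": seed,
        "subjects": [
            {"subject_id": s.subject_id, "seed": s.seed,
             "n_events": len(s.events),
             "eeg_samples": s.eeg.n_samples, "sc_samples": s.sc.n_samples}
            for s in dataset
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
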