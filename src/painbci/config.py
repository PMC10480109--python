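"""YAML configuration loading with package defaults.

The config file mirrors the module structure::

    preprocess:
      eeg_filter: {family: fir_hamming_sinc, low_hz: 3, high_hz: 40, order: 2000}
      sc_filter:  {family: cheby1, low_hz: 0.05, high_hz: 2, order: 3, ripple_db: 0.5}
      eeg_channels: [Cz, C3, C4, CPz, CP1, CP2]
      eeg_window: {length_s: 0.5, overlap_frac: 0.8, ptp_reject_threshold: 150}
      sc_window:  {length_s: 2.0, overlap_frac: 0.8, ptp_reject_threshold: 10}
      patient_window: {length_s: 1.0, overlap_frac: 0.0, ptp_reject_threshold: 150}
    features:  {nfft: 1024, sampen_m: 2, sampen_r_frac: 0.2, higuchi_kmax: 10}
    decode:    {C: 1.0, gamma: 0.01, k: 4}
    online:    {eeg_chunk_s: 0.5, sc_chunk_s: 2.0, trigger_threshold: 0.5, ...}
    synthetic: {alpha_reduction: 0.4, ...}

Any subset may be given; omitted keys keep package defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import FeatureConfig
from .online import EngineConfig
from .pipeline import PreprocessConfig
from .preprocess import FilterSpec, WindowSpec
from .synthetic import ProtocolSpec, SynthConfig


@dataclass
class Config:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    online: EngineConfig = field(default_factory=EngineConfig)
    synthetic: SynthConfig = field(default_factory=SynthConfig)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    svm: dict = field(default_factory=lambda: {"C": 1.0, "gamma": 0.01, "k": 4})


def _build(cls, section: dict):
    return cls(**section)


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config, falling back to defaults for missing sections."""
    cfg = Config()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}

    pp = raw.get("preprocess", {})
    if pp:
        kwargs = {}
        if "eeg_filter" in pp:
            kwargs["eeg_filter"] = _build(FilterSpec, pp["eeg_filter"])
        if "sc_filter" in pp:
            kwargs["sc_filter"] = _build(FilterSpec, pp["sc_filter"])
        if "eeg_channels" in pp:
            kwargs["eeg_channels"] = tuple(pp["eeg_channels"])
        for key in ("eeg_window", "sc_window", "patient_window"):
            if key in pp:
                kwargs[key] = _build(WindowSpec, pp[key])
        cfg.preprocess = PreprocessConfig(**kwargs)
    if "features" in raw:
        sec = dict(raw["features"])
        if "bands" in sec:
            sec["bands"] = {k: tuple(v) for k, v in sec["bands"].items()}
        cfg.features = _build(FeatureConfig, sec)
    if "online" in raw:
        cfg.online = _build(EngineConfig, raw["online"])
    if "synthetic" in raw:
        cfg.synthetic = _build(SynthConfig, raw["synthetic"])
    if "protocol" in raw:
        cfg.protocol = _build(ProtocolSpec, raw["protocol"])
    if "decode" in raw:
        cfg.svm.update(raw["decode"])
    return cfg
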