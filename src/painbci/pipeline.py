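"""End-to-end helpers tying preprocessing, features and decoding together.

These are the offline recipes used by the CLI, the test-suite and the
acceptance script: raw recording + event table -> filtered, windowed,
artifact-screened feature table -> trained decoder / cross-validated
report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import decode, features, preprocess
from .features import FeatureConfig, FeatureTable
from .preprocess import FilterSpec, WindowSpec
from .signal_io import DecoderArtifact, EventTable, Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    eeg_filter: FilterSpec = field(default_factory=FilterSpec.eeg_default)
    sc_filter: FilterSpec = field(default_factory=FilterSpec.sc_default)
    eeg_channels: tuple = tuple(preprocess.EEG_CHANNELS_DEFAULT)
    eeg_window: WindowSpec = WindowSpec(0.5, 0.8, preprocess.EEG_PTP_THRESHOLD)
    sc_window: WindowSpec = WindowSpec(2.0, 0.8, preprocess.SC_PTP_THRESHOLD)
    patient_window: WindowSpec = WindowSpec(1.0, 0.0,
                                            preprocess.EEG_PTP_THRESHOLD)


def eeg_feature_table(rec: Recording, events: EventTable,
                      pp: PreprocessConfig | None = None,
                      fc: FeatureConfig | None = None,
                      window: WindowSpec | None = None) -> FeatureTable:
    """Filter, select channels, window, reject artifacts, featurize."""
    pp = pp or PreprocessConfig()
    fc = fc or FeatureConfig()
    window = window or pp.eeg_window
    filtered = preprocess.bandpass(rec, pp.eeg_filter)
    wanted = [c for c in pp.eeg_channels if c in rec.channel_names]
    if wanted:
        filtered = preprocess.select_channels(filtered, wanted)
    ws = preprocess.extract_windows(filtered, events, window)
    kept, rejected = preprocess.reject_artifacts(ws, window.ptp_reject_threshold)
    if len(rejected):
        logger.info("rejected %d/%d EEG windows", len(rejected), len(ws))
    return features.build_feature_table(kept, fc)


def sc_feature_table(rec: Recording, events: EventTable,
                     pp: PreprocessConfig | None = None) -> FeatureTable:
    pp = pp or PreprocessConfig()
    filtered = preprocess.bandpass(rec, pp.sc_filter)
    ws = preprocess.extract_windows(filtered, events, pp.sc_window)
    kept, rejected = preprocess.reject_artifacts(ws,
                                                 pp.sc_window.ptp_reject_threshold)
    if len(rejected):
        logger.info("rejected %d/%d SC windows", len(rejected), len(ws))
    return features.build_feature_table(kept)


def train_decoder(table: FeatureTable, modality: str,
                  class_set=("P", "R"), seed: int = 0) -> DecoderArtifact:
    """Standardize on the full table and fit the probabilistic SVM."""
    sub = table.select_labels(class_set)
    cfg = decode.SvmConfig(seed=seed)
    return train_with_scaler(sub, cfg, modality)


def train_with_scaler(table: FeatureTable, cfg: decode.SvmConfig,
                      modality: str) -> DecoderArtifact:
    scaler = decode.fit_zscaler(table.X)
    df = table.df.copy()
    df[table.feature_names] = scaler.transform(table.X)
    std = FeatureTable(df, list(table.feature_names))
    return decode.train_svm(std, cfg, modality=modality, standardized=True,
                            scaler=scaler)


def evaluate_offline(table: FeatureTable, class_set=("P", "R"),
                     k: int = 4, seed: int = 0):
    plan = decode.CvPlan(k=k, seed=seed, class_set=tuple(class_set))
    return decode.cross_validate(table, plan, decode.SvmConfig(seed=seed))


def subject_tables(eeg: Recording, sc: Recording, events: EventTable,
                   pp: PreprocessConfig | None = None):
    return (eeg_feature_table(eeg, events, pp),
            sc_feature_table(sc, events, pp))


def pooled_subject_table(tables, subject_ids) -> FeatureTable:
    """Concatenate per-subject tables adding a ``subject`` column."""
    import pandas as pd

    frames = []
    names = None
    for sid, t in zip(subject_ids, tables):
        names = names or list(t.feature_names)
        df = t.df.copy()
        df["subject"] = sid
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    ft = FeatureTable(df.drop(columns=["subject"]), names)
    ft.df["subject"] = df["subject"].to_numpy()
    return ft
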