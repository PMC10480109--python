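"""Per-window feature sets for EEG and skin conductance.

EEG windows yield, per channel: theta/alpha/beta/gamma/total band power,
peak frequency, sample entropy, spectral entropy, Higuchi fractal
dimension and RMS (concatenated across channels as
``<feature>__<channel>`` columns).  SC windows yield eleven amplitude
descriptors of the band-passed signal: mean, max, median, SD, VAR, IQR,
RMS, range, slope, MAD and AUC.

Spectral estimates use a single Hamming-tapered periodogram zero-padded
to 1024 points.  Scalar entry points (:func:`sample_entropy`,
:func:`higuchi_fd`, ...) share their arithmetic with the vectorized batch
table builders, which are what the decoding pipeline calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import WindowSet

logger = logging.getLogger(__name__)

DEFAULT_BANDS = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 40.0),
    "total": (3.0, 40.0),
}

EEG_FEATURES = [
    "theta_power", "alpha_power", "beta_power", "gamma_power", "total_power",
    "peak_frequency", "sample_entropy", "spectral_entropy", "higuchi_fd",
    "rms",
]

SC_FEATURES = [
    "mean", "max", "median", "sd", "var", "iqr", "rms", "range", "slope",
    "mad", "auc",
]

META_COLUMNS = ["window_id", "group", "label"]


@dataclass(frozen=True)
class FeatureConfig:
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    nfft: int = 1024
    sampen_m: int = 2
    sampen_r_frac: float = 0.2   # times the window SD
    higuchi_kmax: int = 10
    psd_taper: str = "hamming"   # "hamming" | "rect"
    spectral_range: tuple = (3.0, 40.0)

    def validate(self, fs: float) -> None:
        for name, (lo, hi) in self.bands.items():
            if not (0 < lo < hi < fs / 2 + 1e-9):
                raise ValueError(f"band {name!r} edges outside (0, fs/2)")
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if self.higuchi_kmax < 2:
            raise ValueError("higuchi_kmax must be >= 2")


@dataclass(frozen=True)
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray
    nfft: int


@dataclass
class FeatureTable:
    """Labeled, group-tagged feature rows with a fixed column order."""

    df: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        for col in META_COLUMNS:
            if col not in self.df.columns:
                raise ValueError(f"feature table missing column {col!r}")
        missing = [f for f in self.feature_names if f not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing features: {missing[:5]}")
        self.df = self.df[META_COLUMNS + self.feature_names].reset_index(drop=True)
        feats = self.df[self.feature_names]
        if len(self.df) and not np.isfinite(feats.to_numpy(dtype=float)).all():
            raise ValueError("feature table contains non-finite values")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.df["group"].to_numpy()

    def select_labels(self, labels) -> "FeatureTable":
        keep = self.df["label"].isin(list(labels))
        return FeatureTable(self.df[keep].copy(), list(self.feature_names))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        feats = [c for c in df.columns if c not in META_COLUMNS]
        return cls(df, feats)


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

def _taper(name: str, n: int) -> np.ndarray:
    if name == "hamming":
        return np.hamming(n)
    if name == "rect":
        return np.ones(n)
    raise ValueError(f"unknown taper {name!r}")


def _psd_batch(x: np.ndarray, fs: float, cfg: FeatureConfig):
    """One-sided tapered periodogram along the last axis, zero-padded."""
    n = x.shape[-1]
    freqs, power = sps.periodogram(
        x, fs=fs, window=_taper(cfg.psd_taper, n), nfft=max(cfg.nfft, n),
        detrend=False, axis=-1,
    )
    return freqs, power


def compute_psd(window_channel: np.ndarray, fs: float,
                cfg: FeatureConfig | None = None) -> Spectrum:
    """Single-segment PSD of one channel's window.

    Scaling is Parseval-consistent: ``sum(power) * df`` approximates the
    signal's mean square for the taper's normalization.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(window_channel, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples for a PSD")
    freqs, power = _psd_batch(x, fs, cfg)
    return Spectrum(freqs, power, max(cfg.nfft, x.size))


def _band_slice(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"no PSD bins in [{lo}, {hi}) Hz")
    return mask


def band_power(spec: Spectrum, lo: float, hi: float) -> float:
    """Rectangle-rule integral of the PSD over ``lo <= f < hi``."""
    mask = _band_slice(spec.freqs, lo, hi)
    df = spec.freqs[1] - spec.freqs[0]
    return float(spec.power[mask].sum() * df)


def peak_frequency(spec: Spectrum, lo: float = 3.0, hi: float = 40.0) -> float:
    """Frequency of the maximum PSD bin in ``[lo, hi)``; ties go low."""
    mask = _band_slice(spec.freqs, lo, hi)
    sub = spec.power[mask]
    if sub.max() <= 0:
        logger.warning("degenerate flat spectrum; peak frequency set to "
                       "lowest bin in range")
    return float(spec.freqs[mask][int(np.argmax(sub))])


def spectral_entropy(spec: Spectrum, lo: float = 3.0, hi: float = 40.0) -> float:
    """Shannon entropy of the PSD over ``[lo, hi)``, normalized to [0, 1]."""
    mask = _band_slice(spec.freqs, lo, hi)
    p = spec.power[mask].astype(float)
    total = p.sum()
    if total <= 0:
        logger.warning("zero spectrum; spectral entropy set to 0")
        return 0.0
    p = p / total
    nz = p[p > 0]
    h = -(nz * np.log(nz)).sum()
    return float(h / np.log(p.size))


# ---------------------------------------------------------------------------
# Entropy / complexity features
# ---------------------------------------------------------------------------

def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy ``-ln(A/B)`` with Chebyshev tolerance ``r``.

    ``B`` counts template pairs of length ``m`` within distance ``r``
    (self-matches excluded), ``A`` the same for length ``m + 1``.  ``r``
    defaults to ``0.2 * SD(x)``.  Degenerate cases: ``A == 0`` is capped
    at ``ln(B)``; ``B == 0`` at ``ln`` of the number of possible pairs.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    if r is None:
        r = 0.2 * x.std()

    # Chebyshev template distances via shifted slices of the scalar
    # |x_i - x_j| matrix: D_m[i,j] = max_{k<m} |x_{i+k} - x_{j+k}|.
    # Both template sets are truncated to the same n - m rows
    # (Richman & Moorman convention).
    diff = np.abs(x[:, None] - x[None, :])
    nt = n - m
    dm = diff[:nt, :nt].copy()
    for k in range(1, m):
        np.maximum(dm, diff[k:k + nt, k:k + nt], out=dm)
    dm1 = np.maximum(dm, diff[m:m + nt, m:m + nt])

    # symmetric matrices: halve the off-diagonal count (diagonal is 0 <= r)
    b = int(((dm <= r).sum() - nt) // 2)
    a = int(((dm1 <= r).sum() - nt) // 2)
    n_pairs = (n - m) * (n - m - 1) // 2
    if b == 0:
        return float(np.log(n_pairs)) if n_pairs > 1 else 0.0
    if a == 0:
        return float(np.log(b)) if b > 1 else float(np.log(2))
    return float(-np.log(a / b))


def _higuchi_fd_batch(X: np.ndarray, kmax: int) -> np.ndarray:
    """Higuchi fractal dimension for each row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[-1]
    lks = np.zeros((kmax, X.shape[0]))
    for k in range(1, kmax + 1):
        lm = np.zeros(X.shape[0])
        cnt = 0
        for m in range(k):
            idx = np.arange(m, n, k)
            nmax = idx.size - 1
            if nmax < 1:
                continue
            dist = np.abs(np.diff(X[:, idx], axis=-1)).sum(axis=-1)
            lm += dist * (n - 1) / (nmax * k) / k
            cnt += 1
        lks[k - 1] = lm / max(cnt, 1)
    ks = np.arange(1, kmax + 1, dtype=float)
    out = np.empty(X.shape[0])
    lnk = np.log(1.0 / ks)
    for i in range(X.shape[0]):
        lk = lks[:, i]
        if np.all(lk <= 0):
            out[i] = 1.0        # flat signal: smooth-curve limit
            continue
        good = lk > 0
        slope = np.polyfit(lnk[good], np.log(lk[good]), 1)[0]
        out[i] = slope
    return out


def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension of a single series (1 smooth, 2 noisy)."""
    return float(_higuchi_fd_batch(np.asarray(x, float).ravel()[None, :], kmax)[0])


def signal_rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    return float(np.sqrt(np.mean(x ** 2)))


# ---------------------------------------------------------------------------
# Feature vectors / tables
# ---------------------------------------------------------------------------

def eeg_feature_names(channel_names) -> list[str]:
    return [f"{feat}__{ch}" for feat in EEG_FEATURES for ch in channel_names]


def _eeg_feature_matrix(stack: np.ndarray, fs: float,
                        cfg: FeatureConfig) -> np.ndarray:
    """(n_windows, n_channels * 10) matrix; vectorized where possible."""
    nwin, nch, ns = stack.shape
    if not np.isfinite(stack).all():
        raise ValueError("NaN or inf in window data")
    freqs, power = _psd_batch(stack, fs, cfg)      # (nwin, nch, nbins)
    dfreq = freqs[1] - freqs[0]

    cols: dict[str, np.ndarray] = {}
    for band in ("theta", "alpha", "beta", "gamma", "total"):
        lo, hi = cfg.bands[band]
        mask = _band_slice(freqs, lo, hi)
        cols[f"{band}_power"] = power[..., mask].sum(axis=-1) * dfreq

    lo, hi = cfg.spectral_range
    mask = _band_slice(freqs, lo, hi)
    sub = power[..., mask]
    cols["peak_frequency"] = freqs[mask][np.argmax(sub, axis=-1)]

    tot = sub.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, sub / np.where(tot > 0, tot, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cols["spectral_entropy"] = -plogp.sum(axis=-1) / np.log(sub.shape[-1])

    flat = stack.reshape(nwin * nch, ns)
    se = np.array([sample_entropy(row, cfg.sampen_m) for row in flat])
    cols["sample_entropy"] = se.reshape(nwin, nch)
    cols["higuchi_fd"] = _higuchi_fd_batch(flat, cfg.higuchi_kmax).reshape(nwin, nch)
    cols["rms"] = np.sqrt(np.mean(stack ** 2, axis=-1))

    return np.concatenate([cols[f] for f in EEG_FEATURES], axis=1)


def eeg_feature_vector(window: np.ndarray, fs: float,
                       channel_names=None,
                       cfg: FeatureConfig | None = None) -> pd.Series:
    """Feature row for one EEG window (channels x samples)."""
    cfg = cfg or FeatureConfig()
    window = np.atleast_2d(np.asarray(window, dtype=float))
    names = list(channel_names) if channel_names is not None else [
        f"ch{i}" for i in range(window.shape[0])
    ]
    vals = _eeg_feature_matrix(window[None, ...], fs, cfg)[0]
    return pd.Series(vals, index=eeg_feature_names(names))


def _sc_feature_matrix(stack: np.ndarray, fs: float) -> np.ndarray:
    """(n_windows, 11) matrix of SC descriptors."""
    x = stack[:, 0, :]                        # SC is single-channel
    if not np.isfinite(x).all():
        raise ValueError("NaN or inf in window data")
    ns = x.shape[-1]
    t = np.arange(ns) / fs
    mean = x.mean(axis=-1)
    mx = x.max(axis=-1)
    med = np.median(x, axis=-1)
    sd = x.std(axis=-1, ddof=1) if ns > 1 else np.zeros(x.shape[0])
    var = sd ** 2
    q75, q25 = np.percentile(x, [75, 25], axis=-1)
    iqr = q75 - q25
    rms = np.sqrt(np.mean(x ** 2, axis=-1))
    rng = mx - x.min(axis=-1)
    tc = t - t.mean()
    denom = (tc ** 2).sum()
    slope = (x @ tc) / denom if denom > 0 else np.zeros(x.shape[0])
    mad = np.median(np.abs(x - med[:, None]), axis=-1)
    auc = np.trapezoid(x, t, axis=-1)
    return np.column_stack([mean, mx, med, sd, var, iqr, rms, rng, slope,
                            mad, auc])


def sc_feature_vector(window: np.ndarray, fs: float) -> pd.Series:
    """Eleven amplitude descriptors of one (filtered) SC window."""
    window = np.atleast_2d(np.asarray(window, dtype=float))
    vals = _sc_feature_matrix(window[None, ...], fs)[0]
    return pd.Series(vals, index=list(SC_FEATURES))


def build_feature_table(ws: WindowSet,
                        cfg: FeatureConfig | None = None) -> FeatureTable:
    """Compute the modality-appropriate feature row for every window."""
    cfg = cfg or FeatureConfig()
    if len(ws) == 0:
        names = (eeg_feature_names(ws.channel_names) if ws.modality == "EEG"
                 else list(SC_FEATURES))
        df = pd.DataFrame(columns=META_COLUMNS + names)
        return FeatureTable(df, names)
    stack = ws.stacked().astype(float)
    if ws.modality == "EEG":
        cfg.validate(ws.fs)
        names = eeg_feature_names(ws.channel_names)
        mat = _eeg_feature_matrix(stack, ws.fs, cfg)
    else:
        names = list(SC_FEATURES)
        mat = _sc_feature_matrix(stack, ws.fs)
    df = pd.DataFrame(mat, columns=names)
    df.insert(0, "label", ws.labels())
    df.insert(0, "group", ws.groups())
    df.insert(0, "window_id", [w.window_id for w in ws])
    return FeatureTable(df, names)
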