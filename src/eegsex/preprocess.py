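"""Raw recording -> network-ready epochs.

Fixed order of operations: channel selection, polyphase resampling to
128 Hz, causal first-order Butterworth band-pass 0.5-25 Hz, then
partitioning into contiguous non-overlapping 2-s epochs.  The default
configuration turns a 26-channel 500-Hz recording into 40 epochs of
256 time samples x 24 channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, DataError
from .montage import DEFAULT_KEEP
from .simulate import Recording

__all__ = [
    "EpochSet", "PreprocessConfig", "select_channels", "resample",
    "bandpass", "epoch", "preprocess_recording",
    "save_epochsets", "load_epochsets",
]


@dataclass
class EpochSet:
    """A subject's stack of fixed-length preprocessed epochs.

    ``epochs`` has shape (n_epochs, time_samples, n_channels); the
    network maps the channel axis to its height and time to its width.
    """

    subject_id: str
    sex: int
    epochs: np.ndarray
    fs: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise DataError("epochs must be (n_epochs, time, channels)")
        if self.epochs.shape[0] < 1:
            raise DataError("need at least one epoch")
        if self.epochs.shape[2] != len(self.channel_names):
            raise DataError("channel axis does not match channel_names")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass(frozen=True)
class PreprocessConfig:
    keep: tuple[str, ...] = DEFAULT_KEEP
    target_fs: float = 128.0
    band: tuple[float, float] = (0.5, 25.0)
    zero_phase: bool = False
    epoch_seconds: float = 2.0
    n_epochs: int = 40
    scale: float | None = 100.0   # fixed divisor in microvolt
    standardize: bool = False     # per-epoch, per-channel z-scoring instead


def select_channels(rec: Recording, keep) -> Recording:
    """Restrict to the requested channels, in the requested order."""
    idx = [rec.montage.index(lab) for lab in keep]  # MontageError if absent
    return Recording(subject_id=rec.subject_id, sex=rec.sex, fs=rec.fs,
                     signal=rec.signal[idx].copy(),
                     montage=rec.montage.subset(keep), seed=rec.seed)


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase rational resampling with FIR anti-aliasing."""
    if target_fs >= rec.fs:
        raise ConfigurationError(
            f"target_fs={target_fs} must be below the current rate {rec.fs}")
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.signal, ratio.numerator, ratio.denominator,
                            axis=1)
    return Recording(subject_id=rec.subject_id, sex=rec.sex, fs=target_fs,
                     signal=out, montage=rec.montage, seed=rec.seed)


def bandpass(rec: Recording, low: float, high: float,
             zero_phase: bool = False) -> Recording:
    """First-order Butterworth band-pass, causal by default.

    The causal (minimum-phase) application preserves waveform causality
    at the cost of phase distortion; ``zero_phase=True`` applies the
    filter forward and backward instead.
    """
    if not (0.0 < low < high < rec.fs / 2.0):
        raise ConfigurationError(
            f"band ({low}, {high}) must satisfy 0 < low < high < fs/2")
    sos = sps.butter(1, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    if zero_phase:
        out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    else:
        out = sps.sosfilt(sos, rec.signal, axis=1)
    return Recording(subject_id=rec.subject_id, sex=rec.sex, fs=rec.fs,
                     signal=np.asarray(out), montage=rec.montage, seed=rec.seed)


def epoch(rec: Recording, epoch_seconds: float, n_epochs: int) -> EpochSet:
    """Partition into ``n_epochs`` contiguous segments starting at t=0."""
    ts = int(round(epoch_seconds * rec.fs))
    needed = ts * n_epochs
    if rec.n_samples < needed:
        raise DataError(
            f"recording too short: need {needed / rec.fs:.1f} s "
            f"({needed} samples), have {rec.duration_s:.1f} s "
            f"({rec.n_samples} samples)")
    sig = rec.signal[:, :needed]                      # channels x samples
    eps = sig.reshape(rec.montage.n_channels, n_epochs, ts)
    eps = np.ascontiguousarray(eps.transpose(1, 2, 0))  # epoch x time x channel
    return EpochSet(subject_id=rec.subject_id, sex=rec.sex, epochs=eps,
                    fs=rec.fs, channel_names=rec.montage.channel_names)


def preprocess_recording(rec: Recording,
                         cfg: PreprocessConfig | None = None) -> EpochSet:
    """Full pipeline: select -> resample -> band-pass -> epoch -> scale."""
    cfg = cfg if cfg is not None else PreprocessConfig()
    out = select_channels(rec, cfg.keep)
    out = resample(out, cfg.target_fs)
    out = bandpass(out, cfg.band[0], cfg.band[1], zero_phase=cfg.zero_phase)
    es = epoch(out, cfg.epoch_seconds, cfg.n_epochs)
    eps = es.epochs.astype(np.float32)
    if cfg.standardize:
        mu = eps.mean(axis=1, keepdims=True)
        sd = eps.std(axis=1, keepdims=True)
        eps = (eps - mu) / np.maximum(sd, 1e-12)
    elif cfg.scale is not None:
        eps = eps / np.float32(cfg.scale)
    es.epochs = eps
    return es


def save_epochsets(epochsets, directory) -> pd.DataFrame:
    """Serialize epoch stacks as little-endian float32 ``.npy`` files plus
    a CSV index; returns the index frame."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for es in epochsets:
        p = directory / f"{es.subject_id}_epochs.npy"
        np.save(p, es.epochs.astype("<f4"))
        rows.append({"subject_id": es.subject_id, "sex": es.sex,
                     "path": str(p), "n_epochs": es.n_epochs, "fs": es.fs,
                     "channels": "|".join(es.channel_names)})
    index = pd.DataFrame(rows)
    index.to_csv(directory / "index.csv", index=False)
    return index


def load_epochsets(directory) -> list[EpochSet]:
    index = pd.read_csv(Path(directory) / "index.csv")
    out = []
    for row in index.itertuples():
        out.append(EpochSet(subject_id=row.subject_id, sex=int(row.sex),
                            epochs=np.load(row.path), fs=float(row.fs),
                            channel_names=tuple(row.channels.split("|"))))
    return out
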