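"""Activation maximization ("deep dream") on the trained network.

For a chosen (conv layer, filter) pair, gradient ascent from seeded
uniform noise produces a surrogate input epoch that maximally activates
that filter; the surrogate's row-averaged amplitude spectrum and
per-channel power shares then characterize what the filter responds to.
In a trained network the deep layers' top-ranked surrogates concentrate
their spectral peak in the band the classifier exploits and their power
on the informative channel subset, while early-layer surrogates remain
noise-like.

The ascent objective is the mean post-activation response of the
filter's feature map; the gradient is RMS-normalized before each step,
and a step that would decrease the objective is rejected with the step
size halved for that surrogate, so the recorded loss trajectory is
non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Network

__all__ = [
    "DreamArtifact", "maximize_filter_activation", "dream_all_filters",
    "row_averaged_spectrum", "spatial_profile", "dream_summary",
]


@dataclass
class DreamArtifact:
    """Surrogate input for one (layer, filter) pair."""

    layer_index: int
    filter_index: int
    surrogate: np.ndarray          # time x channels, input units
    loss: float                    # final mean activation
    freqs: np.ndarray              # Hz, 0..fs/2
    spectrum: np.ndarray           # row-averaged amplitude spectrum
    peak_hz: float                 # spectral argmax within the analysis band
    spatial_profile: np.ndarray    # per-channel power shares, sums to 1
    degenerate: bool = False       # dead filter: zero loss and gradient


def row_averaged_spectrum(matrix: np.ndarray, fs: float = 128.0):
    """Amplitude spectrum of each channel's time series, averaged over
    channels ("rows" in the EEG sense).  Returns (freqs, amplitude)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty matrix")
    n = matrix.shape[0]
    amp = np.abs(np.fft.rfft(matrix, axis=0)) / n
    return np.fft.rfftfreq(n, d=1.0 / fs), amp.mean(axis=1)


def spatial_profile(matrix: np.ndarray) -> np.ndarray:
    """Per-channel share of signal power (mean squared amplitude,
    normalized to sum to 1).  An all-zero matrix yields the uniform
    profile (degenerate case)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("empty matrix")
    power = (matrix ** 2).mean(axis=0)
    total = power.sum()
    if total <= 0.0:
        return np.full(matrix.shape[1], 1.0 / matrix.shape[1])
    return power / total


def _spectral_peak(freqs: np.ndarray, amp: np.ndarray,
                   band: tuple[float, float]) -> float:
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(freqs[sel][np.argmax(amp[sel])])


def _ascend(net: Network, conv_index: int, filter_indices: np.ndarray,
            steps: int, step_size: float, seed: int,
            tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Batched normalized gradient ascent; one surrogate per filter index.

    Returns (surrogates in net layout, final losses)."""
    n_ch, n_t = net.input_shape
    m = len(filter_indices)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD4EA]))
    x = rng.uniform(-0.05, 0.05, size=(m, n_ch, n_t, 1)).astype(np.float32)
    step = np.full(m, step_size, dtype=np.float32)
    prev_x = x.copy()
    prev_loss = np.full(m, -np.inf)
    rows = np.arange(m)
    for it in range(steps):
        maps = net.forward_to_conv(conv_index, x, keep_cache=True)
        hw = maps.shape[2] * maps.shape[3]
        loss = maps[rows, filter_indices].reshape(m, -1).mean(axis=1)
        if not np.all(np.isfinite(loss)):
            raise FloatingPointError(
                f"activation ascent diverged at iteration {it}")
        dmaps = np.zeros_like(maps)
        dmaps[rows, filter_indices] = 1.0 / hw
        g = net.backward_from_conv(conv_index, dmaps)

        rejected = loss < prev_loss - tol
        accepted = ~rejected
        prev_loss[accepted] = loss[accepted]
        prev_x[accepted] = x[accepted]
        x[rejected] = prev_x[rejected]
        step[rejected] *= 0.5

        rms = np.sqrt((g.reshape(m, -1) ** 2).mean(axis=1))
        live = accepted & (rms > 1e-12)
        ghat = np.zeros_like(g)
        ghat[live] = g[live] / rms[live, None, None, None]
        x[live] = x[live] + step[live, None, None, None] * ghat[live]
    # final loss at the last accepted point
    maps = net.forward_to_conv(conv_index, prev_x)
    final = maps[rows, filter_indices].reshape(m, -1).mean(axis=1)
    return prev_x, np.maximum(final, prev_loss)


def _artifact(net: Network, conv_index: int, filter_index: int,
              x: np.ndarray, loss: float, fs: float,
              band: tuple[float, float]) -> DreamArtifact:
    surrogate = np.asarray(x[0, ..., 0], dtype=float).T  # -> time x channels
    freqs, amp = row_averaged_spectrum(surrogate, fs=fs)
    return DreamArtifact(
        layer_index=conv_index, filter_index=int(filter_index),
        surrogate=surrogate, loss=float(loss), freqs=freqs, spectrum=amp,
        peak_hz=_spectral_peak(freqs, amp, band),
        spatial_profile=spatial_profile(surrogate),
        degenerate=bool(loss <= 0.0))


def maximize_filter_activation(net: Network, layer_index: int,
                               filter_index: int, steps: int = 200,
                               step_size: float = 0.1, seed: int = 0,
                               fs: float = 128.0,
                               band: tuple[float, float] = (0.5, 25.0)
                               ) -> DreamArtifact:
    """Surrogate input maximizing one filter's mean activation."""
    xs, losses = _ascend(net, layer_index, np.array([filter_index]),
                         steps, step_size, seed)
    return _artifact(net, layer_index, filter_index, xs[0:1], losses[0],
                     fs, band)


def dream_all_filters(net: Network, layer_index: int, steps: int = 200,
                      step_size: float = 0.1, seed: int = 0,
                      fs: float = 128.0,
                      band: tuple[float, float] = (0.5, 25.0),
                      chunk: int = 32) -> list[DreamArtifact]:
    """One artifact per filter of the layer, sorted by descending loss."""
    pos = net._conv_pos(layer_index)
    n_filters = net.layers[pos].c_out
    artifacts = []
    for start in range(0, n_filters, chunk):
        fi = np.arange(start, min(start + chunk, n_filters))
        xs, losses = _ascend(net, layer_index, fi, steps, step_size, seed)
        for k, f in enumerate(fi):
            artifacts.append(_artifact(net, layer_index, int(f),
                                       xs[k:k + 1], losses[k], fs, band))
    artifacts.sort(key=lambda a: a.loss, reverse=True)
    return artifacts


def dream_summary(artifacts: list[DreamArtifact], top_channels: int = 5,
                  channel_names=None) -> pd.DataFrame:
    """CSV-ready summary: layer, filter, loss, peak frequency, strongest
    channels."""
    rows = []
    for a in artifacts:
        order = np.argsort(a.spatial_profile)[::-1][:top_channels]
        if channel_names is not None:
            top = "|".join(channel_names[i] for i in order)
        else:
            top = "|".join(str(i) for i in order)
        rows.append({"layer": a.layer_index, "filter": a.filter_index,
                     "loss": a.loss, "peak_hz": a.peak_hz,
                     "degenerate": a.degenerate, "top_channels": top})
    return pd.DataFrame(rows)
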