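"""Welch spectra, band powers, group z-score topography, and the
beta-power logistic-regression baseline.

This is the classical counterpart of the network: power spectral
densities by Welch's method (10-s Hann segments, half overlap), band
powers for the canonical EEG bands, standardized female-minus-male group
differences per channel and band, and a logistic regression on the
per-channel log beta power (12-25 Hz) as a sex classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CloughTocher2DInterpolator, NearestNDInterpolator

from .errors import ConfigurationError, DataError
from .montage import MontageSpec
from .simulate import Recording

__all__ = [
    "BANDS", "SpectralTable", "welch_psd", "band_power",
    "spectral_table", "group_zscores", "beta_logistic_baseline",
    "topographic_grid", "TopoMap",
]

#: Canonical band edges in Hz (beta per the figure convention, 12-25 Hz).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 25.0),
}


def welch_psd(rec: Recording, segment_seconds: float = 10.0,
              overlap: float = 0.5):
    """Per-channel Welch PSD (Hann window).  Returns (freqs, psd) with
    psd shaped (n_channels, n_freqs) in uV^2/Hz and frequency resolution
    1/segment_seconds."""
    nperseg = int(round(segment_seconds * rec.fs))
    if rec.n_samples < nperseg:
        raise DataError(
            f"recording ({rec.duration_s:.1f} s) shorter than one "
            f"{segment_seconds:.0f}-s Welch segment")
    freqs, psd = sps.welch(np.asarray(rec.signal, dtype=np.float64),
                           fs=rec.fs, window="hann",
                           nperseg=nperseg,
                           noverlap=int(round(nperseg * overlap)),
                           detrend="constant", axis=1)
    return freqs, psd


def band_power(psd: np.ndarray, freqs: np.ndarray,
               band: tuple[float, float]) -> np.ndarray:
    """Integral of the PSD over [low, high) per channel (rectangle rule,
    so disjoint bands add exactly)."""
    low, high = band
    if low > high:
        raise ConfigurationError(f"band ({low}, {high}) is inverted")
    if low < freqs[0] - 1e-9 or high > freqs[-1] + 1e-9:
        raise ConfigurationError(
            f"band ({low}, {high}) outside the PSD range "
            f"[{freqs[0]}, {freqs[-1]}]")
    df = freqs[1] - freqs[0]
    sel = (freqs >= low) & (freqs < high)
    return np.asarray(psd)[..., sel].sum(axis=-1) * df


@dataclass
class SpectralTable:
    """Per-subject, per-channel spectra and derived band powers."""

    subject_ids: list[str]
    labels: np.ndarray                 # 1 = male, 0 = female
    channel_names: tuple[str, ...]
    freqs: np.ndarray
    psd: np.ndarray                    # (n_subjects, n_channels, n_freqs)
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))

    def band_powers(self, band_name: str) -> np.ndarray:
        """(n_subjects, n_channels) band power in uV^2."""
        return band_power(self.psd, self.freqs, self.bands[band_name])

    def log_amplitude(self) -> np.ndarray:
        """log10 amplitude spectra, the display convention for EEG spectra
        (monotone in the PSD per frequency bin)."""
        return np.log10(np.sqrt(np.maximum(self.psd, 1e-300)))

    def to_frame(self) -> pd.DataFrame:
        """Long-format band-power table (subject, sex, channel, band, power)."""
        rows = []
        for name in self.bands:
            bp = self.band_powers(name)
            for i, sid in enumerate(self.subject_ids):
                for j, ch in enumerate(self.channel_names):
                    rows.append({"subject_id": sid, "sex": int(self.labels[i]),
                                 "channel": ch, "band": name,
                                 "power": bp[i, j]})
        return pd.DataFrame(rows)


def spectral_table(recordings, segment_seconds: float = 10.0,
                   overlap: float = 0.5,
                   max_freq: float = 35.0) -> SpectralTable:
    """Welch spectra for every recording, cropped to [0.5, max_freq] Hz.

    Accepts any iterable of recordings (consumed lazily, one at a time).
    """
    ids, labels, psds = [], [], []
    freqs = channels = None
    for rec in recordings:
        f, p = welch_psd(rec, segment_seconds, overlap)
        sel = (f >= 0.5) & (f <= max_freq)
        if freqs is None:
            freqs, channels = f[sel], rec.montage.channel_names
        ids.append(rec.subject_id)
        labels.append(rec.sex)
        psds.append(p[:, sel])
    if not ids:
        raise DataError("no recordings supplied")
    return SpectralTable(subject_ids=ids, labels=np.asarray(labels),
                         channel_names=channels, freqs=freqs,
                         psd=np.stack(psds))


def group_zscores(table: SpectralTable, labels=None) -> pd.DataFrame:
    """Standardized female-minus-male difference of log band power per
    channel and band (difference of group means over the pooled SD)."""
    y = np.asarray(labels if labels is not None else table.labels)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise DataError("each group needs at least 2 subjects")
    rows = []
    for name in table.bands:
        x = np.log10(np.maximum(table.band_powers(name), 1e-300))
        f, m = x[y == 0], x[y == 1]
        nf, nm = len(f), len(m)
        pooled = np.sqrt(((nf - 1) * f.var(axis=0, ddof=1)
                          + (nm - 1) * m.var(axis=0, ddof=1)) / (nf + nm - 2))
        z = (f.mean(axis=0) - m.mean(axis=0)) / np.maximum(pooled, 1e-300)
        for j, ch in enumerate(table.channel_names):
            rows.append({"band": name, "channel": ch, "z": z[j]})
    return pd.DataFrame(rows)


def beta_logistic_baseline(train_table: SpectralTable, train_labels,
                           test_table: SpectralTable, test_labels,
                           band: str = "beta", ridge: float | None = None
                           ) -> float:
    """Accuracy (percent) of a logistic regression on per-channel log
    beta power, fit on the training cohort and scored on the test cohort.

    ``ridge`` switches on L2 regularization with the given strength C;
    the default is an unpenalized fit.
    """
    from sklearn.linear_model import LogisticRegression

    if train_table.channel_names != test_table.channel_names:
        raise DataError("train and test tables use different channel sets")
    Xtr = np.log10(np.maximum(train_table.band_powers(band), 1e-300))
    Xte = np.log10(np.maximum(test_table.band_powers(band), 1e-300))
    var = Xtr.var(axis=0)
    if np.any(var <= 0):
        dead = [train_table.channel_names[i] for i in np.where(var <= 0)[0]]
        raise DataError(f"zero-variance feature for channel(s) {dead}")
    ytr = np.asarray(train_labels)
    yte = np.asarray(test_labels)
    if ridge is None:
        clf = LogisticRegression(C=np.inf, max_iter=2000)  # unpenalized
    else:
        clf = LogisticRegression(C=ridge, max_iter=2000)
    clf.fit(Xtr, ytr)
    return 100.0 * float((clf.predict(Xte) == yte).mean())


@dataclass
class TopoMap:
    """Interpolated scalp map on a regular unit-square grid (NaN outside
    the head disc) plus the underlying interpolant."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ndarray
    interpolant: object

    def at(self, x, y) -> np.ndarray:
        return np.asarray(self.interpolant(np.column_stack(
            [np.atleast_1d(x), np.atleast_1d(y)])))


def topographic_grid(values, montage: MontageSpec,
                     resolution: int = 64) -> TopoMap:
    """Interpolate per-channel values over the unit disc for topographic
    rendering; electrode positions reproduce their input values exactly."""
    values = np.asarray(values, dtype=float)
    if values.shape != (montage.n_channels,):
        raise DataError(
            f"need one value per montage channel "
            f"({montage.n_channels}), got shape {values.shape}")
    pts = montage.positions
    if np.ptp(values) == 0:
        # constant field: interpolation is the constant itself
        def interp(q):
            q = np.atleast_2d(q)
            return np.full(q.shape[0], values[0])
    else:
        ct = CloughTocher2DInterpolator(pts, values)
        nn = NearestNDInterpolator(pts, values)

        def interp(q):
            q = np.atleast_2d(q)
            out = ct(q)
            bad = ~np.isfinite(out)
            if np.any(bad):
                out[bad] = nn(q[bad])
            return out

    ax = np.linspace(-1.0, 1.0, resolution)
    gx, gy = np.meshgrid(ax, ax)
    flat = interp(np.column_stack([gx.ravel(), gy.ravel()]))
    grid = flat.reshape(gx.shape)
    grid[gx ** 2 + gy ** 2 > 1.0] = np.nan
    return TopoMap(grid_x=gx, grid_y=gy, values=grid, interpolant=interp)
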