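"""Synthetic resting-state EEG cohorts with a planted sex difference.

Each subject's eyes-closed recording is synthesized as the sum of three
independent components per channel:

* a 1/f-like background (amplitude spectrum proportional to ``f**(-gamma/2)``),
* a band-limited alpha oscillation (default 8-12 Hz), stronger posteriorly,
* a band-limited fast-beta oscillation (default 20-25 Hz).

The planted group difference mirrors the structure reported for real
cohorts: female recordings receive a broadband amplitude gain (small) and
an additional beta-specific gain concentrated on a fronto-central /
centro-parietal channel subset.  Per-subject lognormal amplitude factors
(one per component, shared across channels) model inter-individual
variability; a smaller per-channel jitter models within-subject spatial
variability.  Everything is a pure function of ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .montage import MontageSpec, default_montage

__all__ = [
    "EffectSpec",
    "CohortSpec",
    "Recording",
    "default_spatial_profile",
    "generate_recording",
    "generate_cohort",
]


def default_spatial_profile(n_channels: int = 26) -> np.ndarray:
    """Planted-effect channel weights: 1 on montage indices 4-20 (Fz..Pz,
    the fronto-central/centro-parietal strip), 0.3 elsewhere."""
    w = np.full(n_channels, 0.3)
    w[4:21] = 1.0
    return w


@dataclass(frozen=True)
class EffectSpec:
    """Parameters of the planted female-vs-male spectral difference.

    ``beta_female_gain`` multiplies the female beta-component amplitude by
    ``1 + (gain - 1) * spatial_profile[ch]`` per channel, so a gain of 1
    plants no effect anywhere regardless of the profile.
    ``broadband_female_gain`` scales all female components uniformly.
    """

    beta_band: tuple[float, float] = (20.0, 25.0)
    beta_female_gain: float = 1.4
    broadband_female_gain: float = 1.05
    spatial_profile: np.ndarray = field(default_factory=default_spatial_profile)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    noise_exponent: float = 1.0
    subject_amp_cv: float = 0.3
    # realism knobs (not part of the planted contrast)
    channel_amp_cv: float = 0.05
    background_rms: float = 10.0   # microvolt
    alpha_rms: float = 6.0         # microvolt, before posterior weighting
    beta_rms: float = 3.0          # microvolt

    def validate(self, fs: float) -> None:
        for name, (lo, hi) in (("beta_band", self.beta_band),
                               ("alpha_band", self.alpha_band)):
            if not (0.0 < lo < hi < fs / 2.0):
                raise ConfigurationError(
                    f"{name}=({lo}, {hi}) must satisfy 0 < low < high < fs/2 "
                    f"(fs={fs})")
        if self.beta_female_gain < 1.0 or self.broadband_female_gain < 1.0:
            raise ConfigurationError("female gains must be >= 1")
        prof = np.asarray(self.spatial_profile, dtype=float)
        if prof.min() < 0.0 or prof.max() > 1.0:
            raise ConfigurationError("spatial_profile weights must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """A labeled cohort: size, sex ratio, recording length and effect."""

    n_subjects: int
    male_fraction: float = 0.47
    duration_s: float = 120.0
    effect: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0
    fs: float = 500.0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must lie in [0, 1]")
        self.effect.validate(self.fs)


@dataclass
class Recording:
    """One subject's multi-channel EEG.

    ``signal`` is channels x samples in microvolt; ``sex`` is 1 for male,
    0 for female.
    """

    subject_id: str
    sex: int
    fs: float
    signal: np.ndarray
    montage: MontageSpec
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[0] != self.montage.n_channels:
            raise ConfigurationError(
                f"signal has {self.signal.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _butter_bandpass_gain(freqs: np.ndarray, band: tuple[float, float],
                          order: int = 2) -> np.ndarray:
    """Magnitude response of an analog Butterworth band-pass (used as a
    spectral shaping mask for band-limited noise)."""
    lo, hi = band
    w = 2.0 * np.pi * freqs
    w0sq = (2.0 * np.pi * lo) * (2.0 * np.pi * hi)
    bw = 2.0 * np.pi * (hi - lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (w * w - w0sq) / (bw * w)
    x = np.where(freqs > 0, x, np.inf)
    return 1.0 / np.sqrt(1.0 + x ** (2 * order))


def _unit_rms_mask(amp: np.ndarray, n: int) -> np.ndarray:
    """Rescale an amplitude-spectrum mask so that random-phase noise
    shaped by it has unit expected time-domain RMS (Parseval)."""
    a2 = amp.astype(float) ** 2
    mid = a2[1:-1].sum() if n % 2 == 0 else a2[1:].sum()
    edge = a2[-1] if n % 2 == 0 else 0.0
    expected_ms = (2.0 * mid + edge) / n**2
    return (amp / np.sqrt(expected_ms)).astype(np.float32)


def _random_phase_spectrum(rng: np.random.Generator, n_channels: int,
                           amp: np.ndarray) -> np.ndarray:
    """Deterministic-modulus, random-phase spectrum |X| = amp."""
    theta = rng.random((n_channels, amp.size), dtype=np.float32)
    theta *= np.float32(2.0 * np.pi)
    return (np.cos(theta) + 1j * np.sin(theta)) * amp


def _gaussian_spectrum(rng: np.random.Generator, n_channels: int,
                       nf: int, amp: np.ndarray) -> np.ndarray:
    """Complex-normal spectrum with E|X|^2 = amp^2 (filtered white noise).

    Coefficients are drawn only where the mask has appreciable support,
    which for band-limited masks is a small fraction of the spectrum.
    """
    out = np.zeros((n_channels, nf), dtype=np.complex64)
    idx = np.flatnonzero(amp > 1e-4 * amp.max())
    k = idx.size
    re = rng.standard_normal((n_channels, k), dtype=np.float32)
    im = rng.standard_normal((n_channels, k), dtype=np.float32)
    out[:, idx] = (re + 1j * im) * (np.float32(np.sqrt(0.5)) * amp[idx])
    return out


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal amplitude factors with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_recording(effect: EffectSpec, sex: int, seed: int, *,
                       duration_s: float = 120.0, fs: float = 500.0,
                       subject_id: str = "S0000",
                       montage: MontageSpec | None = None) -> Recording:
    """Synthesize one subject's recording; deterministic given ``seed``."""
    effect.validate(fs)
    montage = montage if montage is not None else default_montage()
    n_ch = montage.n_channels
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    # spectral shaping masks, rescaled to unit expected RMS
    gamma = effect.noise_exponent
    f_floor = np.maximum(freqs, 0.5)  # flatten below 0.5 Hz
    bg_amp = _unit_rms_mask(f_floor ** (-gamma / 2.0), n)
    alpha_amp = _unit_rms_mask(_butter_bandpass_gain(freqs, effect.alpha_band), n)
    beta_amp = _unit_rms_mask(_butter_bandpass_gain(freqs, effect.beta_band), n)

    # subject-level component amplitude factors, shared across channels
    subj = _lognormal_factors(rng, effect.subject_amp_cv, 3)
    # per-channel jitter, small
    jit = _lognormal_factors(rng, effect.channel_amp_cv, (3, n_ch))

    # posterior alpha weighting from schematic y-coordinate (eyes closed)
    y = montage.positions[:, 1]
    alpha_profile = 1.0 + 0.8 * np.clip(-y, 0.0, 1.0)

    prof = np.asarray(effect.spatial_profile, dtype=float)
    if prof.shape != (n_ch,):
        raise ConfigurationError(
            f"spatial_profile has shape {prof.shape}, expected ({n_ch},)")
    if sex == 0:
        beta_mult = 1.0 + (effect.beta_female_gain - 1.0) * prof
        broadband = effect.broadband_female_gain
    else:
        beta_mult = np.ones(n_ch)
        broadband = 1.0

    scale_bg = effect.background_rms * subj[0] * jit[0]
    scale_alpha = effect.alpha_rms * alpha_profile * subj[1] * jit[1]
    scale_beta = effect.beta_rms * beta_mult * subj[2] * jit[2]

    nf = n // 2 + 1
    x_f = _random_phase_spectrum(rng, n_ch, bg_amp)
    x_f *= scale_bg[:, None].astype(np.complex64)
    x_f += _gaussian_spectrum(rng, n_ch, nf, alpha_amp) * \
        scale_alpha[:, None].astype(np.float32)
    x_f += _gaussian_spectrum(rng, n_ch, nf, beta_amp) * \
        scale_beta[:, None].astype(np.float32)
    x_f[:, 0] = 0.0
    if n % 2 == 0:
        x_f[:, -1] = x_f[:, -1].real * np.float32(np.sqrt(2.0))
    signal = np.fft.irfft(x_f, n=n, axis=1).astype(np.float32)
    signal *= np.float32(broadband)
    return Recording(subject_id=subject_id, sex=int(sex), fs=fs,
                     signal=signal, montage=montage, seed=int(seed))


def cohort_labels(n_subjects: int, male_fraction: float,
                  seed: int) -> np.ndarray:
    """Deterministic label sequence with round(male_fraction * n) males."""
    n_male = int(round(male_fraction * n_subjects))
    labels = np.zeros(n_subjects, dtype=int)
    labels[:n_male] = 1
    np.random.default_rng(np.random.SeedSequence([seed, 0x5EC])).shuffle(labels)
    return labels


def iter_cohort(spec: CohortSpec):
    """Yield the cohort's recordings one by one (memory-friendly for
    large cohorts; a 2-min 26-channel recording is ~12 MB)."""
    spec.validate()
    labels = cohort_labels(spec.n_subjects, spec.male_fraction, spec.seed)
    seeds = subject_seeds(spec.seed, spec.n_subjects)
    montage = default_montage()
    for i, (sex, s) in enumerate(zip(labels, seeds)):
        yield generate_recording(
            spec.effect, int(sex), int(s),
            duration_s=spec.duration_s, fs=spec.fs,
            subject_id=f"S{i:04d}", montage=montage)


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate ``spec.n_subjects`` recordings with deterministic
    per-subject seeds derived from ``spec.seed``."""
    return list(iter_cohort(spec))


def subject_seeds(seed: int, n_subjects: int) -> np.ndarray:
    """Per-subject generator seeds derived from the cohort seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_subjects, dtype=np.uint32)


def no_effect(effect: EffectSpec | None = None) -> EffectSpec:
    """Copy of ``effect`` with both female gains set to 1 (null cohort)."""
    base = effect if effect is not None else EffectSpec()
    return replace(base, beta_female_gain=1.0, broadband_female_gain=1.0)
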