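"""Synthetic data generators.

Two testbeds make every stage of the pipeline verifiable without recordings:

* :func:`gen_eeg_trials` — EEG-like multichannel trials: 1/f colored noise on
  all channels, plus a band-limited oscillation on a small set of "active"
  channels whose amplitude depends on the trial's class.  This mimics
  ERD/ERS-style class-dependent band-power modulation (the physical signal
  band-power features capture) at the standard shape of a 59-channel,
  100 Hz, 4 s motor-imagery trial.  It is a statistical stand-in, not a
  physiological head model.

* :func:`gen_design` — raw grouped design matrices with a known sparse
  group-structured coefficient matrix, labels drawn from the multinomial
  logistic law at that coefficient matrix; the solver-recovery testbed.

All outputs are deterministic functions of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import TrialSet

__all__ = ["EEGSimSpec", "DesignSimSpec", "gen_eeg_trials", "gen_design"]


@dataclass(frozen=True)
class EEGSimSpec:
    """Simulated motor-imagery EEG conditions.

    Defaults emulate a standard two-class 59-channel recording resampled to
    100 Hz with 400 samples per trial; three central channels carry an
    8-12 Hz rhythm whose amplitude differs strongly between classes
    (amplitudes 2.0 vs 0.5 against unit 1/f noise), i.e. a high-SNR ERD/ERS
    contrast.
    """

    n_channels: int = 59
    n_samples: int = 400
    fs: float = 100.0
    n_trials_per_class: int = 100
    active_channels: tuple = (26, 27, 28)
    rhythm_band: tuple = (8.0, 12.0)
    amplitude_by_class: tuple = (2.0, 0.5)
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(a < 0 for a in self.amplitude_by_class):
            raise ValueError("amplitudes must be nonnegative")
        if any(not 0 <= ch < self.n_channels for ch in self.active_channels):
            raise ValueError("active_channels must be valid channel indices")
        if len(set(self.amplitude_by_class)) > 1 \
                and len(self.active_channels) == 0:
            raise ValueError("unequal class amplitudes require a nonempty "
                             "active channel set")
        if not 0 < self.rhythm_band[0] < self.rhythm_band[1] < self.fs / 2:
            raise ValueError("rhythm band must lie inside (0, fs/2)")


def _colored_noise(rng: np.random.Generator, shape: tuple[int, ...],
                   exponent: float, fs: float) -> np.ndarray:
    """Spectrally shaped (1/f^exponent) Gaussian noise, unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def gen_eeg_trials(spec: EEGSimSpec | None = None) -> TrialSet:
    """EEG-like trials with planted class-discriminative channels.

    Every channel carries independent colored noise; active channels add a
    sinusoid with per-trial random frequency (uniform in the rhythm band) and
    random phase, scaled by the trial class's amplitude — so band power, not
    phase, carries the class information.  Classes are labeled 1..M.
    """
    spec = spec or EEGSimSpec()
    rng = np.random.default_rng(spec.seed)
    m = len(spec.amplitude_by_class)
    n_total = m * spec.n_trials_per_class
    t = np.arange(spec.n_samples) / spec.fs
    trials = np.empty((n_total, spec.n_channels, spec.n_samples))
    labels = np.empty(n_total, dtype=int)
    i = 0
    for cls, amp in enumerate(spec.amplitude_by_class, start=1):
        for _ in range(spec.n_trials_per_class):
            x = spec.noise_scale * _colored_noise(
                rng, (spec.n_channels, spec.n_samples),
                spec.noise_exponent, spec.fs)
            for ch in spec.active_channels:
                f = rng.uniform(*spec.rhythm_band)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                x[ch] += amp * np.sin(2.0 * np.pi * f * t + phase)
            trials[i] = x
            labels[i] = cls
            i += 1
    names = [f"ch{k:02d}" for k in range(spec.n_channels)]
    return TrialSet(trials=trials, labels=labels, fs=spec.fs,
                    channel_names=names)


@dataclass(frozen=True)
class DesignSimSpec:
    """Grouped-design recovery testbed with a known sparse truth."""

    n: int = 400
    p_groups: int = 20
    d: int = 5
    M: int = 2
    active_groups: tuple = (0, 1, 2)
    within_group_density: float = 0.6
    magnitude: float = 1.5
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n, self.p_groups, self.d, self.M) < 1 or self.M < 2:
            raise ValueError("counts must be positive and M >= 2")
        if not 0 < self.within_group_density <= 1:
            raise ValueError("within_group_density must lie in (0, 1]")


def gen_design(spec: DesignSimSpec | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Standard-normal X, labels from the logistic law, and the true beta.

    Returns ``(X, y, beta_true, group_index)``.  Within each active group,
    ``round(density * d * (M-1))`` coefficient entries (at least one) are set
    to ``magnitude`` with random signs; labels are sampled from the
    multinomial logistic probabilities at that coefficient matrix (optionally
    with Gaussian logit noise of sd ``noise_level``).
    """
    spec = spec or DesignSimSpec()
    rng = np.random.default_rng(spec.seed)
    k = spec.M - 1
    p_feat = spec.p_groups * spec.d
    X = rng.standard_normal((spec.n, p_feat))
    beta = np.zeros((p_feat, k))
    n_entries = spec.d * k
    n_active = max(1, int(round(spec.within_group_density * n_entries)))
    for g in spec.active_groups:
        flat = rng.choice(n_entries, size=n_active, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_active)
        block = np.zeros(n_entries)
        block[flat] = spec.magnitude * signs
        beta[g * spec.d:(g + 1) * spec.d] = block.reshape(spec.d, k)
    logits = X @ beta
    if spec.noise_level > 0:
        logits = logits + spec.noise_level * rng.standard_normal(logits.shape)
    full = np.hstack([logits, np.zeros((spec.n, 1))])
    full -= full.max(axis=1, keepdims=True)
    probs = np.exp(full)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.uniform(size=spec.n)
    y = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1) + 1  # classes 1..M
    group_index = np.repeat(np.arange(spec.p_groups), spec.d)
    return X, y, beta, group_index
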