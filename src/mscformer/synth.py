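"""Synthetic motor-imagery-like EEG trials.

Real MI decoding rests on event-related desynchronization: imagining a
movement attenuates or enhances the mu/beta rhythm over class-specific
sensorimotor sites.  The generator emulates exactly that structure — each
trial is a band-limited oscillation with random phase plus 1/f-shaped
broadband noise, and each class modulates the oscillation amplitude on its
own designated channel subset — so every pipeline stage can run with no
recordings on disk.  It does not model volume conduction, artifacts, or
non-stationarity; see docs/methods.md for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TrialSet

__all__ = ["SynthSpec", "generate", "class_channel_subsets", "make_worked_fixture"]


@dataclass(frozen=True)
class SynthSpec:
    """Geometry and effect structure of a synthetic MI trial set.

    ``effect_size`` is the relative amplitude boost of the rhythm on a
    class's designated channels: those channels carry amplitude
    ``1 + effect_size`` while non-designated channels carry 1.
    ``noise_sigma`` is the S.D. of the additive 1/f-shaped noise.
    """

    n_trials_per_class: int = 30
    n_classes: int = 2
    channels: int = 6
    samples: int = 250
    fs: float = 250.0
    rhythm_band: tuple[float, float] = (8.0, 12.0)
    effect_size: float = 2.0
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rhythm_band
        if not (0 < lo < hi < self.fs / 2):
            raise ValueError(f"rhythm band {self.rhythm_band} must lie in (0, fs/2)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if self.channels < self.n_classes:
            raise ValueError(
                f"{self.channels} channels cannot host {self.n_classes} "
                "disjoint class-specific subsets"
            )


def class_channel_subsets(channels: int, n_classes: int) -> list[np.ndarray]:
    """Fixed class -> channel-subset map: class k gets the k-th block of
    ``channels // n_classes`` consecutive channels."""
    width = channels // n_classes
    return [np.arange(k * width, (k + 1) * width) for k in range(n_classes)]


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float) -> np.ndarray:
    """1/f-shaped noise by spectral shaping of white noise, unit S.D."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * shaping, n=shape[-1], axis=-1)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def generate(spec: SynthSpec) -> TrialSet:
    """Draw a balanced, label-shuffled synthetic trial set."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trials_per_class * spec.n_classes
    c, t = spec.channels, spec.samples
    subsets = class_channel_subsets(c, spec.n_classes)
    labels = np.repeat(np.arange(spec.n_classes), spec.n_trials_per_class)
    rng.shuffle(labels)

    time = np.arange(t) / spec.fs
    lo, hi = spec.rhythm_band
    signals = np.zeros((n, c, t))
    for i in range(n):
        freq = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi, size=c)
        osc = np.sin(2 * np.pi * freq * time[None, :] + phase[:, None])
        amp = np.ones(c)
        amp[subsets[labels[i]]] = 1.0 + spec.effect_size
        signals[i] = amp[:, None] * osc
        if spec.noise_sigma > 0:
            signals[i] += spec.noise_sigma * _pink_noise(rng, (c, t), spec.fs)

    class_names = ["left_hand", "right_hand", "feet", "tongue"][: spec.n_classes]
    return TrialSet(
        signals=signals,
        labels=labels,
        fs=spec.fs,
        channel_names=[f"SYN{j:02d}" for j in range(c)],
        class_names=class_names,
        subject_id="synthetic",
        session_tag=f"synthetic-seed{spec.seed}",
        provenance=["synthetic"] * n,
    )


def make_worked_fixture() -> TrialSet:
    """Tiny deterministic 8-trial, 2-channel, 16-sample integer-valued set.

    Signals are a fixed arithmetic pattern (no RNG) so unit tests can verify
    standardization arithmetic and S&R recombination by hand; identical on
    every platform.
    """
    n, c, t = 8, 2, 16
    trial = np.arange(n).reshape(n, 1, 1)
    chan = np.arange(c).reshape(1, c, 1)
    samp = np.arange(t).reshape(1, 1, t)
    # distinct integers per (trial, channel, sample); values 0..1000-ish
    signals = (trial * 100 + chan * 50 + samp).astype(np.float64)
    labels = np.array([0, 1] * 4, dtype=np.int64)
    return TrialSet(
        signals=signals,
        labels=labels,
        fs=250.0,
        channel_names=["SYN00", "SYN01"],
        class_names=["left_hand", "right_hand"],
        subject_id="fixture",
        session_tag="worked-fixture",
        provenance=["synthetic"] * n,
    )
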