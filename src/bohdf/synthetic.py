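"""Synthetic EEG generator with class-conditional spectral structure.

Every emotion class is given a set of oscillation bands; a trial of that
class is 1/f^alpha background noise plus amplitude-modulated sinusoids inside
the class's bands (random frequency, phase and burst envelope per channel),
optionally contaminated with 50 Hz line noise and sub-1 Hz drift to exercise
the band-pass filter.  Generation is a pure function of (spec, seeds): the
same spec and seed always reproduce the same dataset bit for bit.

This emulates the band-power signatures that distinguish emotional states in
real recordings; it does not attempt physiological realism (no volume
conduction, no real artifact morphology).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .io import EEGTrial

#: (low Hz, high Hz, relative power) per band.  Relative power is the ratio of
#: the un-modulated oscillation power to the total background-noise power.
Band = tuple[float, float, float]

_DEFAULT_BANDS: list[list[Band]] = [
    [(8.0, 13.0, 6.0)],    # class 0: alpha-dominant
    [(18.0, 25.0, 6.0)],   # class 1: beta-dominant
    [(32.0, 42.0, 6.0)],   # class 2: low-gamma-dominant
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic-EEG study conditions.

    Defaults are sized for fast, fully-exercised tests: 3 classes with
    well-separated in-passband bands, 8 channels, 200 Hz, 10 s trials.
    """

    n_classes: int = 3
    channels: int = 8
    fs: float = 200.0
    duration: float = 10.0
    class_bands: list[list[Band]] = field(
        default_factory=lambda: [list(b) for b in _DEFAULT_BANDS])
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    line_noise: bool = False
    drift: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_bands) != self.n_classes:
            raise ConfigurationError(
                f"class_bands has {len(self.class_bands)} entries for "
                f"{self.n_classes} classes")
        nyq = self.fs / 2.0
        for cls, bands in enumerate(self.class_bands):
            for low, high, power in bands:
                if not (0.0 < low < high < nyq):
                    raise ConfigurationError(
                        f"class {cls} band ({low}, {high}) Hz outside (0, {nyq}) "
                        f"(Nyquist for fs={self.fs})")
                if power < 0:
                    raise ConfigurationError("band power must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


# Named presets mirroring the benchmark recording geometries.
PRESETS: dict[str, dict] = {
    "default": {},
    "deap_like": {"channels": 32, "fs": 128.0, "duration": 63.0, "n_classes": 2,
                  "class_bands": [[(8.0, 13.0, 6.0)], [(18.0, 25.0, 6.0)]]},
}


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Gaussian noise shaped to a 1/f^exponent power spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    std = x.std()
    return x / std if std > 0 else x


def generate_trial(spec: SyntheticSpec, class_id: int, trial_seed: int) -> EEGTrial:
    """Generate one labeled trial of the given class.

    Each channel is independent background noise plus, per class band, one
    amplitude-modulated sinusoid with random frequency inside the band,
    random phase, and a slow raised-cosine burst envelope.  The sinusoid
    amplitude is ``sqrt(2 * relative_power)`` times the noise scale, so the
    un-modulated oscillation power is ``relative_power`` times the background
    power.
    """
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id {class_id} out of range for {spec.n_classes} classes")
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(trial_seed)
    amp_ref = spec.noise_scale if spec.noise_scale > 0 else 1.0
    samples = np.zeros((spec.channels, n))
    for ch in range(spec.channels):
        x = np.zeros(n)
        if spec.noise_scale > 0:
            x += spec.noise_scale * _pink_noise(rng, n, spec.fs, spec.noise_exponent)
        for low, high, power in spec.class_bands[class_id]:
            if power == 0:
                continue
            f0 = rng.uniform(low, high)
            phase = rng.uniform(0, 2 * np.pi)
            # Raised-cosine burst envelope, 0.1-0.5 Hz modulation: bursty
            # oscillations rather than a steady tone.
            f_env = rng.uniform(0.1, 0.5)
            env_phase = rng.uniform(0, 2 * np.pi)
            envelope = 0.5 * (1.0 + np.cos(2 * np.pi * f_env * t + env_phase))
            amp = np.sqrt(2.0 * power) * amp_ref * rng.uniform(0.8, 1.2)
            x += amp * envelope * np.sin(2 * np.pi * f0 * t + phase)
        if spec.line_noise:
            x += 2.0 * amp_ref * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        if spec.drift:
            x += 5.0 * amp_ref * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
        samples[ch] = x
    return EEGTrial(
        samples=samples,
        fs=spec.fs,
        channel_names=[f"CH{c + 1:02d}" for c in range(spec.channels)],
        label=class_id,
        subject_id="synthetic",
        trial_id=f"c{class_id}_s{trial_seed}",
        meta={"seed": int(trial_seed)},
    )


def generate_dataset(spec: SyntheticSpec, trials_per_class: int) -> list[EEGTrial]:
    """Generate a balanced labeled dataset.

    Trial seeds derive deterministically from ``spec.seed`` through a
    ``SeedSequence``, so trials are pairwise distinct and the whole dataset
    is a pure function of (spec, trials_per_class).
    """
    if trials_per_class < 1:
        raise ValueError("trials_per_class must be >= 1")
    n_total = spec.n_classes * trials_per_class
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_total)
    trials = []
    i = 0
    for class_id in range(spec.n_classes):
        for j in range(trials_per_class):
            trial = generate_trial(spec, class_id, int(seeds[i]))
            trial.trial_id = f"c{class_id}_t{j:03d}"
            trials.append(trial)
            i += 1
    return trials
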