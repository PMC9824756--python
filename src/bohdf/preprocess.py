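"""Band-pass filtering and channel selection.

The canonical preprocessing is an order-4 Butterworth band-pass over
4-45 Hz, applied forward-backward (zero-phase) so spectrogram timing is not
distorted.  Channel selection is pure configuration: a named channel list,
applied by label rather than position so it survives reordering.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ConfigurationError
from .io import EEGTrial


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass design: ``order`` poles per band edge, applied
    once (``zero_phase=False``) or forward-backward (default)."""

    low_cut: float = 4.0
    high_cut: float = 45.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0.0 < self.low_cut < self.high_cut < nyq):
            raise ConfigurationError(
                f"band ({self.low_cut}, {self.high_cut}) Hz invalid for fs={fs} Hz: "
                f"need 0 < low < high < Nyquist ({nyq} Hz)")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order-sections representation of the designed filter."""
        self.validate(fs)
        return signal.butter(self.order, [self.low_cut, self.high_cut],
                             btype="bandpass", fs=fs, output="sos")

    def magnitude_response(self, freqs: Sequence[float], fs: float) -> np.ndarray:
        """|H(f)| of the *applied* filter (squared when zero-phase) at the
        given frequencies in Hz — the analytic contract for attenuation and
        ripple checks."""
        _, h = signal.sosfreqz(self.sos(fs), worN=np.asarray(freqs, dtype=float), fs=fs)
        mag = np.abs(h)
        return mag ** 2 if self.zero_phase else mag


def bandpass_filter(trial: EEGTrial, spec: FilterSpec | None = None) -> EEGTrial:
    """Filter every channel independently; returns a new trial of the same
    shape with the applied design recorded in ``meta['filters']``."""
    spec = spec or FilterSpec()
    sos = spec.sos(trial.fs)
    if spec.zero_phase:
        # Reflect-padded forward-backward pass: no group delay, squared response.
        filtered = signal.sosfiltfilt(sos, trial.samples, axis=-1, padtype="even")
    else:
        filtered = signal.sosfilt(sos, trial.samples, axis=-1)
    meta = dict(trial.meta)
    meta.setdefault("filters", [])
    meta["filters"] = list(meta["filters"]) + [asdict(spec)]
    return EEGTrial(samples=filtered, fs=trial.fs, channel_names=list(trial.channel_names),
                    label=trial.label, subject_id=trial.subject_id,
                    trial_id=trial.trial_id, meta=meta)


def select_channels(trial: EEGTrial, names: Sequence[str]) -> EEGTrial:
    """Restrict a trial to the named channels, in the requested order."""
    index = {name: i for i, name in enumerate(trial.channel_names)}
    missing = [n for n in names if n not in index]
    if missing:
        raise KeyError(f"channels not present in trial: {missing}")
    rows = [index[n] for n in names]
    return EEGTrial(samples=trial.samples[rows], fs=trial.fs,
                    channel_names=list(names), label=trial.label,
                    subject_id=trial.subject_id, trial_id=trial.trial_id,
                    meta=dict(trial.meta))


def rank_channels_by_variance(trial: EEGTrial, n: int | None = None) -> list[str]:
    """Convenience helper: channel names sorted by decreasing signal variance.

    Not a canonical selection criterion — the canonical path is an explicit
    channel list in the pipeline configuration.
    """
    order = np.argsort(-trial.samples.var(axis=1), kind="stable")
    names = [trial.channel_names[i] for i in order]
    return names if n is None else names[:n]
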