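"""Short-time Fourier transform spectrograms and fixed-size image rendering.

A 1D filtered channel is segmented into overlapping windows of ``L`` samples
shifted by ``hop``; frame ``m`` covers samples ``[m*hop, m*hop + L)``.  The
complex frame matrix is

    S(m, k) = sum_i  E(i + m*hop) w(i) exp(-2 pi j i k / L),   i = 0..L-1

and the amplitude spectrogram is A(m, k) = |S(m, k)|^2 / L, which makes the
per-frame sum of A equal the energy of the windowed segment (Parseval).

For the feature extractors the amplitude matrix is optionally log-compressed,
min-max normalised, oriented frequency-up / time-right, and bilinearly
resized to a square image (default 224 x 224, the deep backend's input size).
By default only the filter passband rows (4-45 Hz) are rendered: after the
band-pass the out-of-band rows are near zero and would waste the image's
dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import get_window

_WINDOW_NAMES = {"hann": "hann", "hamming": "hamming",
                 "gaussian": None, "rectangular": "boxcar"}


@dataclass(frozen=True)
class STFTConfig:
    """STFT framing and rendering parameters.

    ``window_len=None`` means one second of samples; ``hop=None`` means 50%
    overlap.  ``band`` restricts rendered rows to a frequency interval
    (``None`` keeps all nonnegative frequencies).
    """

    window_len: Optional[int] = None
    hop: Optional[int] = None
    window_shape: str = "hamming"
    log_scale: bool = True
    image_size: int = 224
    band: Optional[tuple[float, float]] = (4.0, 45.0)

    def resolve(self, fs: float, n_samples: int) -> tuple[int, int]:
        L = self.window_len if self.window_len is not None else int(round(fs))
        hop = self.hop if self.hop is not None else max(1, L // 2)
        if not 1 <= hop <= L:
            raise ValueError(f"hop must satisfy 1 <= hop <= window_len, got {hop} vs {L}")
        if L > n_samples:
            raise ValueError(
                f"signal too short for STFT: {n_samples} samples, need at least "
                f"window_len = {L}")
        return L, hop

    def window(self, L: int) -> np.ndarray:
        if self.window_shape not in _WINDOW_NAMES:
            raise ValueError(f"unknown window shape {self.window_shape!r}; "
                             f"choose from {sorted(_WINDOW_NAMES)}")
        if self.window_shape == "gaussian":
            return get_window(("gaussian", L / 6.0), L)
        return get_window(_WINDOW_NAMES[self.window_shape], L)


@dataclass
class Spectrogram:
    """Complex frame matrix ``S`` (frames x L bins), amplitudes
    ``A = |S|^2 / L``, axis coordinates, and (after rendering) the fixed-size
    grayscale image in [0, 1]."""

    S: np.ndarray
    A: np.ndarray
    fs: float
    frame_times: np.ndarray
    bin_freqs: np.ndarray
    image: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)


def compute_stft(channel: np.ndarray, fs: float, cfg: STFTConfig | None = None) -> Spectrogram:
    """Compute the complex STFT and amplitude spectrogram of one channel.

    Frame count is ``floor((len - L) / hop) + 1``; each frame is the full-L
    DFT of the windowed segment.
    """
    cfg = cfg or STFTConfig()
    x = np.asarray(channel, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("channel must be 1D")
    L, hop = cfg.resolve(fs, x.size)
    w = cfg.window(L)
    frames = np.lib.stride_tricks.sliding_window_view(x, L)[::hop]
    S = np.fft.fft(frames * w, axis=1)
    A = (S.real ** 2 + S.imag ** 2) / L
    n_frames = frames.shape[0]
    return Spectrogram(
        S=S,
        A=A,
        fs=fs,
        frame_times=(np.arange(n_frames) * hop + L / 2.0) / fs,
        bin_freqs=np.fft.fftfreq(L, d=1.0 / fs),
        meta={"window_len": L, "hop": hop, "window_shape": cfg.window_shape},
    )


def _resize_bilinear(img: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize with pixel-area (half-pixel-center) coordinate mapping."""
    H, W = img.shape
    out_h, out_w = out_shape
    rows = (np.arange(out_h) + 0.5) * (H / out_h) - 0.5
    cols = (np.arange(out_w) + 0.5) * (W / out_w) - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(img, [rr, cc], order=1, mode="nearest")


def render_image(spec: Spectrogram, cfg: STFTConfig | None = None) -> np.ndarray:
    """Render the amplitude spectrogram as an ``image_size``-square grayscale
    image in [0, 1], frequency increasing upward and time rightward.

    Log compression (``10 log10(A + 1e-12)``) precedes per-image min-max
    normalisation; a constant amplitude matrix renders as uniform mid-gray.
    The image is stored on ``spec.image`` and returned.
    """
    cfg = cfg or STFTConfig()
    if spec.A.size == 0:
        raise ValueError("cannot render an empty spectrogram")
    freqs = spec.bin_freqs
    if cfg.band is not None:
        keep = (freqs >= cfg.band[0]) & (freqs <= cfg.band[1])
        if not keep.any():
            raise ValueError(f"no frequency bins inside band {cfg.band}")
    else:
        keep = freqs >= 0
    # rows = frequency ascending, then flipped so high frequency is at row 0
    order = np.argsort(freqs[keep], kind="stable")
    M = spec.A[:, keep].T[order][::-1]
    if cfg.log_scale:
        M = 10.0 * np.log10(M + 1e-12)
    lo, hi = M.min(), M.max()
    if hi > lo:
        M = (M - lo) / (hi - lo)
    else:
        M = np.full_like(M, 0.5)
    img = _resize_bilinear(M, (cfg.image_size, cfg.image_size))
    img = np.clip(img, 0.0, 1.0)
    spec.image = img
    return img


def to_rgb(gray: np.ndarray, colormap: Optional[str] = None) -> np.ndarray:
    """3-channel version of a grayscale image for the deep backend: the
    grayscale plane replicated, or a matplotlib colormap when named."""
    if colormap is None:
        return np.repeat(gray[:, :, None], 3, axis=2)
    import matplotlib

    cmap = matplotlib.colormaps[colormap]
    return np.ascontiguousarray(cmap(gray)[:, :, :3])


def save_png(gray: np.ndarray, path) -> None:
    """Write a grayscale image in [0, 1] as an 8-bit PNG."""
    from PIL import Image

    Image.fromarray(np.round(gray * 255.0).astype(np.uint8), mode="L").save(path)
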