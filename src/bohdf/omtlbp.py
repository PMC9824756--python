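"""OMTLBP_SMC: overlapped multi-oriented, multi-scale local binary patterns
with joint sign/magnitude/center encoding.

For every interior pixel of a grayscale image, eight oriented samples are
taken at each of three radii.  Radius 1 samples single (interpolated) values
at 45-degree spacing; radii 2 and 3 average 5 and 7 values at 22.5- and
15-degree spacing respectively, each fan starting at ``45 * (k - 2)`` degrees
so adjacent fans overlap ("overlapped multi-oriented pixel fusion").  The
three radii are then fused into three 8-point topological structures

    U1 = P1,   U2 = (P1 + P2) / 2,   U3 = (P2 + P3) / 2.

Each structure's local differences against the center pixel are split into
sign and magnitude (LDSMT); signs and magnitudes are encoded with the
rotation-invariant uniform scheme (riu2, P = 8: patterns with at most two
circular 0-1 transitions map to their set-bit count 0..8, all others to the
catch-all code 9), the magnitude bits thresholding at the structure's mean
magnitude over the whole image; a center bit thresholds the pixel at the
global image mean.  The per-structure joint (sign, magnitude, center)
10 x 10 x 2 histograms, accumulated over all interior pixels and concatenated
in structure order, form the 600-dimensional descriptor.

Angles are measured counter-clockwise from the +column axis (row offsets
point up, i.e. are negative for positive angles); non-integer sample
coordinates are bilinearly interpolated.  Radius-1 sampling uses the exact
unit circle by default; ``radius1_mode="grid"`` snaps the diagonals to the
integer 8-neighborhood instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

P = 8                      # sample points per structure
N_CODES = P + 2            # riu2 codes 0..8 plus catch-all 9
BINS_PER_STRUCTURE = N_CODES * N_CODES * 2
N_STRUCTURES = 3
DESCRIPTOR_LENGTH = N_STRUCTURES * BINS_PER_STRUCTURE   # 600
_BORDER = 3                # radius-3 neighborhood must stay in bounds


def _fan_offsets(radius: float, n_sub: int, sub_step_deg: float,
                 start_k_offset_deg: float) -> np.ndarray:
    """(8, n_sub, 2) array of (drow, dcol) offsets for the eight oriented
    fans at one radius; k-th fan starts at ``45*k + start_k_offset`` degrees."""
    out = np.empty((P, n_sub, 2))
    for k in range(P):
        for i in range(n_sub):
            theta = math.radians(45.0 * k + start_k_offset_deg + i * sub_step_deg)
            # CCW-positive angles: +row is down in image coordinates
            out[k, i, 0] = -radius * math.sin(theta)
            out[k, i, 1] = radius * math.cos(theta)
    return np.round(out, 12)


def _offset_table(radius1_mode: str = "circle") -> dict[int, np.ndarray]:
    """Sampling offsets per radius.  Fans at radii 2 and 3 start one octant
    early (k-2 in 1-based k) so neighbouring fans overlap."""
    offs1 = _fan_offsets(1.0, 1, 0.0, 0.0)
    if radius1_mode == "grid":
        # snap diagonals to the integer 8-neighborhood (radius sqrt(2))
        offs1 = np.sign(offs1) * np.ceil(np.abs(offs1) - 1e-9)
    elif radius1_mode != "circle":
        raise ValueError(f"unknown radius1_mode {radius1_mode!r}")
    return {
        1: offs1,
        2: _fan_offsets(2.0, 5, 22.5, -45.0),
        3: _fan_offsets(3.0, 7, 15.0, -45.0),
    }


_TABLES: dict[str, dict[int, np.ndarray]] = {}


def _offsets(radius1_mode: str = "circle") -> dict[int, np.ndarray]:
    if radius1_mode not in _TABLES:
        _TABLES[radius1_mode] = _offset_table(radius1_mode)
    return _TABLES[radius1_mode]


@dataclass
class OrientedSamples:
    """Fused oriented samples at the three radii around one pixel."""

    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray
    center: float


@dataclass
class FusedStructures:
    """The three 8-point multi-scale topological structures."""

    U1: np.ndarray
    U2: np.ndarray
    U3: np.ndarray
    center: float


def _bilinear(image: np.ndarray, r: float, c: float) -> float:
    H, W = image.shape
    r0, c0 = math.floor(r), math.floor(c)
    fr, fc = r - r0, c - c0
    val = 0.0
    for ri, wr in ((r0, 1.0 - fr), (r0 + 1, fr)):
        if wr == 0.0:
            continue
        for ci, wc in ((c0, 1.0 - fc), (c0 + 1, fc)):
            if wc == 0.0:
                continue
            val += wr * wc * image[ri, ci]
    return val


def sample_oriented(image: np.ndarray, row: int, col: int,
                    radius1_mode: str = "circle") -> OrientedSamples:
    """Oriented sampling around one pixel (radius-3 neighborhood in bounds)."""
    image = np.asarray(image, dtype=np.float64)
    H, W = image.shape
    if not (_BORDER <= row < H - _BORDER and _BORDER <= col < W - _BORDER):
        raise ValueError(
            f"pixel ({row}, {col}) too close to the border of a {H}x{W} image; "
            f"need at least {_BORDER} pixels of margin")
    table = _offsets(radius1_mode)
    fused = {}
    for radius, offs in table.items():
        vals = np.empty(P)
        for k in range(P):
            vals[k] = np.mean([_bilinear(image, row + dr, col + dc)
                               for dr, dc in offs[k]])
        fused[radius] = vals
    return OrientedSamples(P1=fused[1], P2=fused[2], P3=fused[3],
                           center=float(image[row, col]))


def fuse_scales(samples: OrientedSamples) -> FusedStructures:
    """Fuse adjacent radii into the three topological structures."""
    return FusedStructures(
        U1=samples.P1.copy(),
        U2=(samples.P1 + samples.P2) / 2.0,
        U3=(samples.P2 + samples.P3) / 2.0,
        center=samples.center,
    )


def ldsmt(U: np.ndarray, C: float) -> tuple[np.ndarray, np.ndarray]:
    """Local Difference Sign-Magnitude Transform: Q = U - C decomposed into
    signs (+1 where Q >= 0, else -1) and magnitudes |Q|; signs * magnitudes
    reconstructs Q exactly."""
    Q = np.asarray(U, dtype=np.float64) - C
    signs = np.where(Q >= 0, 1.0, -1.0)
    return signs, np.abs(Q)


def _transitions(bits: np.ndarray) -> int:
    """Circular 0-1 transition count of a bit sequence."""
    return int(np.sum(bits != np.roll(bits, 1)))


def encode_sign_riu2(signs: np.ndarray) -> int:
    """riu2 code of the sign component: set-bit count for uniform patterns
    (at most 2 circular transitions), 9 otherwise."""
    bits = (np.asarray(signs) + 1) // 2
    if _transitions(bits) <= 2:
        return int(bits.sum())
    return P + 1


def encode_magnitude_riu2(magnitudes: np.ndarray, rho_m: float) -> int:
    """riu2 code of the magnitude component, thresholded at ``rho_m`` (the
    structure's mean magnitude; eta(m, rho) = 1 iff m >= rho)."""
    bits = (np.asarray(magnitudes) >= rho_m).astype(np.int64)
    if _transitions(bits) <= 2:
        return int(bits.sum())
    return P + 1


def encode_center(C: float, rho_I: float) -> int:
    """Center bit: 1 iff the center value is at least the global image mean."""
    return int(C >= rho_I)


# ---------------------------------------------------------------------------
# vectorised whole-image descriptor


def _shift_map(image: np.ndarray, dr: float, dc: float) -> np.ndarray:
    """Bilinearly interpolated image values at a constant offset from every
    interior pixel (four weighted integer shifts)."""
    H, W = image.shape
    hi, wi = H - 2 * _BORDER, W - 2 * _BORDER
    r, c = _BORDER + dr, _BORDER + dc
    r0, c0 = math.floor(r), math.floor(c)
    fr, fc = r - r0, c - c0
    out = np.zeros((hi, wi))
    for ri, wr in ((r0, 1.0 - fr), (r0 + 1, fr)):
        if wr == 0.0:
            continue
        for ci, wc in ((c0, 1.0 - fc), (c0 + 1, fc)):
            if wc == 0.0:
                continue
            out += wr * wc * image[ri:ri + hi, ci:ci + wi]
    return out


def _riu2_codes(bits: np.ndarray) -> np.ndarray:
    """Vectorised riu2 over a (8, ...) bit array."""
    transitions = np.abs(bits - np.roll(bits, 1, axis=0)).sum(axis=0)
    return np.where(transitions <= 2, bits.sum(axis=0), P + 1)


def describe(image: np.ndarray, normalize: bool = True,
             radius1_mode: str = "circle") -> np.ndarray:
    """Compute the 600-dimensional OMTLBP_SMC descriptor of a grayscale image.

    Every interior pixel (stride 1, three-pixel border excluded) contributes
    one (sign, magnitude, center) code triple to each structure's joint
    10 x 10 x 2 histogram; histograms are flattened sign-slowest, then
    magnitude, then center bit, and concatenated in structure order 1, 2, 3.
    Unnormalised, the descriptor sums to three times the interior pixel
    count; normalised, to one.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be a 2D grayscale matrix")
    H, W = image.shape
    if H < 2 * _BORDER + 1 or W < 2 * _BORDER + 1:
        raise ValueError(f"image must be at least {2 * _BORDER + 1}x{2 * _BORDER + 1}, "
                         f"got {H}x{W}")
    table = _offsets(radius1_mode)
    fan_means = {}
    for radius, offs in table.items():
        maps = np.stack([
            np.mean([_shift_map(image, dr, dc) for dr, dc in offs[k]], axis=0)
            for k in range(P)
        ])
        fan_means[radius] = maps                     # (8, hi, wi)
    structures = (
        fan_means[1],
        (fan_means[1] + fan_means[2]) / 2.0,
        (fan_means[2] + fan_means[3]) / 2.0,
    )
    # Quantise everything entering a threshold comparison at 1e-12 so that
    # numerically-constant neighbourhoods (equal up to interpolation rounding)
    # encode as exact equality — the sign of a zero difference is defined as +.
    center = np.round(image[_BORDER:H - _BORDER, _BORDER:W - _BORDER], 12)
    rho_I = round(float(image.mean()), 12)
    c_bits = (center >= rho_I).astype(np.int64)
    hist = np.empty(DESCRIPTOR_LENGTH)
    for v, U in enumerate(structures):
        Q = np.round(U, 12) - center[None]
        s_bits = (Q >= 0).astype(np.int64)
        mags = np.abs(Q)
        rho_m = round(float(mags.mean()), 12)        # structure-wide mean magnitude
        m_bits = (mags >= rho_m).astype(np.int64)
        s_codes = _riu2_codes(s_bits)
        m_codes = _riu2_codes(m_bits)
        idx = (s_codes * N_CODES + m_codes) * 2 + c_bits
        hist[v * BINS_PER_STRUCTURE:(v + 1) * BINS_PER_STRUCTURE] = np.bincount(
            idx.ravel(), minlength=BINS_PER_STRUCTURE)
    if normalize:
        hist /= hist.sum()
    return hist


class OMTLBPTransformer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer mapping grayscale images to OMTLBP_SMC
    descriptors.

    Parameters
    ----------
    normalize : bool, default True
        L1-normalise each descriptor.
    radius1_mode : {"circle", "grid"}, default "circle"
        Exact unit-circle radius-1 sampling, or integer 8-neighborhood.
    """

    def __init__(self, normalize: bool = True, radius1_mode: str = "circle"):
        self.normalize = normalize
        self.radius1_mode = radius1_mode

    def fit(self, X, y=None):
        self.n_features_out_ = DESCRIPTOR_LENGTH
        return self

    def transform(self, X) -> np.ndarray:
        """X: iterable of 2D grayscale images (or a 3D stack); returns an
        (n_images, 600) descriptor matrix."""
        return np.stack([describe(img, normalize=self.normalize,
                                  radius1_mode=self.radius1_mode) for img in X])
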