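"""Independent brute-force oracles used by the test suite.

Everything here is written pixel-by-pixel / pattern-by-pattern with plain
loops, independently of the package's vectorised implementations, so tests
compare two separately-derived computations.  The sampling conventions are
re-stated from scratch: angles counter-clockwise from the +column axis
(row offsets negative upward), offsets rounded to 12 decimals, bilinear
interpolation at non-integer coordinates.
"""

from __future__ import annotations

import math

import numpy as np


def bilinear(img: np.ndarray, r: float, c: float) -> float:
    r0, c0 = math.floor(r), math.floor(c)
    fr, fc = r - r0, c - c0
    val = 0.0
    for ri, wr in ((r0, 1.0 - fr), (r0 + 1, fr)):
        if wr == 0.0:
            continue
        for ci, wc in ((c0, 1.0 - fc), (c0 + 1, fc)):
            if wc == 0.0:
                continue
            val += wr * wc * img[ri, ci]
    return val


def fan_angles() -> dict:
    """Radians of every sub-sample of fan k (0-based) at each radius:
    radius 1 samples one point at 45k degrees, radius 2 five points at 22.5
    degree spacing and radius 3 seven points at 15 degree spacing, both fans
    starting one octant early (45k - 45 degrees) so neighbours overlap."""
    table = {}
    for k in range(8):
        table[(1, k)] = [math.radians(45.0 * k)]
        table[(2, k)] = [math.radians(45.0 * k - 45.0 + 22.5 * i) for i in range(5)]
        table[(3, k)] = [math.radians(45.0 * k - 45.0 + 15.0 * i) for i in range(7)]
    return table


def riu2_code(bits) -> int:
    """Set-bit count if the circular 0-1 transition count is at most 2,
    else the catch-all code 9."""
    bits = list(bits)
    transitions = sum(bits[d] != bits[d - 1] for d in range(8))
    return int(sum(bits)) if transitions <= 2 else 9


def brute_force_descriptor(img: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Loop-everywhere OMTLBP_SMC reference: oriented fan means at radii
    1/2/3, scale fusion U1=P1, U2=(P1+P2)/2, U3=(P2+P3)/2, sign/magnitude/
    center riu2 coding, joint 10x10x2 histograms concatenated over the three
    structures."""
    img = np.asarray(img, dtype=np.float64)
    H, W = img.shape
    hi, wi = H - 6, W - 6
    angles = fan_angles()
    fans = {}
    for rad in (1, 2, 3):
        maps = np.empty((8, hi, wi))
        for k in range(8):
            for a in range(hi):
                for b in range(wi):
                    r, c = a + 3, b + 3
                    vals = np.array([
                        bilinear(img,
                                 r + round(-rad * math.sin(t), 12),
                                 c + round(rad * math.cos(t), 12))
                        for t in angles[(rad, k)]])
                    maps[k, a, b] = np.mean(vals)
        fans[rad] = maps
    structures = (fans[1], (fans[1] + fans[2]) / 2.0, (fans[2] + fans[3]) / 2.0)
    # comparisons quantised at 1e-12, same documented convention as the package
    center = np.round(img[3:H - 3, 3:W - 3], 12)
    rho_I = round(float(img.mean()), 12)
    hist = np.zeros(600)
    for v, U in enumerate(structures):
        Q = np.round(U, 12) - center[None]
        mags = np.abs(Q)
        rho_m = round(float(np.mean(mags)), 12)
        for a in range(hi):
            for b in range(wi):
                s = riu2_code([1 if Q[d, a, b] >= 0 else 0 for d in range(8)])
                m = riu2_code([1 if mags[d, a, b] >= rho_m else 0 for d in range(8)])
                cbit = 1 if center[a, b] >= rho_I else 0
                hist[v * 200 + (s * 10 + m) * 2 + cbit] += 1
    return hist / hist.sum() if normalize else hist


def band_power(x: np.ndarray, fs: float, low: float, high: float) -> float:
    """Band-integrated periodogram power of a 1D signal."""
    from scipy.signal import periodogram

    f, p = periodogram(x, fs=fs)
    return float(p[(f >= low) & (f <= high)].sum())


def nearest_centroid(x: np.ndarray, centroids: np.ndarray) -> int:
    """Exhaustive nearest-centroid scan, lowest index on ties."""
    best, best_d = 0, float("inf")
    for j, c in enumerate(centroids):
        d = float(((x - c) ** 2).sum())
        if d < best_d:
            best, best_d = j, d
    return best


def write_minimal_edf(path, n_channels: int = 8, fs: int = 64,
                      n_records: int = 2) -> None:
    """Write a minimal all-zero EDF file (1-second records, int16 zeros)."""
    def pad(text: str, n: int) -> bytes:
        return text.ljust(n)[:n].encode("ascii")

    ns = n_channels
    header = b"".join([
        pad("0", 8), pad("synthetic patient", 80), pad("synthetic recording", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(ns), 4),
    ])
    header += b"".join(pad(f"EEG{i + 1:02d}", 16) for i in range(ns))
    header += b"".join(pad("AgAgCl electrode", 80) for _ in range(ns))
    header += b"".join(pad("uV", 8) for _ in range(ns))
    header += b"".join(pad("-100", 8) for _ in range(ns))      # physical min
    header += b"".join(pad("100", 8) for _ in range(ns))       # physical max
    header += b"".join(pad("-32767", 8) for _ in range(ns))    # digital min
    header += b"".join(pad("32767", 8) for _ in range(ns))     # digital max
    header += b"".join(pad("", 80) for _ in range(ns))
    header += b"".join(pad(str(fs), 8) for _ in range(ns))
    header += b"".join(pad("", 32) for _ in range(ns))
    data = np.zeros(n_records * ns * fs, dtype="<i2").tobytes()
    with open(path, "wb") as fh:
        fh.write(header + data)
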