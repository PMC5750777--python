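"""Region-restricted texture descriptors: local extrema, GLCM homogeneity
and rotation-invariant LBP histogram-Fourier features.

All three operate on an intensity raster restricted to a boolean region
mask; pixel pairs or neighbourhoods that leave the region are excluded
rather than padded, so the descriptors depend only on in-region content.
"""

from __future__ import annotations

import numpy as np

#: 8-neighbour offsets in counter-clockwise order starting east. The order
#: matters for LBP: a 90° image rotation cyclically shifts neighbours by 2,
#: which the histogram-Fourier magnitudes are invariant to.
NEIGHBOUR_OFFSETS = [
    (0, 1), (-1, 1), (-1, 0), (-1, -1),
    (0, -1), (1, -1), (1, 0), (1, 1),
]

LBP_HF_LENGTH = 38


def _shifted(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """arr sampled at (r+dr, c+dc), out-of-image positions set to ``fill``."""
    out = np.full(arr.shape, fill, dtype=float)
    rows, cols = arr.shape
    rs, re = max(dr, 0), rows + min(dr, 0)
    cs, ce = max(dc, 0), cols + min(dc, 0)
    out[rs - dr : re - dr, cs - dc : ce - dc] = arr[rs:re, cs:ce]
    return out


def local_extrema_count(intensity: np.ndarray, region: np.ndarray, mode: str) -> int:
    """Count strict local maxima or minima of the 8-neighbourhood in a region.

    A pixel counts when it is strictly greater (``mode="max"``) or strictly
    less (``mode="min"``) than every *available* neighbour — neighbours
    outside the image or outside the region are ignored. Pixels with no
    available neighbour, and plateau pixels, do not count.
    """
    if mode not in ("max", "min"):
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    intensity = np.asarray(intensity, dtype=float)

    is_extreme = np.ones(intensity.shape, dtype=bool)
    has_neighbour = np.zeros(intensity.shape, dtype=bool)
    for dr, dc in NEIGHBOUR_OFFSETS:
        value = _shifted(intensity, dr, dc, np.nan)
        available = _shifted(region.astype(float), dr, dc, 0.0) > 0
        has_neighbour |= available
        if mode == "max":
            ok = intensity > value
        else:
            ok = intensity < value
        is_extreme &= np.where(available, ok, True)
    return int((is_extreme & has_neighbour & region).sum())


def quantize(intensity: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize 0–255 intensities into ``levels`` gray levels."""
    q = (np.clip(np.asarray(intensity, dtype=float), 0, 255) * levels / 256).astype(np.int64)
    return np.minimum(q, levels - 1)


def glcm_homogeneity(
    intensity: np.ndarray,
    region: np.ndarray,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
) -> float:
    """Homogeneity Σ_ij p(i,j) / (1 + |i−j|) of a region-restricted GLCM.

    The co-occurrence matrix counts quantized gray-level pairs at the given
    pixel displacement, symmetrized (both directions) and normalized to a
    probability table; pairs with either pixel outside the region are
    excluded. A constant region scores exactly 1.
    """
    p = glcm(intensity, region, levels=levels, offset=offset)
    i, j = np.indices(p.shape)
    return float((p / (1.0 + np.abs(i - j))).sum())


def glcm(
    intensity: np.ndarray,
    region: np.ndarray,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
) -> np.ndarray:
    """Symmetric, normalized region-restricted gray-level co-occurrence matrix."""
    region = np.asarray(region, dtype=bool)
    q = quantize(intensity, levels)
    dr, dc = offset
    partner = _shifted(q.astype(float), -dr, -dc, -1)
    partner_in = _shifted(region.astype(float), -dr, -dc, 0.0) > 0
    valid = region & partner_in
    if not valid.any():
        raise ValueError("region contains no co-occurring pixel pair for this offset")
    a = q[valid]
    b = partner[valid].astype(np.int64)
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# LBP histogram-Fourier features
# ---------------------------------------------------------------------------

def _uniform_pattern_table(p: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Map each 8-bit LBP code to its (ones-count n, rotation r) orbit slot.

    Uniform codes (≤ 2 circular 0/1 transitions) with n ones form one run of
    n consecutive set bits; r is the run's starting bit. Non-uniform codes
    map to n = −1.
    """
    n_of = np.full(2**p, -1, dtype=np.int64)
    r_of = np.zeros(2**p, dtype=np.int64)
    for code in range(2**p):
        bits = [(code >> b) & 1 for b in range(p)]
        transitions = sum(bits[b] != bits[(b + 1) % p] for b in range(p))
        if transitions <= 2:
            n = sum(bits)
            n_of[code] = n
            if 0 < n < p:
                # start of the run of ones
                r_of[code] = next(
                    b for b in range(p) if bits[b] == 1 and bits[(b - 1) % p] == 0
                )
    return n_of, r_of


_N_OF, _R_OF = _uniform_pattern_table(8)


def lbp_codes(intensity: np.ndarray, region: np.ndarray) -> np.ndarray:
    """8-neighbour LBP codes for region pixels with a full in-image 3×3 patch.

    Bit b is set when neighbour b (integer grid, counter-clockwise from
    east) is ≥ the centre pixel. Neighbours may fall outside the region;
    only the centre is required to be inside it.
    """
    region = np.asarray(region, dtype=bool)
    intensity = np.asarray(intensity, dtype=float)
    rows, cols = intensity.shape
    if rows < 3 or cols < 3:
        raise ValueError("image too small for an 8-neighbour LBP")
    interior = np.zeros_like(region)
    interior[1:-1, 1:-1] = region[1:-1, 1:-1]
    if not interior.any():
        raise ValueError("region has no pixel with a full 8-neighbourhood")
    code = np.zeros(intensity.shape, dtype=np.int64)
    for b, (dr, dc) in enumerate(NEIGHBOUR_OFFSETS):
        neighbour = _shifted(intensity, dr, dc, -np.inf)
        code |= (neighbour >= intensity).astype(np.int64) << b
    return code[interior]


def lbp_hf(intensity: np.ndarray, region: np.ndarray) -> np.ndarray:
    """38-entry rotation-invariant LBP histogram-Fourier texture vector.

    The uniform-LBP histogram (P=8, R=1) is normalized, then each of the 7
    rotation orbits (patterns with 1–7 set bits, 8 rotations each) is
    Fourier-transformed along its rotation index; the 5 unique DFT
    magnitudes per orbit (u = 0…4, real input) are concatenated with the
    all-zeros, all-ones and non-uniform histogram bins: 7·5 + 3 = 38.
    Image rotation by multiples of 45° only cyclically shifts each orbit,
    so the magnitudes are invariant to it.
    """
    codes = lbp_codes(intensity, region)
    total = codes.size

    orbit = np.zeros((7, 8), dtype=float)       # orbit[n-1, r]
    specials = np.zeros(3, dtype=float)          # all-zeros, all-ones, non-uniform
    ns = _N_OF[codes]
    rs = _R_OF[codes]
    specials[0] = (ns == 0).sum()
    specials[1] = (ns == 8).sum()
    specials[2] = (ns == -1).sum()
    inner = (ns >= 1) & (ns <= 7)
    np.add.at(orbit, (ns[inner] - 1, rs[inner]), 1.0)

    orbit /= total
    specials /= total

    spectra = np.abs(np.fft.rfft(orbit, axis=1))  # (7, 5)
    return np.concatenate([spectra.ravel(), specials])
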