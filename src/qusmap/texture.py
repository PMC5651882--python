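"""Gray-level co-occurrence texture features of parametric maps.

Each parametric image is min-max scaled and quantized to 16 gray levels;
symmetric GLCMs are accumulated at five inter-pixel distances (1-5 px) and
four directions (0°, 45°, 90°, 135°), and four Haralick features are read
off every GLCM and averaged:

    contrast    = sum |i-j|^2 p(i,j)
    correlation = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j)
    energy      = sum p(i,j)^2
    homogeneity = sum p(i,j) / (1 + |i-j|)

Missing pixels (NaN, or masked off the map's validity support) never
contribute: any pair touching a missing pixel is excluded from the counts.
Quantization is per-image over the map's own valid min-max range, so the
texture features are invariant to affine rescaling of the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuantizedMap",
    "GLCM",
    "TextureFeatures",
    "quantize",
    "glcm",
    "glcm_features",
    "map_features",
    "DEFAULT_DISTANCES",
    "DEFAULT_ANGLES",
]

DEFAULT_DISTANCES = (1, 2, 3, 4, 5)
DEFAULT_ANGLES = (0, 45, 90, 135)

#: displacement (d_row, d_col) per angle on the isotropic pixel grid;
#: 0° is the lateral neighbour, 90° the axial neighbour.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class QuantizedMap:
    levels: np.ndarray  # int, 1..n_levels on valid pixels
    valid: np.ndarray  # bool
    n_levels: int
    parameter: str = ""


@dataclass
class GLCM:
    p: np.ndarray  # (n_levels, n_levels) probabilities, symmetric
    distance: int
    angle: int
    pair_count: int

    @property
    def marginal_mean(self) -> float:
        i = np.arange(1, self.p.shape[0] + 1)
        return float(i @ self.p.sum(axis=1))

    @property
    def marginal_sd(self) -> float:
        i = np.arange(1, self.p.shape[0] + 1)
        mu = self.marginal_mean
        return float(np.sqrt(((i - mu) ** 2) @ self.p.sum(axis=1)))


@dataclass
class TextureFeatures:
    mean: float  # native map units
    contrast: float
    correlation: float  # NaN when degenerate in every GLCM
    energy: float
    homogeneity: float
    n_glcms_averaged: int
    n_correlation_defined: int


def quantize(map_: np.ndarray, n_levels: int = 16,
             valid: np.ndarray | None = None, parameter: str = "") -> QuantizedMap:
    """Linearly scale a map's valid min-max range onto levels 1..n_levels.

    level = 1 + floor((v - min) / (max - min) * n_levels), clamped so that
    v = max lands on n_levels.  A constant map degenerates to all level 1.
    """
    m = np.asarray(map_, dtype=float)
    v = np.isfinite(m)
    if valid is not None:
        v = v & np.asarray(valid, dtype=bool)
    if not v.any():
        raise ValueError("no valid pixels to quantize")
    lo, hi = m[v].min(), m[v].max()
    levels = np.zeros(m.shape, dtype=np.int16)
    if hi > lo:
        q = 1 + np.floor((m[v] - lo) / (hi - lo) * n_levels)
        levels[v] = np.minimum(q, n_levels).astype(np.int16)
    else:
        levels[v] = 1
    return QuantizedMap(levels, v, n_levels, parameter)


def glcm(qmap: QuantizedMap, distance: int, angle: int) -> GLCM:
    """Symmetric masked co-occurrence matrix for one (distance, angle).

    Pairs are counted over all pixel offsets ``distance * offset(angle)``
    where both members are valid, symmetrized by adding the transpose and
    normalized to probabilities.  A grid with no valid pair yields an empty
    (all-zero) GLCM flagged by pair_count = 0.
    """
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    dr, dc = (distance * o for o in _ANGLE_OFFSETS[angle])
    lv, valid = qmap.levels, qmap.valid
    nr, nc = lv.shape

    r0_lo, r0_hi = max(0, -dr), min(nr, nr - dr)
    c0_lo, c0_hi = max(0, -dc), min(nc, nc - dc)
    n = qmap.n_levels
    if r0_hi <= r0_lo or c0_hi <= c0_lo:
        return GLCM(np.zeros((n, n)), distance, angle, 0)

    a = lv[r0_lo:r0_hi, c0_lo:c0_hi]
    b = lv[r0_lo + dr:r0_hi + dr, c0_lo + dc:c0_hi + dc]
    ok = valid[r0_lo:r0_hi, c0_lo:c0_hi] & valid[r0_lo + dr:r0_hi + dr,
                                                 c0_lo + dc:c0_hi + dc]
    if not ok.any():
        return GLCM(np.zeros((n, n)), distance, angle, 0)
    i = a[ok].astype(np.int64) - 1
    j = b[ok].astype(np.int64) - 1
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n).astype(float)
    counts = counts + counts.T
    total = counts.sum()
    return GLCM(counts / total, distance, angle, int(total))


def glcm_features(g: GLCM) -> tuple[float, float, float, float]:
    """(contrast, correlation, energy, homogeneity) of one GLCM.

    Correlation is NaN when either marginal standard deviation vanishes
    (e.g. a single-level image); returning 1 instead would silently bias
    homogeneous maps in the 20-GLCM average.
    """
    if g.pair_count == 0:
        raise ValueError("empty GLCM has no features")
    n = g.p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(((ii - jj) ** 2 * g.p).sum())
    energy = float((g.p**2).sum())
    homogeneity = float((g.p / (1.0 + np.abs(ii - jj))).sum())
    mu = g.marginal_mean
    sd = g.marginal_sd
    if sd > 0:
        correlation = float(((ii - mu) * (jj - mu) * g.p).sum() / (sd * sd))
    else:
        correlation = np.nan
    return contrast, correlation, energy, homogeneity


def map_features(map_: np.ndarray, valid: np.ndarray | None = None,
                 n_levels: int = 16,
                 distances: tuple[int, ...] = DEFAULT_DISTANCES,
                 angles: tuple[int, ...] = DEFAULT_ANGLES,
                 parameter: str = "") -> TextureFeatures:
    """Mean-value parameter plus the four texture features of one map.

    The mean is the arithmetic mean of valid pixels in native units; the
    texture features are averaged over all (distance, angle) GLCMs, skipping
    empty ones (and, for correlation, degenerate ones) with counts recorded.
    """
    m = np.asarray(map_, dtype=float)
    q = quantize(m, n_levels, valid, parameter)
    mean = float(m[q.valid].mean())

    feats = []
    for d in distances:
        for ang in angles:
            g = glcm(q, d, ang)
            if g.pair_count == 0:
                continue
            feats.append(glcm_features(g))
    if not feats:
        return TextureFeatures(mean, np.nan, np.nan, np.nan, np.nan, 0, 0)
    arr = np.array(feats)
    corr = arr[:, 1]
    corr_ok = np.isfinite(corr)
    return TextureFeatures(
        mean=mean,
        contrast=float(arr[:, 0].mean()),
        correlation=float(corr[corr_ok].mean()) if corr_ok.any() else np.nan,
        energy=float(arr[:, 2].mean()),
        homogeneity=float(arr[:, 3].mean()),
        n_glcms_averaged=len(feats),
        n_correlation_defined=int(corr_ok.sum()),
    )
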