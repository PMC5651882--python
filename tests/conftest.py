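"""Shared fixtures: acquisition geometry, reference set, simulated frames.

The expensive simulated objects are session-scoped so the recovery and
acceptance tests share them instead of re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from qusmap.synthetic_rf import (AcquisitionSpec, PhantomSpec, simulate_frame,
                                 simulate_reference_set)


@pytest.fixture(scope="session")
def acq() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def refset(acq):
    return simulate_reference_set(acq, seed=99)


@pytest.fixture(scope="session")
def speckle_phantom() -> PhantomSpec:
    """Dense monodisperse-ish medium giving fully developed speckle."""
    return PhantomSpec(scatterer_radius_mean=12.5, radius_cv=0.1,
                       number_density=60.0, impedance_contrast=0.5,
                       attenuation_coeff=0.576)


@pytest.fixture(scope="session")
def speckle_frame(speckle_phantom, acq):
    return simulate_frame(speckle_phantom, acq, seed=123)


@pytest.fixture(scope="session")
def lesion_roi(acq) -> np.ndarray:
    """A generous rectangular ROI in the middle of the frame."""
    roi = np.zeros((acq.n_samples, acq.num_lines), dtype=bool)
    roi[600:1400, 150:350] = True
    return roi


def brute_force_glcm_features(values: np.ndarray, valid: np.ndarray,
                              n_levels: int, distance: int, angle: int):
    """Independent oracle: explicit pair enumeration over the pixel grid.

    Quantizes with the same min-max rule and walks every pixel pair at the
    displacement of (distance, angle), counting both orientations; features
    are computed by direct double summation over the co-occurrence matrix.
    Deliberately naive: no vectorized shifts, no shared code with qusmap.
    """
    offs = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}[angle]
    dr, dc = distance * offs[0], distance * offs[1]
    vals = values[valid]
    lo, hi = vals.min(), vals.max()
    nr, nc = values.shape
    lev = np.zeros((nr, nc), dtype=int)
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c]:
                continue
            if hi > lo:
                q = 1 + int(np.floor((values[r, c] - lo) / (hi - lo) * n_levels))
                lev[r, c] = min(q, n_levels)
            else:
                lev[r, c] = 1
    counts = np.zeros((n_levels, n_levels))
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and valid[r, c] and valid[r2, c2]:
                i, j = lev[r, c] - 1, lev[r2, c2] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    total = counts.sum()
    if total == 0:
        return None
    p = counts / total
    contrast = energy = homog = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            contrast += (i - j) ** 2 * p[i, j]
            energy += p[i, j] ** 2
            homog += p[i, j] / (1 + abs(i - j))
    pi = p.sum(axis=1)
    mu = sum((i + 1) * pi[i] for i in range(n_levels))
    sd = np.sqrt(sum((i + 1 - mu) ** 2 * pi[i] for i in range(n_levels)))
    if sd > 0:
        corr = sum((i + 1 - mu) * (j + 1 - mu) * p[i, j]
                   for i in range(n_levels) for j in range(n_levels)) / (sd * sd)
    else:
        corr = np.nan
    return contrast, corr, energy, homog
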