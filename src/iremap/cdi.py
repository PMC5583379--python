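"""Inversion of the current-density-imaging measurement chain.

Two steps: the accumulated MR phase is divided by ``gamma * tc`` to recover
the current-induced flux density Bz, and Bz is differentiated according to
Ampere's law to recover the in-plane current density,

    jx =  (1/mu0) dBz/dy,      jy = -(1/mu0) dBz/dx.

This is the standard single-component CDI approximation: only Bz is
measurable with the needles parallel to the scanner field, and the
out-of-plane derivative terms are neglected.  Derivatives are central
differences (one-sided at the edges).  An optional Gaussian pre-smoothing of
Bz is available to control noise amplification by the differentiation.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .constants import GAMMA_PROTON, MU_0
from .grid import ScalarMap, VectorMap

__all__ = ["phase_to_bz", "bz_to_current", "current_magnitude"]


def phase_to_bz(phase: ScalarMap, tc: float = 4e-4) -> ScalarMap:
    """Recover Bz (T) from the current-encoded phase: ``bz = phi / (gamma tc)``."""
    if tc <= 0:
        raise ValueError("encoding time tc must be positive")
    return ScalarMap(phase.data / (GAMMA_PROTON * tc), phase.grid, kind="bz")


def bz_to_current(bz: ScalarMap, smooth_sigma_px: float = 0.0) -> VectorMap:
    """Ampere-law inversion of a Bz map to in-plane current density (A/m^2)."""
    grid = bz.grid
    if grid.n_x < 3 or grid.n_y < 3:
        raise ValueError("grid too small for central differences (need >= 3x3)")
    data = bz.data
    if smooth_sigma_px > 0:
        data = gaussian_filter(data, sigma=smooth_sigma_px, mode="nearest")
    h = grid.pixel_m
    dbz_dy, dbz_dx = np.gradient(data, h)
    jx = dbz_dy / MU_0
    jy = -dbz_dx / MU_0
    return VectorMap(jx, jy, grid)


def current_magnitude(J: VectorMap) -> ScalarMap:
    """Pointwise Euclidean norm |J| (A/m^2) — the input to J-substitution."""
    if not (np.all(np.isfinite(J.x)) and np.all(np.isfinite(J.y))):
        raise ValueError("current density components must be finite")
    return ScalarMap(J.magnitude(), J.grid, kind="current_magnitude")
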