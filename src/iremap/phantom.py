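"""Synthetic conductivity phantoms with needle-electrode configurations.

The generator emulates the treated-tumor geometry of a small-animal IRE
session: a roughly 2 mm-radius tumor cross-section in a 30 mm field of view,
two needle electrodes (0.5 mm diameter) 1.2-3.3 mm apart driven at 700 V, and
optional smooth conductivity heterogeneity of up to ~20% coefficient of
variation.  Everything downstream (forward physics, CDI inversion, MREIT
reconstruction, damage prediction) is exercised against these phantoms, so the
generators are deterministic given a seed.

Electrodes are modeled as in-plane disks: the physical needles run
perpendicular to the imaging slice, so their cross-section in the slice is a
disk held at the applied potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import GridSpec, ScalarMap

__all__ = [
    "ElectrodeConfig",
    "PhantomCase",
    "make_phantom",
    "add_heterogeneity",
    "ground_truth_ablation",
    "electrode_masks",
    "electrode_exclusion_mask",
]


@dataclass(frozen=True)
class ElectrodeConfig:
    """Two in-plane disk electrodes at fixed potentials.

    Coordinates are in mm from the lower-left corner of the field of view.
    """

    center_a: tuple[float, float]
    center_b: tuple[float, float]
    diameter_mm: float = 0.5
    potential_a: float = 350.0
    potential_b: float = -350.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("electrode diameter must be positive")
        gap = self.gap_mm
        if gap < self.diameter_mm:
            raise ValueError(
                f"electrode gap {gap:.3g} mm smaller than electrode "
                f"diameter {self.diameter_mm:.3g} mm (electrodes overlap)"
            )

    @property
    def gap_mm(self) -> float:
        """Center-to-center electrode distance, mm."""
        dx = self.center_a[0] - self.center_b[0]
        dy = self.center_a[1] - self.center_b[1]
        return float(np.hypot(dx, dy))

    @property
    def voltage(self) -> float:
        """Applied potential difference |Va - Vb|, V."""
        return abs(self.potential_a - self.potential_b)


@dataclass
class PhantomCase:
    """A complete synthetic case: truth conductivity, electrodes, tumor mask."""

    grid: GridSpec
    sigma_true: ScalarMap
    electrodes: ElectrodeConfig
    tumor_mask: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.sigma_true.data.shape != self.grid.shape:
            raise ValueError("sigma_true shape does not match grid")
        if self.tumor_mask.shape != self.grid.shape:
            raise ValueError("tumor_mask shape does not match grid")
        if not np.all(self.sigma_true.data > 0):
            raise ValueError("sigma_true must be strictly positive everywhere")


def _disk_mask(grid: GridSpec, center_mm: tuple[float, float], radius_mm: float) -> np.ndarray:
    """Pixels whose center lies within ``radius_mm`` of ``center_mm``.

    Guarantees at least one pixel (the nearest center) so that a sub-pixel
    electrode still pins the potential somewhere.
    """
    xx, yy = grid.meshgrid_mm()
    r2 = (xx - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2
    mask = r2 <= radius_mm ** 2
    if not mask.any():
        mask.flat[np.argmin(r2)] = True
    return mask


def electrode_masks(grid: GridSpec, electrodes: ElectrodeConfig) -> tuple[np.ndarray, np.ndarray]:
    """Boolean pixel masks for electrode a and electrode b."""
    r = electrodes.diameter_mm / 2.0
    mask_a = _disk_mask(grid, electrodes.center_a, r)
    mask_b = _disk_mask(grid, electrodes.center_b, r)
    if (mask_a & mask_b).any():
        raise ValueError("electrode pixel footprints overlap on this grid")
    return mask_a, mask_b


def electrode_exclusion_mask(
    grid: GridSpec, electrodes: ElectrodeConfig, annulus_pixels: int = 2
) -> np.ndarray:
    """Electrode pixels dilated by ``annulus_pixels`` — the region excluded
    from quantitative error metrics (current density is near-singular there)."""
    from scipy.ndimage import binary_dilation

    mask_a, mask_b = electrode_masks(grid, electrodes)
    struct = np.ones((3, 3), dtype=bool)
    return binary_dilation(mask_a | mask_b, structure=struct, iterations=annulus_pixels)


def make_phantom(
    grid: GridSpec | None = None,
    tumor_radius_mm: float = 2.2,
    sigma_background: float = 0.2,
    sigma_tumor: float = 0.4,
    electrode_gap_mm: float = 2.2,
    seed: int = 0,
    *,
    electrode_diameter_mm: float = 0.5,
    voltage: float = 700.0,
    tumor_aspect: float = 1.0,
    heterogeneity_cv: float = 0.0,
    correlation_len_mm: float = 1.5,
) -> PhantomCase:
    """Build a tumor-in-background conductivity phantom with two electrodes.

    The tumor is a (possibly elliptical) region of ``sigma_tumor`` centered in
    the field of view; electrodes sit symmetric about the tumor center along x,
    ``electrode_gap_mm`` apart, at ±``voltage``/2.  With ``heterogeneity_cv``
    > 0 a smooth log-normal texture is multiplied onto the tumor conductivity.

    Deterministic given ``seed``.
    """
    if grid is None:
        grid = GridSpec()
    if sigma_background <= 0 or sigma_tumor <= 0:
        raise ValueError("conductivities must be positive")
    if electrode_gap_mm < electrode_diameter_mm:
        raise ValueError("electrode gap smaller than electrode diameter")
    cx = cy = grid.fov_mm / 2.0
    if tumor_radius_mm <= 0 or cx + tumor_radius_mm > grid.fov_mm:
        raise ValueError("tumor must be positive-size and fit inside the FOV")

    xx, yy = grid.meshgrid_mm()
    rx = tumor_radius_mm
    ry = tumor_radius_mm * tumor_aspect
    tumor = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0

    sigma = np.full(grid.shape, float(sigma_background))
    sigma[tumor] = float(sigma_tumor)

    electrodes = ElectrodeConfig(
        center_a=(cx - electrode_gap_mm / 2.0, cy),
        center_b=(cx + electrode_gap_mm / 2.0, cy),
        diameter_mm=electrode_diameter_mm,
        potential_a=+voltage / 2.0,
        potential_b=-voltage / 2.0,
    )
    # validate footprints early so misconfiguration fails here, not mid-solve
    electrode_masks(grid, electrodes)

    sigma_map = ScalarMap(sigma, grid, kind="conductivity")
    if heterogeneity_cv > 0:
        sigma_map = add_heterogeneity(
            sigma_map, heterogeneity_cv, correlation_len_mm, seed, mask=tumor
        )

    return PhantomCase(
        grid=grid,
        sigma_true=sigma_map,
        electrodes=electrodes,
        tumor_mask=tumor,
        seed=seed,
    )


def add_heterogeneity(
    sigma: ScalarMap,
    cv: float,
    correlation_len_mm: float = 1.5,
    seed: int = 0,
    *,
    mask: np.ndarray | None = None,
) -> ScalarMap:
    """Multiply ``sigma`` by a smooth positive random texture.

    The texture is exponentiated Gaussian-filtered white noise (a log-normal
    field, hence strictly positive) rescaled so that its sample coefficient of
    variation over ``mask`` (default: the whole map) is ``cv`` and its sample
    mean is 1, so the mean conductivity is preserved.  ``cv = 0`` returns the
    input unchanged.
    """
    if not 0.0 <= cv < 1.0:
        raise ValueError("cv must satisfy 0 <= cv < 1 (cv >= 1 would allow sigma <= 0)")
    if cv == 0.0:
        return sigma.copy()
    grid = sigma.grid
    region = np.ones(grid.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if region.sum() < 2:
        raise ValueError("heterogeneity mask must contain at least 2 pixels")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    smooth = gaussian_filter(noise, sigma=correlation_len_mm / grid.pixel_mm, mode="reflect")
    z = (smooth - smooth[region].mean()) / smooth[region].std()
    # log-normal: sd of log chosen for target cv, then sample-renormalized
    s = np.sqrt(np.log1p(cv ** 2))
    field = np.exp(s * z)
    field = 1.0 + (field - field[region].mean()) * (cv / (field[region].std() / field[region].mean()))
    field /= field[region].mean()
    if field[region].min() <= 0:  # extreme tail draw; fall back to pure log-normal
        field = np.exp(s * z)
        field /= field[region].mean()

    out = sigma.data.copy()
    out[region] = out[region] * field[region]
    return ScalarMap(out, grid, kind="conductivity")


def ground_truth_ablation(phantom: PhantomCase, protocol=None, p: float = 0.2):
    """Oracle ablation region: forward-solve on the *true* conductivity, apply
    the cell-death model, threshold at probability ``p``.

    Returns ``(region, area_mm2)`` where ``region`` is the boolean super-level
    set of the death-probability map (inclusive threshold) and ``area_mm2`` is
    its pixel-count area.  This plays the role of the reference ("histology")
    area when scoring the reconstruction-based prediction on synthetic cases.
    """
    from .damage import PulseProtocol, death_map, lookup_params, predict_area
    from .forward import compute_fields, solve_potential

    if protocol is None:
        protocol = PulseProtocol()
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")

    if phantom.electrodes.voltage == 0.0:
        region = np.zeros(phantom.grid.shape, dtype=bool)
        return region, 0.0

    u = solve_potential(phantom.sigma_true, phantom.electrodes)
    e_map, _ = compute_fields(u, phantom.sigma_true)
    d = death_map(e_map, lookup_params(protocol))
    if p == 0.0:
        region = np.ones(phantom.grid.shape, dtype=bool)
        return region, region.sum() * phantom.grid.pixel_area_mm2
    area, region = predict_area(d, p)
    return region, area
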