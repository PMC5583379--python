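"""Regular imaging grid and typed 2D maps.

All maps in the package live on a square, cell-centered grid: pixel (row, col)
has its center at ``((col + 0.5) * pixel_mm, (row + 0.5) * pixel_mm)`` with the
origin at the lower-left corner of the field of view.  Arrays are row-major
``(y, x)``; row 0 is the bottom of the domain.  The default geometry mirrors a
small-animal acquisition: a 30 mm field of view sampled on a 64 x 64 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "ScalarMap",
    "VectorMap",
    "SCALAR_KINDS",
]

#: Recognised scalar map kinds and their SI units (as serialized).
SCALAR_KINDS = {
    "conductivity": "S/m",
    "potential": "V",
    "efield": "V/m",
    "bz": "T",
    "phase": "rad",
    "death_probability": "1",
    "current_magnitude": "A/m^2",
    "mask": "1",
}


@dataclass(frozen=True)
class GridSpec:
    """Square cell-centered grid covering ``fov_mm`` x ``fov_mm``."""

    n_x: int = 64
    n_y: int = 64
    fov_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.n_x != self.n_y:
            raise ValueError(f"grid must be square, got {self.n_x}x{self.n_y}")
        if self.n_x < 3:
            raise ValueError("grid must be at least 3x3")
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be positive")

    @property
    def pixel_mm(self) -> float:
        """Pixel spacing in mm (``fov_mm / n_x`` exactly)."""
        return self.fov_mm / self.n_x

    @property
    def pixel_m(self) -> float:
        return self.pixel_mm * 1e-3

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_mm ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)

    def x_coords_mm(self) -> np.ndarray:
        """Pixel-center x coordinates, mm."""
        return (np.arange(self.n_x) + 0.5) * self.pixel_mm

    def y_coords_mm(self) -> np.ndarray:
        return (np.arange(self.n_y) + 0.5) * self.pixel_mm

    def meshgrid_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """``(X, Y)`` pixel-center coordinate maps in mm, shape ``(n_y, n_x)``."""
        return np.meshgrid(self.x_coords_mm(), self.y_coords_mm())

    def contains_mm(self, x_mm: float, y_mm: float) -> bool:
        return 0.0 <= x_mm <= self.fov_mm and 0.0 <= y_mm <= self.fov_mm


def _check_shape(data: np.ndarray, grid: GridSpec, name: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError(f"{name} shape {arr.shape} does not match grid {grid.shape}")
    return arr


@dataclass
class ScalarMap:
    """A scalar field on a :class:`GridSpec` with a unit-bearing kind tag."""

    data: np.ndarray
    grid: GridSpec
    kind: str = "conductivity"

    def __post_init__(self) -> None:
        self.data = _check_shape(self.data, self.grid, "data")
        if self.kind not in SCALAR_KINDS:
            raise ValueError(
                f"unknown map kind {self.kind!r}; known: {sorted(SCALAR_KINDS)}"
            )

    @property
    def units(self) -> str:
        return SCALAR_KINDS[self.kind]

    def copy(self) -> "ScalarMap":
        return ScalarMap(self.data.copy(), self.grid, self.kind)


@dataclass
class VectorMap:
    """An in-plane vector field (e.g. current density) on a grid."""

    x: np.ndarray
    y: np.ndarray
    grid: GridSpec
    kind: str = "current_density"
    units: str = "A/m^2"

    def __post_init__(self) -> None:
        self.x = _check_shape(self.x, self.grid, "x component")
        self.y = _check_shape(self.y, self.grid, "y component")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.x, self.y)
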