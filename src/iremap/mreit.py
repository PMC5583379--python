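"""J-substitution conductivity reconstruction and Ohm's-law field recovery.

The J-substitution scheme alternates a potential solve on the current
conductivity iterate with the pointwise update ``sigma = |J_measured| / |grad u|``:

    1. solve div(sigma_k grad u_k) = 0 with the electrode potentials as
       Dirichlet data;
    2. update sigma_{k+1} = |J| / |grad u_k| pointwise, floored/clamped;
    3. renormalize so the simulated electrode-to-electrode potential
       difference equals the applied voltage (identity under Dirichlet
       drive, computed and logged for the record);
    4. stop when the relative sigma update falls below ``tol``.

Bare J-substitution is unstable where the current stagnates (|grad u| -> 0),
so the gradient magnitude is floored and sigma is clamped to a physiological
bracket each iteration.  The electric-field map is then |E| = |J| / sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import ScalarMap
from .phantom import ElectrodeConfig, electrode_exclusion_mask, electrode_masks
from .forward import solve_potential

__all__ = [
    "ReconstructionLog",
    "j_substitution",
    "reconstruct_efield",
    "fill_electrode_region",
    "field_summary",
]

SIGMA_MIN = 1e-4  # S/m, clamp floor
SIGMA_MAX = 1e2   # S/m, clamp ceiling
GRAD_FLOOR = 1e-9  # V/m, |grad u| floor at stagnation points


@dataclass
class ReconstructionLog:
    """Convergence record of a J-substitution run."""

    iterations: int = 0
    residual_history: list[float] = field(default_factory=list)
    converged: bool = False
    clamped_pixels: int = 0
    voltage_scale_history: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "residual_history": [float(r) for r in self.residual_history],
            "converged": bool(self.converged),
            "clamped_pixels": int(self.clamped_pixels),
            "voltage_scale_history": [float(s) for s in self.voltage_scale_history],
        }


def _gradient_magnitude(u: ScalarMap) -> np.ndarray:
    h = u.grid.pixel_m
    dy, dx = np.gradient(u.data, h)
    return np.hypot(dx, dy)


def j_substitution(
    j_mag: ScalarMap,
    electrodes: ElectrodeConfig,
    sigma_init: float | ScalarMap = 0.1,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> tuple[ScalarMap, ReconstructionLog]:
    """Reconstruct conductivity from a |J| map by iterative J-substitution.

    Parameters
    ----------
    j_mag : current-density magnitude map (A/m^2), e.g. from Ampere-law CDI.
    electrodes : electrode geometry and applied potentials (the drive).
    sigma_init : uniform starting conductivity (S/m) or a full starting map.
    tol : relative sigma-update stopping threshold (L2).
    max_iter : iteration cap; on hitting it the result is returned with
        ``log.converged = False`` and the caller decides.

    Returns ``(sigma, log)``.  Electrode pixels are not updated from data
    (|grad u| is ill-defined there); they keep the current iterate's value.
    """
    grid = j_mag.grid
    if np.any(j_mag.data < 0):
        raise ValueError("|J| map must be non-negative")
    if isinstance(sigma_init, ScalarMap):
        sigma = sigma_init.data.copy()
    else:
        if sigma_init <= 0:
            raise ValueError("sigma_init must be positive")
        sigma = np.full(grid.shape, float(sigma_init))

    mask_a, mask_b = electrode_masks(grid, electrodes)
    electrode_px = mask_a | mask_b
    # |grad u| is ill-defined on the equipotential electrode pixels; they are
    # refilled from the immediately adjacent ring each iteration (pinning them
    # at sigma_init would insert a resistive skin that chokes the drive and
    # makes the iteration diverge; a wider ring would average across nearby
    # tissue boundaries and bias the local solve)
    annulus = electrode_exclusion_mask(grid, electrodes, annulus_pixels=1) & ~electrode_px
    log = ReconstructionLog()

    for it in range(1, max_iter + 1):
        u = solve_potential(ScalarMap(sigma, grid, "conductivity"), electrodes)
        grad = np.maximum(_gradient_magnitude(u), GRAD_FLOOR)
        sigma_new = j_mag.data / grad
        sigma_new[electrode_px] = sigma_new[annulus].mean()
        n_clamped = int(np.sum((sigma_new < SIGMA_MIN) | (sigma_new > SIGMA_MAX)))
        sigma_new = np.clip(sigma_new, SIGMA_MIN, SIGMA_MAX)

        # Dirichlet drive pins the inter-electrode voltage to the applied
        # value; the renormalization factor is therefore 1 by construction
        # but is computed from the solved potential and logged.
        v_sim = abs(u.data[mask_a].mean() - u.data[mask_b].mean())
        scale = electrodes.voltage / v_sim if v_sim > 0 else 1.0
        log.voltage_scale_history.append(scale)

        update = float(
            np.linalg.norm(sigma_new - sigma) / max(np.linalg.norm(sigma), 1e-300)
        )
        sigma = sigma_new
        log.iterations = it
        log.residual_history.append(update)
        log.clamped_pixels = n_clamped
        if update < tol:
            log.converged = True
            break

    return ScalarMap(sigma, grid, "conductivity"), log


def reconstruct_efield(j_mag: ScalarMap, sigma: ScalarMap) -> ScalarMap:
    """Ohm's law: ``|E| = |J| / sigma`` pointwise, in V/m."""
    if j_mag.grid != sigma.grid:
        raise ValueError("grids differ between |J| and sigma")
    if np.any(sigma.data <= 0):
        raise ValueError("sigma must be strictly positive for Ohm's-law inversion")
    return ScalarMap(j_mag.data / sigma.data, j_mag.grid, kind="efield")


def fill_electrode_region(
    m: ScalarMap, electrodes: ElectrodeConfig, annulus_pixels: int = 2
) -> ScalarMap:
    """Replace the electrode-adjacent pixels by their nearest valid neighbor.

    Reconstructed quantities are not trustworthy within a couple of pixels of
    the needles (singular current densities, and in a real acquisition
    susceptibility artifacts), so before any thresholding or area extraction
    that band is inpainted with the nearest measurable value outside it.
    """
    from scipy.ndimage import distance_transform_edt

    invalid = electrode_exclusion_mask(m.grid, electrodes, annulus_pixels)
    if invalid.all():
        raise ValueError("electrode exclusion region covers the whole map")
    _, (ir, ic) = distance_transform_edt(invalid, return_indices=True)
    data = m.data[ir, ic]
    out = m.data.copy()
    out[invalid] = data[invalid]
    return ScalarMap(out, m.grid, kind=m.kind)


def field_summary(
    e: ScalarMap,
    mask: np.ndarray | None = None,
    thresholds_kv_cm: tuple[float, ...] = (1.8,),
) -> dict:
    """Summary statistics of a field-magnitude map over ``mask``.

    ``e`` is in V/m internally; thresholds are supplied in kV/cm and the
    max/mean are reported in kV/cm, matching how treatment fields are quoted.
    """
    from .constants import V_PER_M_PER_KV_PER_CM as KV

    if mask is None:
        mask = np.ones(e.grid.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != e.grid.shape:
        raise ValueError("mask shape does not match grid")
    if not mask.any():
        raise ValueError("mask is empty")
    vals_kv = e.data[mask] / KV
    return {
        "max_kv_cm": float(vals_kv.max()),
        "mean_kv_cm": float(vals_kv.mean()),
        "fraction_above": {
            float(t): float(np.mean(vals_kv >= t)) for t in thresholds_kv_cm
        },
    }
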