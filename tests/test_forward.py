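"""Forward physics: potential solver, Ohm's-law fields, Bz synthesis, phase."""

import numpy as np
import pytest

from iremap import (
    GridSpec,
    PhaseWrapError,
    ScalarMap,
    SolverError,
    VectorMap,
    biot_savart_bz,
    compute_fields,
    make_phantom,
    phase_to_bz,
    solve_potential,
    synthesize_bz,
    synthesize_cdi_phase,
)
from iremap.constants import MU_0
from iremap.forward import solve_potential_dirichlet
from iremap.phantom import electrode_exclusion_mask


def plate_solution(n=64, sigma=0.3):
    """Left edge 0 V, right edge 1 V on a homogeneous map."""
    grid = GridSpec(n, n, 30.0)
    sig = ScalarMap(np.full(grid.shape, sigma), grid, "conductivity")
    ma = np.zeros(grid.shape, bool)
    mb = np.zeros(grid.shape, bool)
    ma[:, 0] = True
    mb[:, -1] = True
    u = solve_potential_dirichlet(sig, {"lo": (ma, 0.0), "hi": (mb, 1.0)})
    return grid, sig, u


class TestSolvePotential:
    def test_plate_mode_uniform_field(self):
        """Homogeneous plate capacitor: u linear in x, |E| = V / span."""
        grid, sig, u = plate_solution()
        e, j = compute_fields(u, sig)
        span_m = (grid.n_x - 1) * grid.pixel_m
        expected = 1.0 / span_m
        interior = np.zeros(grid.shape, bool)
        interior[2:-2, 2:-2] = True
        rel = np.abs(e.data[interior] - expected) / expected
        assert rel.max() < 0.005

    def test_two_line_source_closed_form(self):
        """Two small electrodes far from the boundary follow the
        (I / 2 pi sigma) ln(rb/ra) potential up to an additive constant."""
        grid = GridSpec(256, 256, 120.0)
        ph = make_phantom(
            grid, sigma_background=0.3, sigma_tumor=0.3,
            electrode_gap_mm=6.0, tumor_radius_mm=2.0,
        )
        u = solve_potential(ph.sigma_true, ph.electrodes)
        e, j = compute_fields(u, ph.sigma_true)
        h = grid.pixel_m
        div = np.gradient(j.x, h, axis=1) + np.gradient(j.y, h, axis=0)
        xx, yy = grid.meshgrid_mm()
        ca, cb = ph.electrodes.center_a, ph.electrodes.center_b
        box_a = (np.abs(xx - ca[0]) < 2.5) & (np.abs(yy - ca[1]) < 2.5)
        current = np.sum(div[box_a]) * h * h  # line-source strength, A/m
        ra = np.hypot(xx - ca[0], yy - ca[1]) * 1e-3
        rb = np.hypot(xx - cb[0], yy - cb[1]) * 1e-3
        u_closed = current / (2 * np.pi * 0.3) * np.log(rb / ra)
        cx = grid.fov_mm / 2
        far = (ra > 3e-3) & (rb > 3e-3)
        far &= (np.abs(xx - cx) < 12) & (np.abs(yy - cx) < 12)
        offset = (u.data - u_closed)[far].mean()
        err = np.abs(u.data - u_closed - offset)[far]
        assert err.max() / np.ptp(u_closed[far]) < 0.02

    def test_swapping_potentials_negates_u_up_to_constant(self, grid64):
        ph = make_phantom(grid64, sigma_background=0.3, sigma_tumor=0.3)
        u1 = solve_potential(ph.sigma_true, ph.electrodes)
        from dataclasses import replace

        swapped = replace(
            ph.electrodes,
            potential_a=ph.electrodes.potential_b,
            potential_b=ph.electrodes.potential_a,
        )
        u2 = solve_potential(ph.sigma_true, swapped)
        s = u1.data + u2.data
        assert np.ptp(s) < 1e-6 * np.ptp(u1.data)

    def test_scaling_voltage_scales_fields_linearly(self, grid64):
        ph1 = make_phantom(grid64, sigma_background=0.3, sigma_tumor=0.3, voltage=700.0)
        ph2 = make_phantom(grid64, sigma_background=0.3, sigma_tumor=0.3, voltage=350.0)
        e1, j1 = compute_fields(solve_potential(ph1.sigma_true, ph1.electrodes), ph1.sigma_true)
        e2, j2 = compute_fields(solve_potential(ph2.sigma_true, ph2.electrodes), ph2.sigma_true)
        np.testing.assert_allclose(e1.data, 2 * e2.data, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(j1.x, 2 * j2.x, rtol=1e-9, atol=1e-6)

    def test_discrete_maximum_principle(self, tworegion_fields):
        u = tworegion_fields["u"]
        ph = tworegion_fields["phantom"]
        assert u.data.max() <= ph.electrodes.potential_a + 1e-9
        assert u.data.min() >= ph.electrodes.potential_b - 1e-9

    def test_no_electrode_pixels_is_singular_configuration(self, grid64):
        sig = ScalarMap(np.full(grid64.shape, 0.3), grid64, "conductivity")
        empty = np.zeros(grid64.shape, bool)
        with pytest.raises(SolverError):
            solve_potential_dirichlet(sig, {"a": (empty, 0.0), "b": (empty, 1.0)})

    def test_grid_refinement_reduces_interior_error(self):
        """Plate-mode interior error decreases when n doubles (trivially ~0)
        and the two-point solve converges under refinement: the solved total
        current approaches a limit."""
        currents = []
        for n, fov in ((128, 60.0), (256, 60.0)):
            grid = GridSpec(n, n, fov)
            ph = make_phantom(
                grid, sigma_background=0.3, sigma_tumor=0.3,
                electrode_gap_mm=6.0, tumor_radius_mm=2.0,
            )
            u = solve_potential(ph.sigma_true, ph.electrodes)
            _, j = compute_fields(u, ph.sigma_true)
            currents.append(np.sum(j.x[:, n // 2]) * grid.pixel_m)
        assert abs(currents[1] - currents[0]) / currents[1] < 0.1


class TestComputeFields:
    def test_linear_potential_analytic_fields(self):
        grid = GridSpec(16, 16, 30.0)
        xx, _ = grid.meshgrid_mm()
        u = ScalarMap(-100.0 * xx * 1e-3, grid, "potential")  # slope -100 V/m
        sig = ScalarMap(np.full(grid.shape, 0.5), grid, "conductivity")
        e, j = compute_fields(u, sig)
        np.testing.assert_allclose(e.data, 100.0, rtol=1e-12)
        np.testing.assert_allclose(j.x, 50.0, rtol=1e-12)
        np.testing.assert_allclose(j.y, 0.0, atol=1e-9)

    def test_constant_potential_zero_fields(self, grid64):
        u = ScalarMap(np.full(grid64.shape, 7.0), grid64, "potential")
        sig = ScalarMap(np.full(grid64.shape, 0.5), grid64, "conductivity")
        e, j = compute_fields(u, sig)
        assert np.all(e.data == 0) and np.all(j.x == 0) and np.all(j.y == 0)

    def test_divergence_free_away_from_electrodes(self, homog_fields):
        """Discrete div J vanishes (relative to max |J| per pixel) away from
        the electrode singularities and the one-sided boundary stencils."""
        j = homog_fields["j"]
        grid = j.grid
        h = grid.pixel_m
        div = np.gradient(j.x, h, axis=1) + np.gradient(j.y, h, axis=0)
        # the truncation error of the central-difference divergence decays
        # ~r^-3 from the field singularity; 8 px (3.8 mm) is "away"
        far = ~electrode_exclusion_mask(
            grid, homog_fields["phantom"].electrodes, annulus_pixels=8
        )
        far[:2, :] = far[-2:, :] = far[:, :2] = far[:, -2:] = False
        assert (np.abs(div[far]).max() * h) / j.magnitude().max() < 1e-3


class TestBiotSavart:
    def test_zero_current_zero_field(self, grid64):
        J = VectorMap(np.zeros(grid64.shape), np.zeros(grid64.shape), grid64)
        assert np.all(biot_savart_bz(J).data == 0)

    @pytest.mark.parametrize("d_px", [3, 5, 10, 20])
    def test_single_pixel_wire_matches_closed_form(self, grid64, d_px):
        """One pixel carrying line current I: Bz(d) = mu0 I / (2 pi d)."""
        h = grid64.pixel_m
        jx = np.zeros(grid64.shape)
        jx[32, 32] = 1.0 / (h * h)  # total current 1 A
        bz = biot_savart_bz(VectorMap(jx, np.zeros(grid64.shape), grid64))
        expected = MU_0 * 1.0 / (2 * np.pi * d_px * h)
        assert bz.data[32 + d_px, 32] == pytest.approx(expected, rel=0.03)

    def test_reversing_currents_negates_bz_exactly(self, homog_fields):
        j = homog_fields["j"]
        neg = VectorMap(-j.x, -j.y, j.grid)
        np.testing.assert_array_equal(
            biot_savart_bz(neg).data, -biot_savart_bz(j).data
        )


class TestSynthesizeBz:
    def test_stream_function_inverts_to_current(self, homog_fields):
        """The synthesized measurement carries the full current: Ampere
        inversion recovers interior J (this is the CDI operating identity)."""
        from iremap import bz_to_current

        j = homog_fields["j"]
        ph = homog_fields["phantom"]
        bz = synthesize_bz(j, source_centers_mm=(ph.electrodes.center_a, ph.electrodes.center_b))
        jrec = bz_to_current(bz)
        ok = ~electrode_exclusion_mask(j.grid, ph.electrodes, annulus_pixels=2)
        ok[:2, :] = ok[-2:, :] = ok[:, :2] = ok[:, -2:] = False
        err = np.hypot(jrec.x - j.x, jrec.y - j.y)
        assert np.linalg.norm(err[ok]) / np.linalg.norm(j.magnitude()[ok]) < 0.05

    def test_source_detection_matches_supplied_centers(self, homog_fields):
        from iremap import estimate_source_current

        j = homog_fields["j"]
        ph = homog_fields["phantom"]
        i_auto, a_auto, b_auto = estimate_source_current(j)
        i_ref, a_ref, b_ref = estimate_source_current(
            j, (ph.electrodes.center_a, ph.electrodes.center_b)
        )
        assert i_auto == pytest.approx(i_ref, rel=0.05)
        assert np.hypot(a_auto[0] - a_ref[0], a_auto[1] - a_ref[1]) < 0.5


class TestPhaseSynthesis:
    def test_known_flux_and_encoding_time(self, grid64):
        """1 uT for 400 us accumulates 0.1070 rad of proton phase."""
        bz = ScalarMap(np.full(grid64.shape, 1e-6), grid64, "bz")
        phi = synthesize_cdi_phase(bz, tc=4e-4, snr=np.inf)
        np.testing.assert_allclose(phi.data, 0.1070, rtol=1e-4)

    def test_zero_flux_zero_phase(self, grid64):
        bz = ScalarMap(np.zeros(grid64.shape), grid64, "bz")
        assert np.all(synthesize_cdi_phase(bz, tc=4e-4).data == 0)

    def test_noise_free_round_trip_exact(self, grid64):
        rng = np.random.default_rng(5)
        bz = ScalarMap(rng.normal(0, 1e-7, grid64.shape), grid64, "bz")
        phi = synthesize_cdi_phase(bz, tc=4e-4, snr=np.inf)
        back = phase_to_bz(phi, tc=4e-4)
        np.testing.assert_allclose(back.data, bz.data, rtol=1e-12)

    def test_wrapping_phase_raises(self, grid64):
        bz = ScalarMap(np.full(grid64.shape, 1e-3), grid64, "bz")  # ~100 rad
        with pytest.raises(PhaseWrapError):
            synthesize_cdi_phase(bz, tc=4e-4)

    def test_rejects_nonpositive_encoding_time(self, grid64):
        bz = ScalarMap(np.zeros(grid64.shape), grid64, "bz")
        with pytest.raises(ValueError):
            synthesize_cdi_phase(bz, tc=0.0)
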