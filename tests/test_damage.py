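"""Peleg-Fermi survival model, death maps and ablation areas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iremap import (
    AreaRecord,
    MissingParameterError,
    PelegFermiParams,
    PulseProtocol,
    ScalarMap,
    area_curve,
    death_map,
    death_probability,
    load_parameter_table,
    lookup_params,
    predict_area,
    survival,
)

# frozen high-precision reference values (sympy, 20 digits) for
# Ec = 2.344 kV/cm, k = 0.2677 kV/cm
D_AT_ZERO = 1.5747753924959345e-4
D_AT_1P8 = 0.11587099617112653


class TestLookupParams:
    def test_treatment_protocol_parameters(self):
        p = lookup_params(PulseProtocol(n_pulses=8, t_p=100e-6))
        assert p.e_c == 2.344
        assert p.k == 0.2677

    def test_lookup_is_pure(self):
        a = lookup_params(PulseProtocol())
        b = lookup_params(PulseProtocol())
        assert a == b

    def test_unknown_protocol_lists_available_keys(self):
        with pytest.raises(MissingParameterError) as err:
            lookup_params(PulseProtocol(n_pulses=7, t_p=100e-6))
        assert "N=8" in str(err.value)

    def test_user_table_extension(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text(
            "n_pulses,t_p_us,e_c_kv_cm,k_kv_cm\n8,100,2.344,0.2677\n90,100,0.5,0.1\n"
        )
        table = load_parameter_table(path)
        p = lookup_params(PulseProtocol(n_pulses=90, t_p=100e-6), table)
        assert p.e_c == 0.5


class TestSurvival:
    def test_midpoint_is_exactly_half(self, pf_params):
        assert death_probability(pf_params.e_c, pf_params) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_death_at_zero_field(self, pf_params):
        assert death_probability(0.0, pf_params) == pytest.approx(
            D_AT_ZERO, rel=1e-12
        )

    def test_death_at_necrosis_threshold_field(self, pf_params):
        """At 1.8 kV/cm (the field above which necrosis was observed) the
        model predicts ~11.6% death probability."""
        assert death_probability(1.8, pf_params) == pytest.approx(
            D_AT_1P8, rel=1e-12
        )

    def test_survival_plus_death_is_one(self, pf_params):
        e = np.linspace(0, 6, 301)
        np.testing.assert_allclose(
            survival(e, pf_params) + death_probability(e, pf_params), 1.0,
            rtol=0, atol=1e-15,
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        e1=st.floats(0, 10, allow_nan=False),
        e2=st.floats(0, 10, allow_nan=False),
    )
    def test_survival_strictly_decreasing(self, pf_params, e1, e2):
        lo, hi = sorted((e1, e2))
        if hi - lo > 1e-6:  # resolvable separation at double precision
            assert survival(hi, pf_params) < survival(lo, pf_params)

    def test_negative_field_rejected(self, pf_params):
        with pytest.raises(ValueError):
            survival(-0.1, pf_params)

    def test_params_must_be_positive(self):
        with pytest.raises(ValueError):
            PelegFermiParams(e_c=-1.0, k=0.1)


class TestDeathMap:
    def test_zero_field_map_near_zero_probability(self, grid64, pf_params):
        e = ScalarMap(np.zeros(grid64.shape), grid64, "efield")
        d = death_map(e, pf_params)
        assert d.data.max() < 1e-3

    def test_constant_critical_field_gives_half(self, grid64, pf_params):
        e = ScalarMap(
            np.full(grid64.shape, pf_params.e_c * 1e5), grid64, "efield"
        )
        d = death_map(e, pf_params)
        np.testing.assert_allclose(d.data, 0.5, atol=1e-12)

    def test_pointwise_monotone_in_field(self, grid64, pf_params):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ea = rng.uniform(0, 5e5, grid64.shape)
            eb = ea + rng.uniform(0, 1e5, grid64.shape)
            da = death_map(ScalarMap(ea, grid64, "efield"), pf_params)
            db = death_map(ScalarMap(eb, grid64, "efield"), pf_params)
            assert np.all(db.data >= da.data)

    def test_wrong_kind_rejected(self, grid64, pf_params):
        bad = ScalarMap(np.zeros(grid64.shape), grid64, "conductivity")
        with pytest.raises(ValueError):
            death_map(bad, pf_params)


class TestPredictArea:
    def test_zero_probability_map_zero_area(self, grid64, pf_params):
        d = ScalarMap(np.zeros(grid64.shape), grid64, "death_probability")
        area, region = predict_area(d, 0.2)
        assert area == 0.0 and not region.any()

    def test_constant_half_map_full_fov_area(self, grid64):
        """Inclusive threshold: d = 0.5 everywhere at p = 0.2 covers the
        whole 30 mm field of view: 4096 * (30/64)^2 = 900 mm^2."""
        d = ScalarMap(np.full(grid64.shape, 0.5), grid64, "death_probability")
        area, _ = predict_area(d, 0.2)
        assert area == pytest.approx(900.0)
        # inclusive comparison keeps the p = 0.5 level non-empty too
        area_at_half, _ = predict_area(d, 0.5)
        assert area_at_half == pytest.approx(900.0)

    def test_area_nonincreasing_in_p(self, grid64):
        rng = np.random.default_rng(3)
        d = ScalarMap(rng.uniform(0, 1, grid64.shape), grid64, "death_probability")
        ps = np.linspace(0.05, 0.95, 19)
        areas = [predict_area(d, p)[0] for p in ps]
        assert all(b <= a for a, b in zip(areas, areas[1:]))
        assert max(areas) <= 900.0

    def test_largest_component_filter(self, grid64):
        d = np.zeros(grid64.shape)
        d[5:10, 5:10] = 0.9          # 25 px blob
        d[40:42, 40:42] = 0.9        # 4 px blob
        m = ScalarMap(d, grid64, "death_probability")
        full, _ = predict_area(m, 0.5)
        largest, _ = predict_area(m, 0.5, largest_component=True)
        assert full == pytest.approx(29 * grid64.pixel_area_mm2)
        assert largest == pytest.approx(25 * grid64.pixel_area_mm2)

    def test_invalid_p_rejected(self, grid64):
        d = ScalarMap(np.zeros(grid64.shape), grid64, "death_probability")
        for p in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                predict_area(d, p)


class TestAreaCurve:
    def test_matches_per_level_calls_exactly(self, grid64):
        rng = np.random.default_rng(8)
        d = ScalarMap(rng.uniform(0, 1, grid64.shape), grid64, "death_probability")
        levels = [0.1, 0.2, 0.3]
        records = area_curve(d, levels, case_id="m1")
        for rec, p in zip(records, levels):
            assert rec.a_ire == predict_area(d, p)[0]
            assert rec.case_id == "m1"
        areas = [r.a_ire for r in records]
        assert all(b <= a for a, b in zip(areas, areas[1:]))

    def test_single_level_reduces_to_predict_area(self, grid64):
        d = ScalarMap(np.full(grid64.shape, 0.4), grid64, "death_probability")
        (rec,) = area_curve(d, [0.25])
        assert rec.a_ire == predict_area(d, 0.25)[0]

    def test_non_increasing_grid_rejected(self, grid64):
        d = ScalarMap(np.zeros(grid64.shape), grid64, "death_probability")
        with pytest.raises(ValueError):
            area_curve(d, [0.3, 0.2])
        with pytest.raises(ValueError):
            area_curve(d, [])


class TestAreaRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            AreaRecord(p=0.0, a_ire=1.0)
        with pytest.raises(ValueError):
            AreaRecord(p=0.2, a_ire=-1.0)
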