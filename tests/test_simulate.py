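"""Scenario enumeration, the TNT-equivalency surrogate, and the synthetic study."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import skew

from expfusion.simulate import (
    ChemicalRecord,
    LeakScenario,
    ScenarioGrid,
    SurrogateConfig,
    chemicals_to_frame,
    dataset_to_frame,
    enumerate_scenarios,
    generate_dataset,
    make_synthetic_chemicals,
    sadovsky_scaled_distance,
    surrogate_diameter,
    standard_grid,
)


def _chem(**kw):
    base = dict(
        chem_id="x", smiles="CCO", density=500.0, heat_of_combustion=46.0,
        boiling_point=-50.0, descriptors={},
    )
    base.update(kw)
    return ChemicalRecord(**base)


class TestEnumerateScenarios:
    def test_standard_grid_has_108_release_conditions(self):
        assert len(enumerate_scenarios(standard_grid())) == 108

    @pytest.mark.parametrize(
        "axes,expected",
        [
            (((0.0,), (1.0,), (1.0,), (1.0,)), 1),
            (((0.0, 1.0), (1.0, 2.0), (1.0,), (1.0,)), 4),
        ],
    )
    def test_product_counts(self, axes, expected):
        grid = ScenarioGrid(*axes)
        assert len(enumerate_scenarios(grid)) == expected

    @given(
        nt=st.integers(1, 4), npr=st.integers(1, 3),
        nl=st.integers(1, 3), nq=st.integers(1, 3),
    )
    @settings(max_examples=25, deadline=None)
    def test_count_equals_axis_product(self, nt, npr, nl, nq):
        grid = ScenarioGrid(
            tuple(float(i) for i in range(nt)),
            tuple(float(i + 1) for i in range(npr)),
            tuple(float(i + 1) for i in range(nl)),
            tuple(float(i + 1) for i in range(nq)),
        )
        scens = enumerate_scenarios(grid)
        assert len(scens) == nt * npr * nl * nq
        assert len(set(scens)) == len(scens)

    def test_lexicographic_order(self):
        scens = enumerate_scenarios(standard_grid())
        keys = [(s.temperature, s.pressure, s.leak_size, s.quantity) for s in scens]
        assert keys == sorted(keys)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            ScenarioGrid((), (1.0,), (1.0,), (1.0,))


class TestSurrogateDiameter:
    def test_worked_example_matches_independent_root_find(self):
        """dHc=46, rho=500, V=10, leak 50, p 1000, T >> Tb: W ~ 1474.4 kg,
        Z* ~ 49.97 at 2.068 kPa, diameter ~ 1.14e3 m."""
        chem = _chem(boiling_point=-500.0)  # r_release -> 1
        scen = LeakScenario(100.0, 1000.0, 50.0, 10.0)
        z_oracle = brentq(lambda z: 95 / z + 390 / z**2 + 1300 / z**3 - 2.068, 1, 1e4)
        assert sadovsky_scaled_distance(2068.0) == pytest.approx(z_oracle, abs=1e-8)
        assert z_oracle == pytest.approx(49.97, abs=0.01)
        d = surrogate_diameter(chem, scen)
        w = 0.03 * 500.0 * 10.0 * 46.0 / 4.68
        assert w == pytest.approx(1474.4, abs=0.1)
        assert d == pytest.approx(2 * z_oracle * w ** (1 / 3), rel=1e-4)
        assert d == pytest.approx(1.14e3, rel=0.01)

    def test_doubling_quantity_scales_by_cube_root_of_two(self):
        chem = _chem()
        d1 = surrogate_diameter(chem, LeakScenario(20.0, 500.0, 25.0, 10.0))
        d2 = surrogate_diameter(chem, LeakScenario(20.0, 500.0, 25.0, 20.0))
        assert d2 / d1 == pytest.approx(2 ** (1 / 3), rel=1e-10)

    def test_scale_consistency_in_tnt_mass(self):
        # diameter(lambda^3 W) = lambda * diameter(W): via quantity factor
        chem = _chem()
        lam = 1.7
        d1 = surrogate_diameter(chem, LeakScenario(20.0, 500.0, 25.0, 5.0))
        d2 = surrogate_diameter(chem, LeakScenario(20.0, 500.0, 25.0, 5.0 * lam**3))
        assert d2 == pytest.approx(lam * d1, rel=1e-10)

    @pytest.mark.parametrize("field,lo,hi", [
        ("pressure", 100.0, 500.0),
        ("leak_size", 10.0, 25.0),
        ("quantity", 10.0, 20.0),
        ("temperature", 0.0, 50.0),
    ])
    def test_strictly_increasing_in_each_scenario_parameter(self, field, lo, hi):
        chem = _chem(boiling_point=30.0)
        base = dict(temperature=20.0, pressure=500.0, leak_size=25.0, quantity=10.0)
        lo_scen = LeakScenario(**{**base, field: lo})
        hi_scen = LeakScenario(**{**base, field: hi})
        assert surrogate_diameter(chem, hi_scen) > surrogate_diameter(chem, lo_scen)

    def test_increasing_in_heat_of_combustion(self):
        scen = LeakScenario(20.0, 500.0, 25.0, 10.0)
        assert surrogate_diameter(_chem(heat_of_combustion=40.0), scen) > surrogate_diameter(
            _chem(heat_of_combustion=20.0), scen
        )

    def test_noise_reproducible_and_multiplicative(self):
        chem, scen = _chem(), LeakScenario(20.0, 500.0, 25.0, 10.0)
        cfg = SurrogateConfig(noise_sigma=0.1, seed=7)
        assert surrogate_diameter(chem, scen, cfg) == surrogate_diameter(chem, scen, cfg)
        assert surrogate_diameter(chem, scen, cfg) != surrogate_diameter(chem, scen)


class TestSyntheticChemicals:
    def test_seeded_determinism_byte_identical(self):
        a = chemicals_to_frame(make_synthetic_chemicals(40, seed=3))
        b = chemicals_to_frame(make_synthetic_chemicals(40, seed=3))
        assert a.equals(b)

    def test_single_record_satisfies_invariants(self):
        (c,) = make_synthetic_chemicals(1, seed=0)
        assert c.density > 0 and c.heat_of_combustion > 0 and c.smiles

    def test_signal_descriptor_tracks_heat_of_combustion(self):
        chems = make_synthetic_chemicals(200, seed=1)
        dhc = np.array([c.heat_of_combustion for c in chems])
        ehomo = np.array([c.descriptors["e_homo"] for c in chems])
        assert np.corrcoef(dhc, ehomo)[0, 1] > 0.5

    def test_capacity_overflow_reuses_templates_with_warning(self):
        with pytest.warns(UserWarning, match="capacity"):
            chems = make_synthetic_chemicals(60, seed=2)
        assert len(chems) == 60
        assert len({c.chem_id for c in chems}) == 60


class TestGenerateDataset:
    def test_full_factorial_row_count(self):
        chems = make_synthetic_chemicals(3, seed=0)
        assert len(generate_dataset(chems)) == 3 * 108

    def test_single_cell(self):
        chems = make_synthetic_chemicals(1, seed=0)
        grid = ScenarioGrid((20.0,), (500.0,), (25.0,), (10.0,))
        assert len(generate_dataset(chems, grid)) == 1

    def test_noise_free_monotone_in_quantity_per_chemical(self):
        chems = make_synthetic_chemicals(5, seed=4)
        df = dataset_to_frame(generate_dataset(chems))
        for _, g in df.groupby(["chem_id", "temperature_c", "pressure_psi", "leak_size_in"]):
            d = g.sort_values("quantity_m3")["diameter_m"].to_numpy()
            assert np.all(np.diff(d) > 0)

    def test_default_study_diameters_right_skewed(self):
        chems = make_synthetic_chemicals(40, seed=0)
        df = dataset_to_frame(generate_dataset(chems))
        assert len(df) == 4320
        assert skew(df["diameter_m"]) > 0
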