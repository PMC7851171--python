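"""Materials, layered geometries and scenario presets."""

import numpy as np
import pytest

from ionobeat.geometry import GridSpec, Layer, Scenario, SensorSpec, build_scenario
from ionobeat.materials import Material, get_material, material_grueneisen


class TestGrueneisen:
    def test_water_value_at_lab_temperature(self):
        # thermal expansion 2.09e-4 K^-1, c=1484.1 m/s, Cp=4182 J/kg/K
        gamma = material_grueneisen(2.09e-4, 1484.1, 4182.0)
        assert gamma == pytest.approx(0.11, rel=0.01)

    def test_zero_expansion_gives_zero(self):
        assert material_grueneisen(0.0, 1500.0, 4000.0) == 0.0

    def test_quadratic_in_sound_speed(self):
        g1 = material_grueneisen(2e-4, 1000.0, 4000.0)
        g2 = material_grueneisen(2e-4, 2000.0, 4000.0)
        assert g2 == pytest.approx(4 * g1)

    @pytest.mark.parametrize("args", [(2e-4, 0.0, 4000.0), (2e-4, 1500.0, -1.0)])
    def test_invalid_arguments_raise(self, args):
        with pytest.raises(ValueError):
            material_grueneisen(*args)


class TestMaterial:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Material("bad", density=-1, speed_of_sound=1500, grueneisen=0.1)
        with pytest.raises(ValueError):
            Material("bad", density=1000, speed_of_sound=1500, grueneisen=-0.1)
        with pytest.raises(ValueError):
            Material("bad", density=1000, speed_of_sound=1500, grueneisen=0.1,
                     mu_a=(np.array([300.0, 700.0]), np.array([-1.0, 1.0])))

    def test_absorption_interpolation_and_contrast(self):
        water = get_material("water")
        ink = get_material("india_ink_1pct")
        # 1% India ink: 3.7e3 mm^-1 vs far below 1 mm^-1 in water at 632.8 nm
        assert ink.mu_a_at(632.8) == pytest.approx(3.7e3)
        assert water.mu_a_at(632.8) < 1.0
        assert ink.mu_a_at(632.8) / max(water.mu_a_at(632.8), 1e-12) > 1e6

    def test_transparent_material_absorbs_nothing(self):
        assert np.all(get_material("air").mu_a_at(np.linspace(300, 700, 5)) == 0)


class TestPresets:
    def test_tandem_sensor_to_entrance_window(self):
        sc = build_scenario("tandem22")
        assert sc.sensor.position == pytest.approx(36e-3)

    def test_cref_is_polyimide_when_present(self):
        assert build_scenario("tandem22").c_ref == pytest.approx(2400.0)
        assert build_scenario("tandem22_ripple").c_ref == pytest.approx(2400.0)

    def test_cfl_time_step(self):
        # dt = CFL dx / c_ref = 0.3 * 25 um / 2400 m/s = 3.125 ns
        sc = build_scenario("tandem22")
        assert sc.time_step == pytest.approx(3.125e-9)
        assert sc.time_step * sc.c_ref / sc.grid.axial_spacing == pytest.approx(sc.grid.cfl)

    def test_build_is_deterministic(self):
        a = build_scenario("tandem22").to_dict()
        b = build_scenario("tandem22").to_dict()
        assert a == b

    def test_clinical_bragg_to_edge_placement(self):
        sc = build_scenario("clinical_liver", {"bragg_to_edge": 14.49e-3})
        tumor = [l for l in sc.layers if l.material.name == "hepatic_tumor"][0]
        assert tumor.x_start == pytest.approx(0.114 - 14.49e-3)
        assert tumor.thickness == pytest.approx(0.02)
        assert sc.sensor.position == pytest.approx(0.27)

    def test_unknown_preset_and_override(self):
        with pytest.raises(KeyError):
            build_scenario("nope")
        with pytest.raises(KeyError):
            build_scenario("tandem22", {"does_not_exist": 1})

    def test_layers_tile_exactly(self):
        sc = build_scenario("tandem22", {"phantom_fill": "india_ink_1pct"})
        total = sum(l.thickness for l in sc.layers)
        span = sc.layers[-1].x_end - sc.layers[0].x_start
        assert total == pytest.approx(span, abs=1e-15)

    def test_overlapping_layers_rejected(self):
        water = get_material("water")
        with pytest.raises(ValueError):
            Scenario(
                "bad",
                (Layer(water, 0.0, 2e-3), Layer(water, 1e-3, 3e-3)),
                SensorSpec(1e-3),
                GridSpec(extent=(0.0, 2e-3)),
            )

    def test_sensor_must_be_inside_domain(self):
        water = get_material("water")
        with pytest.raises(ValueError):
            Scenario("bad", (Layer(water, 0.0, 1e-2),), SensorSpec(5e-2),
                     GridSpec(extent=(0.0, 1e-2)))


class TestSerialization:
    def test_yaml_round_trip_lossless(self, tmp_path):
        sc = build_scenario("tandem22", {"phantom_fill": "india_ink_1pct"})
        path = tmp_path / "scenario.yaml"
        sc.to_yaml(path)
        back = type(sc).from_yaml(path)
        assert back.to_dict() == sc.to_dict()
        np.testing.assert_allclose(back.sound_speed_map, sc.sound_speed_map)

    def test_water_equivalent_depth_monotone_and_invertible(self):
        sc = build_scenario("tandem22")
        x = np.linspace(-60e-3, 40e-3, 64)
        we = sc.water_equivalent_depth(x)
        assert np.all(np.diff(we) > 0)
        np.testing.assert_allclose(sc.geometric_depth(we), x, atol=1e-12)
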