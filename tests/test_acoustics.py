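"""Pressure conversion, k-space propagation, detector and superposition."""

import numpy as np
import pytest
import scipy.fft as sfft

from ionobeat.acoustics import (
    PressureField,
    PressureTrace,
    apply_pulse_train,
    detector_response,
    initial_pressure,
    propagate,
    superpose_photoacoustic,
)
from ionobeat.dose import BeamSpec, DoseMap
from ionobeat.geometry import GridSpec, Layer, Scenario, SensorSpec
from ionobeat.materials import get_material
from ionobeat.timing import square_pulse_train


def water_scenario(length=60e-3, sensor=45e-3, dx=25e-6, lateral=None, dy=50e-6):
    water = get_material("water")
    grid = GridSpec(extent=(0.0, length), axial_spacing=dx,
                    lateral_extent=lateral, lateral_spacing=dy)
    return Scenario("water_box", (Layer(water, 0.0, length),), SensorSpec(sensor), grid)


class TestInitialPressure:
    def test_one_gray_in_water(self):
        """D=1 Gy, Γ=0.11, ρ=998 -> p0 = 109.8 Pa."""
        sc = water_scenario()
        dose = DoseMap(sc.grid.x, np.ones(sc.grid.nx), BeamSpec(22.0), sc.name)
        field = initial_pressure(dose, sc)
        np.testing.assert_allclose(field.p0, 0.11 * 998.0, rtol=1e-12)

    def test_zero_dose_zero_pressure(self):
        sc = water_scenario()
        dose = DoseMap(sc.grid.x, np.zeros(sc.grid.nx), BeamSpec(22.0), sc.name)
        assert np.all(initial_pressure(dose, sc).p0 == 0)

    def test_linearity_in_grueneisen(self):
        sc = water_scenario()
        dose = DoseMap(sc.grid.x, np.ones(sc.grid.nx), BeamSpec(22.0), sc.name)
        p1 = initial_pressure(dose, sc).p0
        hot = get_material("water").with_overrides(grueneisen=0.22)
        sc2 = Scenario("hot", (Layer(hot, 0.0, 60e-3),), SensorSpec(45e-3),
                       GridSpec(extent=(0.0, 60e-3)))
        p2 = initial_pressure(DoseMap(sc2.grid.x, np.ones(sc2.grid.nx), BeamSpec(22.0), "hot"), sc2).p0
        np.testing.assert_allclose(p2, 2 * p1, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        sc = water_scenario()
        other = water_scenario(length=30e-3, sensor=20e-3)
        dose = DoseMap(other.grid.x, np.zeros(other.grid.nx), BeamSpec(22.0), "x")
        with pytest.raises(ValueError):
            initial_pressure(dose, sc)


class TestPropagation1D:
    def test_dalembert_oracle(self):
        """Homogeneous 1D: the solver splits a Gaussian p0 into two
        half-amplitude travelling waves (d'Alembert) to <1%."""
        sc = water_scenario()
        x = sc.grid.x
        x_src, sig = x[600], 0.3e-3
        p0 = np.exp(-0.5 * ((x - x_src) / sig) ** 2)
        tr = propagate(PressureField(x, p0, sc.name), sc, t_end=26e-6)
        from ionobeat.acoustics import _sensor_indices
        xs = x[_sensor_indices(sc)[0]]
        c = 1484.1
        analytic = 0.5 * np.exp(-0.5 * ((xs - x_src - c * tr.t) / sig) ** 2)
        err = np.max(np.abs(tr.p - analytic)) / analytic.max()
        assert err < 0.01

    def test_tof_matches_distance_over_c(self):
        sc = water_scenario()
        x = sc.grid.x
        x_src = x[400]
        p0 = np.exp(-0.5 * ((x - x_src) / 0.2e-3) ** 2)
        tr = propagate(PressureField(x, p0, sc.name), sc, t_end=30e-6)
        from ionobeat.acoustics import _sensor_indices
        d = x[_sensor_indices(sc)[0]] - x_src
        t_arr = tr.t[np.argmax(tr.p)]
        assert abs(t_arr - d / 1484.1) < 2 / tr.fs + sc.time_step

    def test_absorbing_boundaries_swallow_outgoing_wave(self):
        """After the wave leaves the domain nothing reflects back."""
        sc = water_scenario(length=30e-3, sensor=15e-3)
        x = sc.grid.x
        p0 = np.exp(-0.5 * ((x - x[300]) / 0.2e-3) ** 2)
        tr = propagate(PressureField(x, p0, sc.name), sc, t_end=60e-6)
        late = np.abs(tr.p[tr.t > 40e-6]).max()
        assert late < 5e-3 * np.abs(tr.p).max()

    def test_cfl_guard(self):
        sc = water_scenario()
        with pytest.raises(ValueError):
            GridSpec(extent=(0.0, 1e-2), cfl=0.6)


class TestPropagation2D:
    def test_cylindrical_amplitude_decay(self):
        """Compact 2D source: peak pressure decays ~ 1/sqrt(r)."""
        sc1 = water_scenario(length=40e-3, sensor=17.5e-3, dx=100e-6,
                             lateral=(-12.8e-3, 12.8e-3), dy=100e-6)
        x = sc1.grid.x
        y = sc1.grid.y
        src_x, sig = 5e-3, 0.25e-3
        p0 = np.exp(-0.5 * (((x[:, None] - src_x) ** 2 + y[None, :] ** 2) / sig**2))
        sc1 = Scenario(sc1.name, sc1.layers, SensorSpec(17.5e-3, geometry="point"), sc1.grid)
        tr1 = propagate(PressureField(x, p0, sc1.name, y=y), sc1, t_end=20e-6)
        sc2 = Scenario(sc1.name, sc1.layers, SensorSpec(30e-3, geometry="point"), sc1.grid)
        tr2 = propagate(PressureField(x, p0, sc2.name, y=y), sc2, t_end=20e-6)
        r1, r2 = 12.5e-3, 25e-3
        ratio = np.abs(tr1.p).max() / np.abs(tr2.p).max()
        assert ratio == pytest.approx(np.sqrt(r2 / r1), rel=0.05)

    def test_disk_sensor_averages_aperture(self):
        sc = water_scenario(length=20e-3, sensor=15e-3, dx=100e-6,
                            lateral=(-6.4e-3, 6.4e-3), dy=100e-6)
        sc_disk = Scenario(sc.name, sc.layers, SensorSpec(15e-3, geometry="disk"), sc.grid)
        x, y = sc.grid.x, sc.grid.y
        p0 = np.exp(-0.5 * (((x[:, None] - 5e-3) ** 2 + y[None, :] ** 2) / 0.3e-3**2))
        tr_point = propagate(PressureField(x, p0, sc.name, y=y), sc, t_end=10e-6)
        tr_disk = propagate(PressureField(x, p0, sc.name, y=y), sc_disk, t_end=10e-6)
        # spatial averaging over the curved wavefront lowers the disk peak
        assert np.abs(tr_disk.p).max() < np.abs(tr_point.p).max()


class TestPulseTrainConvolution:
    def _impulse(self):
        fs = 156.25e6
        p = np.zeros(4000)
        p[500] = 1.0
        return PressureTrace(p, fs, meta={"source_protons": 1e6})

    def test_delta_train_is_identity(self):
        imp = self._impulse()
        tr = square_pulse_train(6.4e-9, 1e-6, 1, 1e6)  # one-sample pulse, same charge
        out = apply_pulse_train(imp, tr)
        np.testing.assert_allclose(out.p[: imp.p.size], imp.p, atol=1e-9)

    def test_amplitude_scales_with_protons(self):
        imp = self._impulse()
        out1 = apply_pulse_train(imp, square_pulse_train(200e-9, 1e-6, 1, 1e6))
        out2 = apply_pulse_train(imp, square_pulse_train(200e-9, 1e-6, 1, 2e6))
        np.testing.assert_allclose(out2.p, 2 * out1.p, rtol=1e-12)

    def test_25_cycle_train_dominant_line(self):
        imp = self._impulse()
        out = apply_pulse_train(imp, square_pulse_train(200e-9, 400e-9, 25, 1e6))
        spec = np.abs(sfft.rfft(out.p, n=4 * out.p.size))
        freqs = sfft.rfftfreq(4 * out.p.size, out.dt)
        mask = freqs > 1e6
        assert freqs[mask][np.argmax(spec[mask])] == pytest.approx(2.5e6, rel=0.05)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            apply_pulse_train(self._impulse(), square_pulse_train(200e-9, 1e-6, 1, 0.0))


class TestDetectorResponse:
    def _tone(self, f0, fs=156.25e6, n=60000):
        t = np.arange(n) / fs
        return PressureTrace(np.sin(2 * np.pi * f0 * t), fs)

    def _gain(self, f0):
        tr = detector_response(self._tone(f0))
        settled = tr.p[tr.p.size // 2:]
        return np.abs(settled).max()

    def test_dc_is_rejected(self):
        tr = detector_response(PressureTrace(np.ones(60000), 156.25e6))
        assert np.abs(tr.p[-10000:]).max() < 1e-3

    def test_passband_gain_near_unity(self):
        assert 20 * np.log10(self._gain(5e6)) == pytest.approx(0.0, abs=1.0)

    def test_25mhz_attenuated_at_least_8db_vs_5mhz(self):
        att = 20 * np.log10(self._gain(5e6) / self._gain(25e6))
        assert att >= 8.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            detector_response(self._tone(1e6), band=(0.15e6, 90e6))


class TestSuperposition:
    def test_zero_factor_returns_iono(self):
        a = PressureTrace(np.arange(10.0), 1e6)
        b = PressureTrace(np.ones(10), 1e6)
        out = superpose_photoacoustic(a, b, 0.0)
        np.testing.assert_array_equal(out.p, a.p)

    def test_linear_in_both_arguments(self):
        rng = np.random.default_rng(0)
        a = PressureTrace(rng.normal(size=32), 1e6)
        b = PressureTrace(rng.normal(size=32), 1e6)
        out = superpose_photoacoustic(a, b, 5e5)
        np.testing.assert_allclose(out.p, a.p + 5e5 * b.p, rtol=1e-12)

    def test_axis_mismatch_rejected(self):
        a = PressureTrace(np.zeros(10), 1e6)
        b = PressureTrace(np.zeros(11), 1e6)
        with pytest.raises(ValueError):
            superpose_photoacoustic(a, b, 1.0)
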