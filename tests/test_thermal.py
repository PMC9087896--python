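import numpy as np
import pytest

from coastveg.grids import Scene
from coastveg.scene_synth import StationRecord
from coastveg.sensors import AtmosphericParameters, SensorProfile, get_sensor_profile
from coastveg.thermal import (
    calibrate_dn,
    constant_emissivity,
    planck_radiance,
    radiance_from_dn_inverse,
    radiance_to_temperature,
    retrieve_lst,
    solve_surface_radiance,
    validate_lst,
)

from conftest import make_grid

TOY = SensorProfile("toy", gain=0.05, offset=1.2, k1=666.09, k2=1282.71)


class TestCalibration:
    def test_linear_map(self):
        rad = calibrate_dn(make_grid([[100.0]]), TOY)
        assert rad.values[0, 0] == pytest.approx(6.2)

    def test_nodata_propagates(self):
        dn = make_grid([[100.0, 50.0]], mask=[[True, False]])
        rad = calibrate_dn(dn, TOY)
        assert rad.mask.tolist() == [[True, False]]

    def test_forward_inverse_within_one_quantization_step(self):
        rng = np.random.default_rng(5)
        radiance = rng.uniform(2.0, 15.0, size=(6, 6))
        dn = radiance_from_dn_inverse(radiance, TOY)
        recovered = calibrate_dn(make_grid(dn), TOY).values
        assert np.max(np.abs(recovered - radiance)) <= TOY.gain  # one DN step


class TestSurfaceRadiance:
    def test_transparent_atmosphere_black_surface_is_identity(self):
        l_sen = make_grid([[7.3, 9.1]])
        atm = AtmosphericParameters(tau=1.0, l_up=0.0, l_down=0.0)
        b = solve_surface_radiance(l_sen, constant_emissivity(l_sen, 1.0), atm)
        np.testing.assert_allclose(b.values, l_sen.values)

    def test_direct_substitution(self):
        # independent recomputation of ((L_sen − L_u)/τ − (1 − ε)·L_d)/ε
        l_sen, tau, l_up, l_down, eps = 8.0, 0.8, 1.0, 1.6, 0.95
        expected = ((l_sen - l_up) / tau - (1 - eps) * l_down) / eps
        atm = AtmosphericParameters(tau=tau, l_up=l_up, l_down=l_down)
        grid = make_grid([[l_sen]])
        b = solve_surface_radiance(grid, constant_emissivity(grid, eps), atm)
        assert b.values[0, 0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(9.126315789473684)

    def test_nonpositive_surface_radiance_masked(self):
        atm = AtmosphericParameters(tau=0.8, l_up=1.0, l_down=0.0)
        grid = make_grid([[1.0]])  # L_sen == L_u → B = 0
        b = solve_surface_radiance(grid, constant_emissivity(grid, 0.95), atm)
        assert bool(b.mask[0, 0])

    def test_monotone_in_sensor_radiance(self):
        atm = AtmosphericParameters(tau=0.8, l_up=1.0, l_down=1.6)
        grid = make_grid(np.linspace(4, 14, 20).reshape(1, -1))
        b = solve_surface_radiance(grid, constant_emissivity(grid, 0.95), atm)
        assert np.all(np.diff(b.values[0]) > 0)


class TestPlanckInversion:
    @pytest.mark.parametrize("sensor", ["tm", "etm", "oli_tirs"])
    def test_radiance_forcing_unit_log_gives_k2(self, sensor):
        profile = get_sensor_profile(sensor)
        b = make_grid([[profile.k1 / (np.e - 1.0)]])
        t = radiance_to_temperature(b, profile)
        assert t.values[0, 0] == pytest.approx(profile.k2, abs=1e-9)

    def test_temperature_roundtrip_over_plausible_sweep(self):
        profile = get_sensor_profile("oli_tirs")
        t0 = np.linspace(220.0, 340.0, 601).reshape(1, -1)
        b = planck_radiance(t0, profile)
        t1 = radiance_to_temperature(make_grid(b), profile).values
        assert np.max(np.abs(t1 - t0)) < 1e-9

    def test_strictly_increasing_in_radiance(self):
        profile = get_sensor_profile("tm")
        b = make_grid(np.linspace(0.5, 30, 50).reshape(1, -1))
        t = radiance_to_temperature(b, profile)
        assert np.all(np.diff(t.values[0]) > 0)

    def test_nonpositive_radiance_masked_not_raised(self):
        t = radiance_to_temperature(make_grid([[-1.0, 0.0, 5.0]]), TOY)
        assert t.mask.tolist() == [[True, True, False]]


class TestRetrieveLst:
    def test_reduces_to_brightness_temperature(self):
        profile = get_sensor_profile("oli_tirs")
        dn = make_grid(np.array([[20000.0, 25000.0, 30000.0]]))
        scene = Scene(
            red=make_grid([[0.2, 0.2, 0.2]]),
            nir=make_grid([[0.4, 0.4, 0.4]]),
            thermal=dn,
            sensor_id="oli_tirs",
        )
        atm = AtmosphericParameters(tau=1.0, l_up=0.0, l_down=0.0)
        lst = retrieve_lst(scene, constant_emissivity(dn, 1.0), atm)
        expected = radiance_to_temperature(calibrate_dn(dn, profile), profile)
        np.testing.assert_allclose(lst.values, expected.values)

    def test_missing_thermal_band_is_an_error(self):
        scene = Scene(red=make_grid([[0.2]]), nir=make_grid([[0.4]]), thermal=None)
        atm = AtmosphericParameters(tau=1.0, l_up=0.0, l_down=0.0)
        with pytest.raises(ValueError, match="thermal"):
            retrieve_lst(scene, constant_emissivity(scene.red, 1.0), atm)

    def test_plausibility_bounds_mask_gross_failures(self):
        profile = get_sensor_profile("oli_tirs")
        dn = make_grid([[100.0, 25000.0]])  # first pixel implausibly cold
        scene = Scene(
            red=make_grid([[0.2, 0.2]]), nir=make_grid([[0.4, 0.4]]), thermal=dn
        )
        atm = AtmosphericParameters(tau=1.0, l_up=0.0, l_down=0.0)
        lst = retrieve_lst(scene, constant_emissivity(dn, 1.0), atm, profile=profile)
        assert bool(lst.mask[0, 0]) and not bool(lst.mask[0, 1])


def _stations_for(grid, residuals):
    geom = grid.geometry
    recs = []
    for i, resid in enumerate(residuals):
        x = geom.x_origin + (i + 0.5) * geom.cell_size
        y = geom.y_origin - 0.5 * geom.cell_size
        recs.append(
            StationRecord(f"S{i}", x, y, temperature_k=grid.values[0, i] - resid)
        )
    return recs


class TestValidation:
    def test_perfect_predictions(self):
        lst = make_grid([[300.0, 301.0, 302.0]])
        res = validate_lst(lst, _stations_for(lst, [0, 0, 0]))
        assert (res.mae, res.rmse, res.n) == (0.0, 0.0, 3)

    def test_alternating_unit_residuals(self):
        lst = make_grid([[300.0, 301.0, 302.0, 303.0]])
        res = validate_lst(lst, _stations_for(lst, [1, -1, 1, -1]))
        assert res.mae == pytest.approx(1.0)
        assert res.rmse == pytest.approx(1.0)

    def test_closed_form_mae_rmse(self):
        lst = make_grid([[300.0, 301.0]])
        res = validate_lst(lst, _stations_for(lst, [3, 4]))
        assert res.mae == pytest.approx(3.5)
        assert res.rmse == pytest.approx(np.sqrt(12.5))

    def test_station_outside_grid_dropped_and_empty_match_raises(self):
        lst = make_grid([[300.0]])
        far = StationRecord("far", 1e7, 1e7, 300.0)
        with pytest.raises(ValueError, match="no station"):
            validate_lst(lst, [far])


def test_transmissivity_mismatch_degrades_station_mae(small_scene):
    from coastveg.scene_synth import generate_stations
    from coastveg.thermal import emissivity_from_fvc
    from coastveg.vegetation import DimidiateEndpoints, compute_fvc, compute_ndvi

    spec, scene, truth = small_scene
    stations = generate_stations(truth, n=15, noise_sd=0.0, seed=9)
    fvc = compute_fvc(compute_ndvi(scene), DimidiateEndpoints(0.06, 0.6))
    eps = emissivity_from_fvc(fvc)
    atm = truth.atmosphere
    mae_true = validate_lst(retrieve_lst(scene, eps, atm), stations).mae
    for dtau in (-0.1, +0.1):
        perturbed = AtmosphericParameters(atm.tau + dtau, atm.l_up, atm.l_down)
        mae = validate_lst(retrieve_lst(scene, eps, perturbed), stations).mae
        assert mae > mae_true
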