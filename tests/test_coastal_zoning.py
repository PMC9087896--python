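import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from coastveg.coastal_zoning import (
    CoastlineGeometry,
    assign_zone,
    build_fishnet,
    distance_to_coast,
    fit_zone_regression,
)

from conftest import make_grid


class TestDistance:
    def test_point_on_the_coastline(self):
        coast = CoastlineGeometry(LineString([(0, 0), (0, 1000)]))
        assert distance_to_coast([0.0], [500.0], coast)[0] == 0.0

    def test_perpendicular_distance_to_vertical_line(self):
        coast = CoastlineGeometry(LineString([(0, -1e6), (0, 1e6)]))
        assert distance_to_coast([30_000.0], [0.0], coast)[0] == pytest.approx(30.0)

    def test_against_dense_sampling_oracle(self):
        rng = np.random.default_rng(8)
        verts = rng.uniform(0, 1000, size=(5, 2))
        coast = CoastlineGeometry(LineString(verts))
        px, py = rng.uniform(-500, 1500, size=10), rng.uniform(-500, 1500, size=10)
        fast = distance_to_coast(px, py, coast) * 1000.0  # back to metres
        # brute force: minimum distance to points sampled every ~0.2 m along the line
        n = int(coast.line.length / 0.2)
        samples = np.array(
            [coast.line.interpolate(f, normalized=True).coords[0] for f in np.linspace(0, 1, n)]
        )
        brute = np.min(
            np.hypot(px[:, None] - samples[None, :, 0], py[:, None] - samples[None, :, 1]),
            axis=1,
        )
        np.testing.assert_allclose(fast, brute, atol=1.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        verts = rng.uniform(0, 1000, size=(4, 2))
        px, py = rng.uniform(0, 2000, size=20), rng.uniform(0, 2000, size=20)
        shift = np.array([12345.6, -9876.5])
        d0 = distance_to_coast(px, py, CoastlineGeometry(LineString(verts)))
        d1 = distance_to_coast(
            px + shift[0], py + shift[1], CoastlineGeometry(LineString(verts + shift))
        )
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_crs_mismatch_rejected(self):
        coast = CoastlineGeometry(LineString([(0, 0), (0, 1)]), crs="EPSG:32650")
        with pytest.raises(ValueError, match="CRS"):
            distance_to_coast([1.0], [1.0], coast, crs="EPSG:4326")


class TestZoneAssignment:
    @pytest.mark.parametrize(
        "d, zone",
        [(5, "offshore"), (15, "middle"), (30, "inland"), (10, "offshore"), (25, "middle"), (0, "offshore")],
    )
    def test_labels_and_boundaries(self, d, zone):
        assert assign_zone(float(d)) == zone

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            assign_zone(-1.0)

    def test_partition_over_array(self):
        d = np.linspace(0, 60, 500)
        zones = assign_zone(d)
        counts = pd.Series(zones).value_counts()
        assert counts.sum() == 500
        assert set(counts.index) == {"offshore", "middle", "inland"}


def _west_coast():
    return CoastlineGeometry(LineString([(0, -1e7), (0, 1e7)]))


class TestFishnet:
    def test_uniform_fields_give_exact_cell_means(self):
        fvc = make_grid(np.full((8, 8), 0.5), cell_size=100.0)
        lst = make_grid(np.full((8, 8), 300.0), cell_size=100.0)
        table = build_fishnet(fvc, lst, _west_coast(), cell_length=200.0)
        assert len(table) == 16
        assert (table["mean_fvc"] == 0.5).all()
        assert (table["mean_lst_k"] == 300.0).all()
        assert (table["zone"] == "offshore").all()

    def test_noninteger_cell_ratio_rejected(self):
        fvc = make_grid(np.full((8, 8), 0.5), cell_size=30.0)
        lst = make_grid(np.full((8, 8), 300.0), cell_size=30.0)
        with pytest.raises(ValueError, match="multiple"):
            build_fishnet(fvc, lst, _west_coast(), cell_length=100.0)

    def test_fully_masked_cell_dropped_and_half_valid_kept(self):
        values = np.full((4, 4), 1.0)
        mask = np.zeros((4, 4), bool)
        mask[:2, :2] = True  # top-left fishnet cell fully NoData
        mask[0, 2] = True  # top-right cell: 3/4 valid
        fvc = make_grid(values, cell_size=100.0, mask=mask)
        lst = make_grid(np.full((4, 4), 300.0), cell_size=100.0, mask=mask)
        table = build_fishnet(
            fvc, lst, _west_coast(), cell_length=200.0, min_valid_fraction=0.5
        )
        assert len(table) == 3
        assert set(table["n_valid"]) == {3, 4}

    def test_means_match_brute_force_aggregation(self):
        rng = np.random.default_rng(17)
        vals_f = rng.random((12, 18))
        vals_l = rng.normal(300, 2, size=(12, 18))
        mask = rng.random((12, 18)) < 0.3
        fvc = make_grid(vals_f, cell_size=50.0, mask=mask)
        lst = make_grid(vals_l, cell_size=50.0, mask=mask)
        table = build_fishnet(
            fvc, lst, _west_coast(), cell_length=150.0, min_valid_fraction=0.1
        )
        block = 3
        ncol = 18 // block
        for _, row in table.iterrows():
            cid = int(row["cell_id"])
            r0, c0 = (cid // ncol) * block, (cid % ncol) * block
            sel = ~mask[r0 : r0 + block, c0 : c0 + block]
            assert row["mean_fvc"] == pytest.approx(
                vals_f[r0 : r0 + block, c0 : c0 + block][sel].mean(), abs=1e-12
            )
            assert row["mean_lst_k"] == pytest.approx(
                vals_l[r0 : r0 + block, c0 : c0 + block][sel].mean(), abs=1e-12
            )

    def test_zone_populations_partition_retained_cells(self):
        rng = np.random.default_rng(23)
        fvc = make_grid(rng.random((10, 200)), cell_size=200.0)
        lst = make_grid(rng.normal(300, 1, size=(10, 200)), cell_size=200.0)
        table = build_fishnet(fvc, lst, _west_coast(), cell_length=200.0)
        assert table["zone"].value_counts().sum() == len(table)
        assert set(table["zone"]) == {"offshore", "middle", "inland"}


class TestRegression:
    def test_exact_line(self):
        fvc = np.linspace(0.1, 0.9, 30)
        table = pd.DataFrame(
            {"zone": "offshore", "mean_fvc": fvc, "mean_lst_k": 310.0 - 5.0 * fvc}
        )
        fit = fit_zone_regression(table, "offshore")
        assert fit.slope == pytest.approx(-5.0)
        assert fit.intercept == pytest.approx(310.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.n == 30

    def test_insufficient_cells(self):
        table = pd.DataFrame(
            {"zone": ["inland"] * 2, "mean_fvc": [0.1, 0.2], "mean_lst_k": [300, 301]}
        )
        with pytest.raises(ValueError, match="at least 3"):
            fit_zone_regression(table, "inland")

    def test_constant_fvc_degenerate(self):
        table = pd.DataFrame(
            {"zone": ["middle"] * 5, "mean_fvc": [0.4] * 5, "mean_lst_k": range(5)}
        )
        with pytest.raises(ValueError, match="constant FVC"):
            fit_zone_regression(table, "middle")

    def test_unknown_zone_rejected(self):
        with pytest.raises(ValueError, match="unknown zone"):
            fit_zone_regression(pd.DataFrame({"zone": []}), "nearshore")
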