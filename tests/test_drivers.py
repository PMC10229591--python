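"""Climate distance, OLS fits, least-cost isolation, hierarchical
partitioning and the time-resolved driver series."""

import numpy as np
import pandas as pd
import pytest

from florealm.containers import BetaMatrix, ClimateTable, CostSurface, Partition
from florealm.drivers import (
    CostParams,
    climate_distance,
    driver_series,
    hpart_two,
    isolation_series,
    least_cost_isolation,
    ols_r2,
    within_between_r2,
)
from florealm.errors import ConsistencyError, InvalidParameterError

KM_PER_DEG = 111.195


def _climate(rows):
    frame = pd.DataFrame(rows).set_index("gsu_id")
    return ClimateTable(frame=frame)


class TestClimateDistance:
    def test_identical_climates_zero(self):
        clim = _climate(
            [
                {"gsu_id": "a", "mat_c": 10.0, "map_mm": 800.0},
                {"gsu_id": "b", "mat_c": 10.0, "map_mm": 800.0},
                {"gsu_id": "c", "mat_c": 20.0, "map_mm": 400.0},
            ]
        )
        dist = climate_distance(clim)
        assert dist.loc["a", "b"] == pytest.approx(0.0)

    def test_one_sd_each_axis_gives_sqrt2(self):
        clim = _climate(
            [
                {"gsu_id": "a", "mat_c": 0.0, "map_mm": 0.0},
                {"gsu_id": "b", "mat_c": 2.0, "map_mm": 100.0},
            ]
        )
        # two points: each variable has SD = half its range, so the pair
        # sits 2 SD apart per axis -> distance 2*sqrt(2)
        dist = climate_distance(clim)
        assert dist.loc["a", "b"] == pytest.approx(2 * np.sqrt(2))

    def test_zero_variance_variable_rejected(self):
        clim = _climate(
            [
                {"gsu_id": "a", "mat_c": 5.0, "map_mm": 100.0},
                {"gsu_id": "b", "mat_c": 5.0, "map_mm": 300.0},
            ]
        )
        with pytest.raises(InvalidParameterError):
            climate_distance(clim)
        raw = climate_distance(clim, standardize=False)
        assert raw.loc["a", "b"] == pytest.approx(200.0)

    def test_symmetry_zero_diagonal(self, rng):
        clim = _climate(
            [
                {"gsu_id": f"g{i}", "mat_c": rng.normal(), "map_mm": abs(rng.normal()) * 100}
                for i in range(6)
            ]
        )
        dist = climate_distance(clim)
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0.0)


class TestOlsR2:
    def test_perfect_line(self):
        x = np.arange(10.0)
        assert ols_r2(2 * x + 1, x) == pytest.approx(1.0)

    def test_orthogonal_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert ols_r2(y, x) == pytest.approx(0.0, abs=1e-12)

    def test_equals_sse_formula(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        slope, intercept = np.polyfit(x, y, 1)
        sse = ((y - slope * x - intercept) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert ols_r2(y, x) == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(InvalidParameterError):
            ols_r2(np.arange(4.0), np.ones(4))


class TestLeastCost:
    def _flat_row(self, mask):
        return CostSurface(
            time=0.0,
            mask=np.asarray([mask], bool),
            elevation=np.zeros((1, len(mask))),
            cellsize=1.0,
            xllcorner=0.0,
            yllcorner=-0.5,
        )

    def _centroids(self, n):
        return pd.DataFrame(
            {
                "gsu_id": [f"g{i}" for i in range(n)],
                "lon": [i + 0.5 for i in range(n)],
                "lat": [0.0] * n,
            }
        )

    def test_collinear_equatorial_cells(self):
        surface = self._flat_row([True, True, True])
        iso = least_cost_isolation(
            surface, self._centroids(3), CostParams(k_ocean=10, k_elev=0)
        )
        assert iso.value("g0", "g2") == pytest.approx(2 * KM_PER_DEG, rel=1e-4)

    def test_ocean_middle_cell_multiplies_cost(self):
        land = self._flat_row([True, True, True])
        ocean = self._flat_row([True, False, True])
        params = CostParams(k_ocean=10, k_elev=0)
        cent = self._centroids(3)
        base = least_cost_isolation(land, cent, params)
        detour = least_cost_isolation(ocean, cent, params)
        # both edges now average land (1) and ocean (10) friction: 5.5x
        assert detour.value("g0", "g2") == pytest.approx(
            base.value("g0", "g2") * 5.5, rel=1e-6
        )

    def test_triangle_inequality_random_surface(self, rng):
        mask = rng.random((6, 6)) > 0.2
        mask[0, 0] = mask[5, 5] = mask[2, 3] = True
        surface = CostSurface(
            time=0.0,
            mask=mask,
            elevation=np.where(mask, rng.random((6, 6)) * 2000, 0.0),
            cellsize=1.0,
            xllcorner=0.0,
            yllcorner=-3.0,
        )
        cent = pd.DataFrame(
            {
                "gsu_id": [f"g{i}" for i in range(6)],
                "lon": rng.random(6) * 6,
                "lat": rng.random(6) * 6 - 3,
            }
        )
        iso = least_cost_isolation(surface, cent)
        ids = iso.gsu_ids
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    assert (
                        iso.values[a, c]
                        <= iso.values[a, b] + iso.values[b, c] + 1e-9
                    )
        assert np.allclose(iso.values, iso.values.T)
        assert np.allclose(np.diag(iso.values), 0.0)
        assert len(ids) == 6


class TestHpartTwo:
    def test_identity_holds(self, rng):
        for _ in range(100):
            x1 = rng.normal(size=20)
            x2 = rng.normal(size=20)
            y = rng.normal(size=20)
            i1, i2, full = hpart_two(y, x1, x2)
            assert i1 + i2 == pytest.approx(full, abs=1e-12)
            assert i1 >= -1e-12 and i2 >= -1e-12

    def test_matches_orderings_average(self, rng):
        x1 = rng.normal(size=40)
        x2 = 0.3 * x1 + rng.normal(size=40)
        y = x1 + 0.5 * x2 + rng.normal(size=40)
        i1, i2, full = hpart_two(y, x1, x2)

        def r2(design):
            d = np.column_stack([np.ones(len(y))] + design)
            coef, *_ = np.linalg.lstsq(d, y, rcond=None)
            resid = y - d @ coef
            return 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()

        # ordering A: x1 first; ordering B: x1 second
        inc_a = r2([x1])
        inc_b = r2([x1, x2]) - r2([x2])
        assert i1 == pytest.approx((inc_a + inc_b) / 2, abs=1e-12)

    def test_pure_signal_attributed_to_its_predictor(self, rng):
        x1 = rng.normal(size=60)
        x2 = rng.normal(size=60)
        y = x1.copy()
        i1, i2, full = hpart_two(y, x1, x2)
        assert i1 > 0.9 * full and i2 < 0.1

    def test_collinear_predictors_split_evenly(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(size=20) * 0.1
        i1, i2, full = hpart_two(y, x, x)
        assert i1 == pytest.approx(i2) == pytest.approx(full / 2)


def _toy_driver_inputs():
    ids = ["a1", "a2", "b1", "b2"]
    beta_vals = np.array(
        [
            [0.0, 0.1, 0.8, 0.9],
            [0.1, 0.0, 0.7, 0.8],
            [0.8, 0.7, 0.0, 0.1],
            [0.9, 0.8, 0.1, 0.0],
        ]
    )
    beta = BetaMatrix(ids, beta_vals)
    part = Partition({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    return beta, part


def test_driver_series_constant_bins_have_zero_se(rng):
    from florealm.drivers import IsolationMatrix

    beta, part = _toy_driver_inputs()
    ids = beta.gsu_ids
    iso_vals = rng.random((4, 4))
    iso_vals = (iso_vals + iso_vals.T) * 50
    np.fill_diagonal(iso_vals, 0)
    clim = ClimateTable(
        frame=pd.DataFrame(
            {"mat_c": [1.0, 2.0, 3.0, 4.0], "map_mm": [10.0, 30.0, 70.0, 90.0]},
            index=pd.Index(ids, name="gsu_id"),
        )
    )
    iso = [
        IsolationMatrix(time=float(t), gsu_ids=ids, values=iso_vals)
        for t in range(5)
    ]
    clims = [
        ClimateTable(frame=clim.frame, time=float(t)) for t in range(5)
    ]
    series = driver_series(beta, part, (1, 2), iso, clims)
    assert len(series.steps) == 5
    row = series.bins.iloc[0]
    assert row["n_steps"] == 5
    assert row["i_geo_se"] == pytest.approx(0.0, abs=1e-12)
    assert row["i_clim_se"] == pytest.approx(0.0, abs=1e-12)


def test_driver_series_misaligned_grids_rejected(rng):
    from florealm.drivers import IsolationMatrix

    beta, part = _toy_driver_inputs()
    ids = beta.gsu_ids
    iso = [IsolationMatrix(time=0.0, gsu_ids=ids, values=np.zeros((4, 4)))]
    clim = [
        ClimateTable(
            frame=pd.DataFrame(
                {"mat_c": [1.0] * 4, "map_mm": [2.0] * 4},
                index=pd.Index(ids, name="gsu_id"),
            ),
            time=3.0,
        )
    ]
    with pytest.raises(ConsistencyError):
        driver_series(beta, part, (1, 2), iso, clim)


def test_within_between_r2_structure():
    beta, part = _toy_driver_inputs()
    clim = pd.DataFrame(
        np.array(
            [
                [0.0, 0.1, 0.8, 0.9],
                [0.1, 0.0, 0.7, 0.8],
                [0.8, 0.7, 0.0, 0.1],
                [0.9, 0.8, 0.1, 0.0],
            ]
        ),
        index=beta.gsu_ids,
        columns=beta.gsu_ids,
    )
    table = within_between_r2(beta, part, clim, min_pairs=1)
    scopes = set(table["scope"])
    assert scopes == {"within:1", "within:2", "between:1-2"}
    between = table.set_index("scope").loc["between:1-2"]
    assert between["n_pairs"] == 4
    assert between["r2"] == pytest.approx(1.0)  # beta == climate distance
    within = table.set_index("scope").loc["within:1"]
    assert within["flag"] != "" or np.isnan(within["r2"]) or within["n_pairs"] == 1


def test_within_between_insufficient_pairs_flagged():
    beta, part = _toy_driver_inputs()
    clim = pd.DataFrame(
        np.ones((4, 4)) - np.eye(4), index=beta.gsu_ids, columns=beta.gsu_ids
    )
    table = within_between_r2(beta, part, clim, min_pairs=3)
    flagged = table[table["scope"].str.startswith("within")]
    assert (flagged["flag"] == "insufficient").all()


def test_isolation_series_caches_identical_surfaces(paleo_like_surfaces):
    surfaces, cent = paleo_like_surfaces
    series = isolation_series(surfaces, cent)
    assert [m.time for m in series] == [s.time for s in surfaces]
    # identical masks share values
    assert np.array_equal(series[1].values, series[2].values)


@pytest.fixture
def paleo_like_surfaces():
    mask_open = np.ones((2, 4), bool)
    mask_strip = mask_open.copy()
    mask_strip[:, 2] = False
    def make(t, mask):
        return CostSurface(
            time=t, mask=mask, elevation=np.zeros((2, 4)),
            cellsize=1.0, xllcorner=0.0, yllcorner=-1.0,
        )
    surfaces = [make(0.0, mask_strip), make(1.0, mask_open), make(2.0, mask_open)]
    cent = pd.DataFrame(
        {"gsu_id": ["a", "b"], "lon": [0.5, 3.5], "lat": [0.5, 0.5]}
    )
    return surfaces, cent
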