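"""Drivers of realm divergence: contemporary climate, historical climate,
and geographic isolation.

Contemporary-climate effects are OLS fits of phylogenetic beta diversity on
pairwise climate distance (Euclidean in z-scored temperature/precipitation
space), compared within vs between realms on raw scales. The time-resolved
attribution regresses, at every time step, ln(beta) on ln(geographic
isolation) and ln(historical climate distance) for the cross-realm GSU
pairs of one realm pair, and splits the full-model R^2 into independent
contributions by hierarchical partitioning; per-5-Ma bins summarise the
series as mean +/- SE.

Geographic isolation between two GSUs at a time step is the minimum
accumulated route cost over the paleo-landscape: 8-neighbour moves between
raster cells, each edge costing the great-circle length between the cell
centers times the mean friction of the two cells, with friction
1 + k_elev * (elevation / 1000 m) on land and k_ocean on ocean. The
functional form and constants are configuration, not data: defaults are
k_ocean = 10 (ocean an order of magnitude more resistant than flat land)
and k_elev = 1 (one extra land-unit of friction per km of elevation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .containers import BetaMatrix, ClimateTable, CostSurface, Partition
from .errors import (
    ConsistencyError,
    InsufficientDataError,
    InvalidParameterError,
)

logger = logging.getLogger("florealm")

__all__ = [
    "CostParams",
    "IsolationMatrix",
    "DriverSeries",
    "climate_distance",
    "ols_r2",
    "within_between_r2",
    "least_cost_isolation",
    "hpart_two",
    "driver_series",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class CostParams:
    """Route-cost constants; friction(land) = 1 + k_elev*elev_km, ocean = k_ocean."""

    k_ocean: float = 10.0
    k_elev: float = 1.0

    def __post_init__(self):
        if self.k_ocean <= 0 or self.k_elev < 0:
            raise InvalidParameterError("need k_ocean > 0 and k_elev >= 0")


@dataclass
class IsolationMatrix:
    """Pairwise minimum route costs among GSUs at one time step."""

    time: float
    gsu_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, km-equivalent units

    def __post_init__(self):
        n = len(self.gsu_ids)
        if self.values.shape != (n, n):
            raise ConsistencyError("isolation matrix shape mismatch")
        self._index = {g: i for i, g in enumerate(self.gsu_ids)}

    def value(self, gsu1: str, gsu2: str) -> float:
        return float(self.values[self._index[gsu1], self._index[gsu2]])


def climate_distance(
    climate: ClimateTable, standardize: bool = True
) -> pd.DataFrame:
    """Pairwise Euclidean distance in (temperature, precipitation) space.

    With ``standardize`` (default) both variables are z-scored first, since
    degrees Celsius and millimetres are incommensurable.
    """
    ids = sorted(climate.gsu_ids)
    x = climate.values_for(ids)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        if (sd == 0).any():
            bad = ["mat_c", "map_mm"][int(np.argmax(sd == 0))]
            raise InvalidParameterError(
                f"cannot standardize zero-variance climate variable {bad!r}"
            )
        x = (x - x.mean(axis=0)) / sd
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return pd.DataFrame(dist, index=ids, columns=ids)


def ols_r2(response: np.ndarray, predictor: np.ndarray) -> float:
    """Coefficient of determination of the least-squares line."""
    response = np.asarray(response, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    if response.shape != predictor.shape or response.ndim != 1:
        raise InvalidParameterError("response and predictor must be aligned 1-D")
    if response.size < 3:
        raise InsufficientDataError("need at least 3 pairs for a fit")
    if np.ptp(predictor) == 0:
        raise InvalidParameterError("constant predictor: R^2 undefined")
    sst = ((response - response.mean()) ** 2).sum()
    if sst == 0:
        return 0.0
    slope, intercept = np.polyfit(predictor, response, 1)
    sse = ((response - (slope * predictor + intercept)) ** 2).sum()
    return float(1.0 - sse / sst)


def within_between_r2(
    beta: BetaMatrix,
    partition: Partition,
    climdist: pd.DataFrame,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Climate explanatory power within each realm and between realm pairs.

    One row per realm (within-realm GSU pairs) and per realm pair
    (cross-realm pairs only), with the OLS R^2 of beta on climate distance,
    the pair count, and a flag for entries with too few pairs or a constant
    predictor.
    """
    ids = beta.gsu_ids
    labels = partition.label_vector(ids)
    cd = climdist.loc[ids, ids].to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    bvals = beta.values[iu]
    cvals = cd[iu]
    li, lj = labels[iu[0]], labels[iu[1]]
    rows = []
    for realm in sorted(set(labels.tolist())):
        sel = (li == realm) & (lj == realm)
        rows.append(_fit_row(f"within:{realm}", bvals[sel], cvals[sel], min_pairs))
    realms = sorted(set(labels.tolist()))
    for a in range(len(realms)):
        for b in range(a + 1, len(realms)):
            p, q = realms[a], realms[b]
            sel = ((li == p) & (lj == q)) | ((li == q) & (lj == p))
            rows.append(
                _fit_row(f"between:{p}-{q}", bvals[sel], cvals[sel], min_pairs)
            )
    return pd.DataFrame(rows)


def _fit_row(scope: str, y: np.ndarray, x: np.ndarray, min_pairs: int) -> dict:
    row = {"scope": scope, "n_pairs": int(y.size), "r2": np.nan, "flag": ""}
    if y.size < min_pairs:
        row["flag"] = "insufficient"
        return row
    try:
        row["r2"] = ols_r2(y, x)
    except (InvalidParameterError, InsufficientDataError) as exc:
        row["flag"] = str(exc)
    return row


def _haversine_km(lon1, lat1, lon2, lat2) -> float:
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    dp = p2 - p1
    h = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def least_cost_isolation(
    surface: CostSurface,
    centroids: pd.DataFrame,
    params: CostParams = CostParams(),
) -> IsolationMatrix:
    """All-pairs minimum route costs among GSU centroids on one surface.

    ``centroids`` needs columns gsu_id, lon, lat. Each centroid snaps to its
    raster cell; centroids falling on ocean are snapped to the nearest land
    cell with a logged warning. Costs are in km-equivalents (great-circle km
    times friction); they form a shortest-path metric, so the triangle
    inequality holds by construction.
    """
    nrows, ncols = surface.shape
    elev_km = np.where(surface.mask, surface.elevation, 0.0) / 1000.0
    friction = np.where(
        surface.mask, 1.0 + params.k_elev * elev_km, params.k_ocean
    )

    def node(r: int, c: int) -> int:
        return r * ncols + c

    src_nodes, dst_nodes, weights = [], [], []
    moves = [(-1, -1), (-1, 0), (-1, 1), (0, 1)]  # half of 8-neighbourhood
    for r in range(nrows):
        for c in range(ncols):
            lon1, lat1 = surface.cell_center(r, c)
            for dr, dc in moves:
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nrows and 0 <= c2 < ncols):
                    continue
                lon2, lat2 = surface.cell_center(r2, c2)
                dist = _haversine_km(lon1, lat1, lon2, lat2)
                w = dist * 0.5 * (friction[r, c] + friction[r2, c2])
                src_nodes.append(node(r, c))
                dst_nodes.append(node(r2, c2))
                weights.append(w)
    n_nodes = nrows * ncols
    graph = coo_matrix(
        (weights, (src_nodes, dst_nodes)), shape=(n_nodes, n_nodes)
    )

    gsu_ids = sorted(centroids["gsu_id"])
    table = centroids.set_index("gsu_id")
    land_cells = np.argwhere(surface.mask)
    cell_of_gsu: dict[str, int] = {}
    for g in gsu_ids:
        r, c = surface.cell_of(float(table.loc[g, "lon"]), float(table.loc[g, "lat"]))
        if not surface.mask[r, c]:
            if land_cells.size == 0:
                raise InvalidParameterError("surface has no land cells")
            d2 = ((land_cells - [r, c]) ** 2).sum(axis=1)
            r, c = land_cells[np.argmin(d2)]
            logger.warning(
                "GSU %s centroid on ocean at t=%g Ma; snapped to nearest land",
                g,
                surface.time,
            )
        cell_of_gsu[g] = node(int(r), int(c))
    sources = [cell_of_gsu[g] for g in gsu_ids]
    dist = dijkstra(graph, directed=False, indices=sources)
    values = dist[:, sources]
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    if np.isinf(values).any():
        logger.warning(
            "t=%g Ma: %d GSU pairs are unreachable (infinite cost)",
            surface.time,
            int(np.isinf(values).sum() / 2),
        )
    return IsolationMatrix(
        time=surface.time, gsu_ids=gsu_ids, values=values
    )


def isolation_series(
    surfaces: list[CostSurface],
    centroids: pd.DataFrame,
    params: CostParams = CostParams(),
) -> list[IsolationMatrix]:
    """Least-cost isolation for a whole surface series.

    Surfaces with identical land/ocean masks and elevation share one
    shortest-path computation (paleo series change only at landscape
    events), so an 81-step series typically costs a handful of Dijkstra
    runs.
    """
    cache: dict[bytes, IsolationMatrix] = {}
    out = []
    for surface in surfaces:
        key = surface.mask.tobytes() + surface.elevation.tobytes()
        if key not in cache:
            cache[key] = least_cost_isolation(surface, centroids, params)
        base = cache[key]
        out.append(
            IsolationMatrix(
                time=surface.time, gsu_ids=base.gsu_ids, values=base.values
            )
        )
    return out


def hpart_two(
    response: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> tuple[float, float, float]:
    """Hierarchical partitioning of a two-predictor OLS R^2.

    Returns ``(I1, I2, R2_full)`` with I1 = [R2(x1) + R2(full) - R2(x2)]/2
    and symmetrically for I2, the average-over-orderings incremental R^2;
    the identity I1 + I2 = R2(full) holds algebraically. Collinear
    predictors degrade to an even split with a logged warning.
    """
    y = np.asarray(response, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if y.size < 4:
        raise InsufficientDataError("need at least 4 observations")
    r2_full = _multiple_r2(y, np.column_stack([x1, x2]))
    corr = np.corrcoef(x1, x2)[0, 1] if np.ptp(x1) and np.ptp(x2) else 1.0
    if not np.isfinite(corr) or abs(corr) > 1 - 1e-12:
        logger.warning("collinear predictors: splitting R^2 evenly")
        return r2_full / 2.0, r2_full / 2.0, r2_full
    r2_1 = _multiple_r2(y, x1[:, None])
    r2_2 = _multiple_r2(y, x2[:, None])
    i1 = 0.5 * (r2_1 + r2_full - r2_2)
    i2 = 0.5 * (r2_2 + r2_full - r2_1)
    assert abs((i1 + i2) - r2_full) < 1e-9
    return float(i1), float(i2), float(r2_full)


def _multiple_r2(y: np.ndarray, x: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return 0.0
    return float(1.0 - (resid**2).sum() / sst)


@dataclass
class DriverSeries:
    """Per-Ma attribution of a realm pair's divergence, with 5-Ma bins."""

    realm_pair: tuple[int, int]
    steps: pd.DataFrame  # per time step: r, i_geo, i_clim, r2_full
    bins: pd.DataFrame  # per bin: means and SEs


def _ln_offset(v: np.ndarray) -> np.ndarray:
    """ln with a small offset so zero distances stay finite."""
    positive = v[v > 0]
    delta = 1e-6 * positive.max() if positive.size else 1.0
    return np.log(v + delta)


def driver_series(
    beta: BetaMatrix,
    partition: Partition,
    realm_pair: tuple[int, int],
    iso_series: list[IsolationMatrix],
    clim_series: list[ClimateTable],
    bin_width: float = 5.0,
    standardize_climate: bool = True,
) -> DriverSeries:
    """Time-resolved attribution of one realm pair's divergence.

    At every time step (the isolation and paleoclimate series must share
    the same time grid), the cross-realm GSU pairs' ln(beta) is regressed
    on ln(isolation) and ln(climate distance); the independent R^2 of each
    predictor comes from hierarchical partitioning, and the Pearson
    correlation between the two predictors is recorded. Bins of
    ``bin_width`` Ma aggregate the per-step values as mean and SE
    (SD/sqrt(n) over the steps in the bin).
    """
    iso_times = [m.time for m in iso_series]
    clim_times = [c.time for c in clim_series]
    if iso_times != clim_times:
        raise ConsistencyError(
            f"isolation times {iso_times[:5]}... and paleoclimate times "
            f"{clim_times[:5]}... are misaligned"
        )
    p, q = realm_pair
    gsus_p = [g for g in beta.gsu_ids if partition.labels.get(g) == p]
    gsus_q = [g for g in beta.gsu_ids if partition.labels.get(g) == q]
    if len(gsus_p) < 2 or len(gsus_q) < 2:
        raise InsufficientDataError(
            f"realm pair {realm_pair}: need >= 2 GSUs per realm"
        )
    pair_idx = [
        (beta.gsu_ids.index(a), beta.gsu_ids.index(b))
        for a in gsus_p
        for b in gsus_q
    ]
    ii = np.array([i for i, _ in pair_idx])
    jj = np.array([j for _, j in pair_idx])
    y = _ln_offset(beta.values[ii, jj])

    records = []
    for iso, clim in zip(iso_series, clim_series):
        iso_v = np.array(
            [iso.value(beta.gsu_ids[i], beta.gsu_ids[j]) for i, j in pair_idx]
        )
        cd = climate_distance(clim, standardize=standardize_climate)
        clim_v = np.array(
            [cd.loc[beta.gsu_ids[i], beta.gsu_ids[j]] for i, j in pair_idx]
        )
        finite = np.isfinite(iso_v)
        x1 = _ln_offset(iso_v[finite])
        x2 = _ln_offset(clim_v[finite])
        yv = y[finite]
        if np.ptp(x1) and np.ptp(x2):
            r = float(np.corrcoef(x1, x2)[0, 1])
        else:
            r = np.nan
        i_geo, i_clim, r2_full = hpart_two(yv, x1, x2)
        records.append(
            {
                "time": iso.time,
                "pearson_r": r,
                "i_geo": i_geo,
                "i_clim": i_clim,
                "r2_full": r2_full,
                "n_pairs": int(finite.sum()),
            }
        )
    steps = pd.DataFrame(records).sort_values("time").reset_index(drop=True)
    steps["bin"] = (steps["time"] // bin_width) * bin_width
    agg = steps.groupby("bin").agg(
        i_geo_mean=("i_geo", "mean"),
        i_geo_se=("i_geo", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
        i_clim_mean=("i_clim", "mean"),
        i_clim_se=("i_clim", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
        r2_full_mean=("r2_full", "mean"),
        n_steps=("i_geo", "size"),
    )
    return DriverSeries(
        realm_pair=(p, q), steps=steps.drop(columns="bin"), bins=agg.reset_index()
    )
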