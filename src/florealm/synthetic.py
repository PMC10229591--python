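"""Synthetic worlds with planted floristic realms.

The generator produces the statistical structure the analysis stages assume,
with known ground truth at every stage:

* a lattice of GSUs partitioned into contiguous rectangular realm blocks;
* a dated phylogeny whose oldest disjoint clades are each tied to one realm,
  diverging at planted split times (Ma);
* a binary genus x GSU matrix where each genus occupies GSUs of its clade's
  home realm with probability ``affinity`` and any foreign GSU with
  probability ``leakage`` (so between-realm turnover is high and
  within-realm turnover low);
* contemporary climate mixing a latitudinal gradient with realm-mean
  offsets;
* per-Ma paleo-landscape rasters in which an ocean strip opens between two
  realm blocks once their planted split time has passed, so least-cost
  geographic isolation increases after the split, plus per-GSU paleoclimate
  series that can optionally carry a realm signal.

No attempt is made to simulate continental drift, speciation geography or
niche evolution; the target is the block structure, chronology and driver
signals that the downstream stages are built to recover. All randomness
derives from one master seed through named substreams, so each stage is
individually reproducible.
"""

from __future__ import annotations

import math
import random
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .containers import ClimateTable, CostSurface, OccurrenceMatrix
from .errors import GenerationError, InvalidParameterError
from .tree import DatedTree

__all__ = [
    "WorldTruth",
    "SyntheticWorld",
    "gen_tree",
    "gen_world",
    "gen_ranges",
    "gen_climate",
    "gen_paleo",
    "simulate_world",
]

_SUBSTREAMS = {"tree": 1, "ranges": 2, "climate": 3, "paleo": 4}
KM_PER_DEG = 111.195  # great-circle km per degree at the equator


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _SUBSTREAMS[name]])
    )


@dataclass
class WorldTruth:
    """Planted parameters of a synthetic world."""

    grid_dims: tuple[int, int]
    realm_of_gsu: dict[str, int]
    split_times: dict[tuple[int, int], float] = field(default_factory=dict)
    affinity: float = 0.8
    leakage: float = 0.02
    seed: int = 0
    crown_age: float | None = None

    def __post_init__(self):
        if not 0 <= self.leakage < self.affinity <= 1:
            raise InvalidParameterError(
                "need 0 <= leakage < affinity <= 1, got "
                f"leakage={self.leakage}, affinity={self.affinity}"
            )
        for pair, t in self.split_times.items():
            if t <= 0:
                raise InvalidParameterError(f"split time {pair} not positive")
            if self.crown_age is not None and t > self.crown_age + 1e-9:
                raise InvalidParameterError(
                    f"split time {t} exceeds crown age {self.crown_age}"
                )

    @property
    def n_realms(self) -> int:
        return len(set(self.realm_of_gsu.values()))

    def split_time(self, p: int, q: int) -> float:
        return self.split_times[tuple(sorted((p, q)))]

    def realm_partition(self):
        from .containers import Partition

        return Partition(dict(self.realm_of_gsu))


def gen_tree(
    n_tips: int,
    crown_age: float,
    birth_rate: float = 0.1,
    death_rate: float = 0.0,
    seed: int = 0,
) -> DatedTree:
    """Simulate a birth-death tree and rescale its crown to ``crown_age`` Ma.

    Tips are labelled ``t0001``... in a deterministic traversal order; the
    same seed yields a byte-identical newick string.
    """
    if n_tips < 2:
        raise InvalidParameterError("a tree needs at least 2 tips")
    if crown_age <= 0:
        raise InvalidParameterError("crown age must be positive")
    if birth_rate <= death_rate or birth_rate <= 0 or death_rate < 0:
        raise InvalidParameterError(
            "need birth_rate > death_rate >= 0 and birth_rate > 0"
        )
    if n_tips == 2:
        # the process starts with two lineages, so the simulated waiting
        # time is zero; the rescaled shape is fully determined
        return DatedTree.from_newick(
            f"(t0001:{crown_age:.10g},t0002:{crown_age:.10g});"
        )
    from dendropy.model import birthdeath

    rng = random.Random(int(seed))
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=rng,
        is_retain_extinct_tips=False,
        repeat_until_success=True,
    )
    tree.seed_node.edge.length = None  # drop any stem on the root
    # deterministic tip labels in leaf-iteration order
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i:04d}"
    _rescale_to_depth(tree, crown_age)
    return DatedTree(tree)


def _rescale_to_depth(tree: dendropy.Tree, depth: float) -> None:
    """Rescale all edges so the maximum root-to-tip distance equals depth."""
    dmax = 0.0
    tree.seed_node._d = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node._d = node.parent_node._d + (node.edge.length or 0.0)
            if node.is_leaf():
                dmax = max(dmax, node._d)
    if dmax <= 0:
        raise GenerationError("degenerate simulated tree of zero depth")
    factor = depth / dmax
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    # pin tips exactly to the present to keep the tree ultrametric to 1e-9
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node._d = node.parent_node._d + edge_len(node)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = max(leaf.edge.length + depth - leaf._d, 0.0)


def edge_len(node) -> float:
    return node.edge.length or 0.0


def _block_grid(rows: int, cols: int, n_realms: int) -> tuple[int, int]:
    """Factor n_realms into (block_rows, block_cols) matching the lattice."""
    best = None
    for br in range(1, n_realms + 1):
        if n_realms % br:
            continue
        bc = n_realms // br
        if br > rows or bc > cols:
            continue
        aspect = abs(math.log((rows / br) / max(cols / bc, 1e-9)))
        if best is None or aspect < best[0]:
            best = (aspect, br, bc)
    if best is None:
        raise InvalidParameterError(
            f"cannot tile a {rows}x{cols} lattice with {n_realms} realms"
        )
    return best[1], best[2]


def _bands(
    total: int, parts: int, weights: list[float] | None = None
) -> list[tuple[int, int]]:
    """Split range(total) into contiguous [start, stop) bands.

    Without weights the bands are near-equal; with weights they are
    proportional (largest-remainder rounding, at least 1 each).
    """
    if weights is None:
        sizes = [
            total // parts + (1 if i < total % parts else 0)
            for i in range(parts)
        ]
    else:
        if len(weights) != parts or any(w <= 0 for w in weights):
            raise InvalidParameterError(
                f"need {parts} positive weights, got {weights}"
            )
        wsum = float(sum(weights))
        raw = [total * w / wsum for w in weights]
        sizes = [max(1, math.floor(r)) for r in raw]
        rema = sorted(
            range(parts), key=lambda i: raw[i] - math.floor(raw[i]), reverse=True
        )
        j = 0
        while sum(sizes) < total:
            sizes[rema[j % parts]] += 1
            j += 1
        while sum(sizes) > total:
            big = max(range(parts), key=lambda i: sizes[i])
            if sizes[big] <= 1:
                raise InvalidParameterError("weights incompatible with grid")
            sizes[big] -= 1
    out, start = [], 0
    for s in sizes:
        out.append((start, start + s))
        start += s
    return out


def gsu_id(row: int, col: int) -> str:
    return f"gsu{row:02d}x{col:02d}"


def gen_world(
    grid_dims: tuple[int, int],
    n_realms: int,
    seed: int = 0,
    affinity: float = 0.8,
    leakage: float = 0.02,
    cell_deg: float = 4.0,
    realm_weights: list[float] | None = None,
) -> tuple[WorldTruth, pd.DataFrame]:
    """Partition a GSU lattice into contiguous rectangular realm blocks.

    Returns the planted truth and a GSU table with ids, centroid lon/lat
    (degrees; lattice centered on the equator, ``cell_deg`` per GSU) and an
    approximate cell area in km^2. ``realm_weights`` makes realm areas
    proportional instead of equal; it requires the realms to tile the
    lattice as parallel bands (a one-dimensional block grid).
    """
    rows, cols = grid_dims
    if rows < 1 or cols < 1:
        raise InvalidParameterError("grid dimensions must be positive")
    if not 1 <= n_realms <= rows * cols:
        raise InvalidParameterError(
            f"n_realms={n_realms} must be in 1..{rows * cols}"
        )
    br, bc = _block_grid(rows, cols, n_realms)
    if realm_weights is not None:
        if bc == n_realms:
            row_bands = _bands(rows, br)
            col_bands = _bands(cols, bc, realm_weights)
        elif br == n_realms:
            row_bands = _bands(rows, br, realm_weights)
            col_bands = _bands(cols, bc)
        else:
            raise InvalidParameterError(
                "realm_weights need a band layout (n_realms blocks in a row "
                f"or column); got a {br}x{bc} block grid"
            )
    else:
        row_bands = _bands(rows, br)
        col_bands = _bands(cols, bc)
    realm_of: dict[str, int] = {}
    records = []
    lat0 = rows * cell_deg / 2.0  # top (north) edge
    for r in range(rows):
        for c in range(cols):
            rb = next(i for i, (a, b) in enumerate(row_bands) if a <= r < b)
            cb = next(i for i, (a, b) in enumerate(col_bands) if a <= c < b)
            realm = rb * bc + cb + 1
            gid = gsu_id(r, c)
            realm_of[gid] = realm
            lon = (c + 0.5) * cell_deg
            lat = lat0 - (r + 0.5) * cell_deg
            area = (KM_PER_DEG * cell_deg) ** 2 * math.cos(math.radians(lat))
            records.append(
                {
                    "gsu_id": gid,
                    "lon": lon,
                    "lat": lat,
                    "area_km2": round(area, 1),
                    "true_realm": realm,
                }
            )
    table = (
        pd.DataFrame(records).sort_values("gsu_id").reset_index(drop=True)
    )
    truth = WorldTruth(
        grid_dims=(rows, cols),
        realm_of_gsu=realm_of,
        affinity=affinity,
        leakage=leakage,
        seed=int(seed),
    )
    return truth, table


def _oldest_disjoint_clade_nodes(tree: DatedTree, k: int) -> list:
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    clades = [tree.dendropy_tree.seed_node]
    while len(clades) < k:
        splittable = [c for c in clades if not c.is_leaf()]
        if not splittable:
            raise InvalidParameterError(
                f"tree has fewer than {k} disjoint clades"
            )
        oldest = max(splittable, key=lambda n: (n.florealm_age))
        clades.remove(oldest)
        clades.extend(oldest.child_nodes())
        if len(clades) > k:
            raise InvalidParameterError(
                "polytomy prevents an exact k-clade decomposition"
            )
    return clades


def oldest_disjoint_clades(tree: DatedTree, k: int) -> list[list[str]]:
    """Tip sets of the k oldest disjoint clades (split the oldest repeatedly)."""
    return [
        tree.clade_tip_labels(c) for c in _oldest_disjoint_clade_nodes(tree, k)
    ]


def _assign_patches(
    tree: DatedTree,
    clade_root,
    rect: tuple[int, int, int, int],
    rng: np.random.Generator,
    patch_frac: float,
) -> dict[str, tuple[int, int, int, int]]:
    """Nested contiguous range patches for every tip of one realm clade.

    ``rect`` is (row0, row1, col0, col1), half-open, in lattice coordinates.
    Each child inherits a sub-rectangle covering ``patch_frac`` of the
    parent's longer axis, the two children anchored at opposite ends (which
    end is drawn at random), so sister lineages diverge spatially while
    still overlapping. This is what gives within-realm turnover at every
    phylogenetic depth, and hence recoverable sub-realms.
    """
    tip_patch: dict[str, tuple[int, int, int, int]] = {}
    stack = [(clade_root, rect)]
    while stack:
        node, (r0, r1, c0, c1) = stack.pop()
        if node.is_leaf():
            tip_patch[node.taxon.label] = (r0, r1, c0, c1)
            continue
        children = node.child_nodes()
        flip = bool(rng.integers(0, 2))
        for i, child in enumerate(children):
            if (r1 - r0) >= (c1 - c0):
                span = r1 - r0
                size = max(min(2, span), math.floor(patch_frac * span))
                low = (i % 2 == 0) != flip
                crect = (
                    (r0, r0 + size, c0, c1)
                    if low
                    else (r1 - size, r1, c0, c1)
                )
            else:
                span = c1 - c0
                size = max(min(2, span), math.floor(patch_frac * span))
                low = (i % 2 == 0) != flip
                crect = (
                    (r0, r1, c0, c0 + size)
                    if low
                    else (r0, r1, c1 - size, c1)
                )
            stack.append((child, crect))
    return tip_patch


_GSU_RE = re.compile(r"gsu(\d+)x(\d+)$")


def _gsu_rowcol(gid: str) -> tuple[int, int]:
    m = _GSU_RE.match(gid)
    if not m:
        raise InvalidParameterError(f"cannot parse lattice GSU id {gid!r}")
    return int(m.group(1)), int(m.group(2))


def gen_ranges(
    tree: DatedTree,
    world: WorldTruth,
    patch_frac: float = 1.0,
    max_gsu_retries: int = 100,
    leakage_mode: str = "uniform",
    decay_scale: float = 2.0,
    clim_field: pd.DataFrame | None = None,
    clim_sigma: float = 1.0,
) -> OccurrenceMatrix:
    """Sample the planted genus x GSU presence matrix.

    The ``n_realms`` oldest disjoint clades are mapped to realms: clades in
    tip-count-balanced order (largest first, ties by smallest tip label)
    onto realms by decreasing GSU count (ties by label). Within each realm,
    descendant clades inherit nested contiguous range patches (each child a
    ``patch_frac`` sub-rectangle of its parent's patch, sisters anchored at
    opposite ends), so assemblage composition varies inside realms at every
    phylogenetic depth. Each tip then occurs in each GSU of its own patch
    with probability ``affinity`` and in every other GSU with probability at
    most ``leakage``. ``patch_frac=1`` disables the within-realm structure.

    ``leakage_mode`` shapes how occupancy decays beyond the home patch:
    ``'uniform'`` (flat ``leakage`` everywhere), ``'distance'``
    (``leakage * exp(-d/decay_scale)`` with d the lattice distance to the
    patch, planting a distance decay of similarity that geographic
    isolation can explain), or ``'climate'`` (decay with z-scored climate
    distance from the home patch over ``clim_field``, planting a
    climate-matched turnover instead).

    Empty genera are redrawn until occupied; an empty GSU has its column
    redrawn up to ``max_gsu_retries`` times before a
    :class:`GenerationError`.
    """
    if leakage_mode not in ("uniform", "distance", "climate"):
        raise InvalidParameterError(f"unknown leakage_mode {leakage_mode!r}")
    if leakage_mode == "climate" and clim_field is None:
        raise InvalidParameterError("climate leakage mode needs clim_field")
    if not 0 < patch_frac <= 1:
        raise InvalidParameterError("patch_frac must be in (0, 1]")
    rng = _substream(world.seed, "ranges")
    k = world.n_realms
    clade_nodes = _oldest_disjoint_clade_nodes(tree, k)
    clade_nodes = sorted(
        clade_nodes,
        key=lambda n: (
            -len(tree.clade_tip_labels(n)),
            min(tree.clade_tip_labels(n)),
        ),
    )
    realm_sizes: dict[int, int] = {}
    for realm in world.realm_of_gsu.values():
        realm_sizes[realm] = realm_sizes.get(realm, 0) + 1
    realms = sorted(realm_sizes, key=lambda r: (-realm_sizes[r], r))

    gsu_ids = sorted(world.realm_of_gsu)
    rowcol = {g: _gsu_rowcol(g) for g in gsu_ids}
    realm_rect: dict[int, tuple[int, int, int, int]] = {}
    for g, realm in world.realm_of_gsu.items():
        r, c = rowcol[g]
        r0, r1, c0, c1 = realm_rect.get(realm, (r, r + 1, c, c + 1))
        realm_rect[realm] = (
            min(r0, r),
            max(r1, r + 1),
            min(c0, c),
            max(c1, c + 1),
        )

    tip_patch: dict[str, tuple[int, int, int, int]] = {}
    for node, realm in zip(clade_nodes, realms):
        tip_patch.update(
            _assign_patches(tree, node, realm_rect[realm], rng, patch_frac)
        )

    genus_ids = tree.tip_labels
    rows_arr = np.asarray([rowcol[g][0] for g in gsu_ids])
    cols_arr = np.asarray([rowcol[g][1] for g in gsu_ids])
    home = np.zeros((len(genus_ids), len(gsu_ids)), dtype=bool)
    foreign = np.full((len(genus_ids), len(gsu_ids)), world.leakage)
    if leakage_mode == "climate":
        field = clim_field.loc[gsu_ids, ["mat_c", "map_mm"]].to_numpy(float)
        sd = field.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        zfield = (field - field.mean(axis=0)) / sd
    for i, genus in enumerate(genus_ids):
        r0, r1, c0, c1 = tip_patch[genus]
        inside = (
            (rows_arr >= r0) & (rows_arr < r1)
            & (cols_arr >= c0) & (cols_arr < c1)
        )
        home[i] = inside
        if leakage_mode == "distance":
            dr = np.maximum(np.maximum(r0 - rows_arr, rows_arr - (r1 - 1)), 0)
            dc = np.maximum(np.maximum(c0 - cols_arr, cols_arr - (c1 - 1)), 0)
            d = np.hypot(dr, dc)
            foreign[i] = world.leakage * np.exp(-d / decay_scale)
        elif leakage_mode == "climate":
            home_val = zfield[inside].mean(axis=0)
            d = np.linalg.norm(zfield - home_val, axis=1)
            foreign[i] = world.leakage * np.exp(-d / clim_sigma)
    prob = np.where(home, world.affinity, foreign)
    data = rng.random(prob.shape) < prob

    for _ in range(max_gsu_retries):
        empty_rows = np.nonzero(~data.any(axis=1))[0]
        for i in empty_rows:
            while not data[i].any():  # terminates a.s.: affinity > 0
                data[i] = rng.random(prob.shape[1]) < prob[i]
        empty_cols = np.nonzero(~data.any(axis=0))[0]
        if empty_cols.size == 0:
            break
        for j in empty_cols:
            data[:, j] = rng.random(prob.shape[0]) < prob[:, j]
    else:
        raise GenerationError(
            "could not populate every GSU; affinity too low for this world"
        )
    return OccurrenceMatrix(genus_ids, gsu_ids, data)


def gen_climate(
    world: WorldTruth,
    gsu_table: pd.DataFrame,
    gradient_align: float = 0.5,
    noise_sd: float = 0.5,
    seed: int | None = None,
) -> ClimateTable:
    """Contemporary climate: latitudinal gradient mixed with realm offsets.

    ``gradient_align`` in [0, 1] is the weight of the realm-mean offsets:
    0 gives a pure latitude-driven climate, 1 a climate constant within each
    realm. Gaussian noise with ``noise_sd`` (in units of one within-grid
    standard deviation of each variable) is added on top.
    """
    if not 0 <= gradient_align <= 1:
        raise InvalidParameterError("gradient_align must be in [0, 1]")
    rng = _substream(world.seed if seed is None else seed, "climate")
    table = gsu_table.set_index("gsu_id").sort_index()
    lat = table["lat"].to_numpy(dtype=float)
    realm = np.asarray([world.realm_of_gsu[g] for g in table.index])
    # gradient: warm/wet equator, cold/dry poles
    grad_mat = 28.0 - 0.65 * np.abs(lat)
    grad_map = 2600.0 - 35.0 * np.abs(lat)
    offsets_mat = {
        r: rng.normal(0.0, 12.0) for r in sorted(set(realm.tolist()))
    }
    offsets_map = {
        r: rng.normal(0.0, 900.0) for r in sorted(set(realm.tolist()))
    }
    mat = (1 - gradient_align) * grad_mat + gradient_align * (
        15.0 + np.asarray([offsets_mat[r] for r in realm])
    )
    mapp = (1 - gradient_align) * grad_map + gradient_align * (
        1500.0 + np.asarray([offsets_map[r] for r in realm])
    )
    if noise_sd > 0:
        mat = mat + rng.normal(0.0, noise_sd * max(grad_mat.std(), 1.0), mat.shape)
        mapp = mapp + rng.normal(
            0.0, noise_sd * max(grad_map.std(), 1.0), mapp.shape
        )
    mapp = np.maximum(mapp, 0.0)
    frame = pd.DataFrame(
        {"mat_c": mat, "map_mm": mapp}, index=table.index
    )
    return ClimateTable(frame=frame, time=0.0)


CELLS_PER_GSU = 4  # 1-degree raster cells per 4-degree GSU edge


def gen_paleo(
    world: WorldTruth,
    gsu_table: pd.DataFrame,
    times: list[float],
    seed: int | None = None,
    geo_split_times: dict[tuple[int, int], float] | None = None,
    clim_split_times: dict[tuple[int, int], float] | None = None,
    clim_noise_sd: float = 0.2,
    hill_sd_m: float = 200.0,
    realm_offsets: tuple[dict[int, float], dict[int, float]] | None = None,
    micro: pd.DataFrame | None = None,
) -> tuple[list[CostSurface], list[ClimateTable]]:
    """Paleo-landscape rasters and paleoclimate series on a 1-Ma-style grid.

    ``times`` is ascending from 0 (Ma before present). For each realm pair
    with geographic split time ``s``, a one-cell ocean strip is carved along
    their shared block boundary at every time ``t < s`` (after the split);
    at ``t >= s`` the strip is land, so the two blocks form one landmass and
    least-cost isolation between their GSUs rises once the split has
    happened. Elevation is a fixed random hill field, constant through time,
    so isolation changes come from the ocean alone.

    Paleoclimate defaults to the latitudinal gradient plus noise (no realm
    signal). With ``clim_split_times``, realm climate offsets switch on for
    times younger than each realm's split, planting a climate-driven
    divergence signal instead.
    """
    times = sorted(float(t) for t in times)
    if not times:
        raise InvalidParameterError("need at least one time step")
    if times[0] < 0:
        raise InvalidParameterError("times must be >= 0 Ma")
    if geo_split_times is None:
        geo_split_times = dict(world.split_times)
    for pair, s in {**geo_split_times, **(clim_split_times or {})}.items():
        if not times[0] <= s <= times[-1]:
            raise InvalidParameterError(
                f"split time {s} for realm pair {pair} outside the "
                f"time window [{times[0]}, {times[-1]}]"
            )
    rows, cols = world.grid_dims
    cpg = CELLS_PER_GSU
    nrows, ncols = rows * cpg, cols * cpg
    rng = _substream(world.seed if seed is None else seed, "paleo")
    elevation = np.clip(rng.normal(300.0, hill_sd_m, (nrows, ncols)), 0.0, None)

    table = gsu_table.set_index("gsu_id").sort_index()
    cell_deg = 4.0
    xll = 0.0
    yll = 0.0  # lattice spans [0, rows*cell] in lat offsets; see gen_world
    lat_top = rows * cell_deg / 2.0
    yll = lat_top - rows * cell_deg

    realm_grid = np.empty((rows, cols), dtype=int)
    for r in range(rows):
        for c in range(cols):
            realm_grid[r, c] = world.realm_of_gsu[gsu_id(r, c)]

    def strip_cells(t: float) -> np.ndarray:
        ocean = np.zeros((nrows, ncols), dtype=bool)
        for r in range(rows):
            for c in range(cols):
                p = realm_grid[r, c]
                if c + 1 < cols and realm_grid[r, c + 1] != p:
                    s = geo_split_times.get(
                        tuple(sorted((p, realm_grid[r, c + 1])))
                    )
                    if s is not None and t < s:
                        col = c * cpg + cpg - 1  # east edge of west GSU
                        ocean[r * cpg : (r + 1) * cpg, col] = True
                if r + 1 < rows and realm_grid[r + 1, c] != p:
                    s = geo_split_times.get(
                        tuple(sorted((p, realm_grid[r + 1, c])))
                    )
                    if s is not None and t < s:
                        rw = r * cpg + cpg - 1  # south edge of north GSU
                        ocean[rw, c * cpg : (c + 1) * cpg] = True
        return ocean

    surfaces = []
    for t in times:
        ocean = strip_cells(t)
        mask = ~ocean
        elev = np.where(mask, elevation, 0.0)
        surfaces.append(
            CostSurface(
                time=t,
                mask=mask,
                elevation=elev,
                cellsize=cell_deg / cpg,
                xllcorner=xll,
                yllcorner=yll,
            )
        )

    lat = table["lat"].to_numpy(dtype=float)
    realm = np.asarray([world.realm_of_gsu[g] for g in table.index])
    grad_mat = 28.0 - 0.65 * np.abs(lat)
    grad_map = 2600.0 - 35.0 * np.abs(lat)
    realm_list = sorted(set(realm.tolist()))
    if realm_offsets is None:
        off_mat = {r: rng.normal(0.0, 12.0) for r in realm_list}
        off_map = {r: rng.normal(0.0, 900.0) for r in realm_list}
    else:
        off_mat, off_map = realm_offsets
    if micro is None:
        micro_mat = np.zeros(len(table))
        micro_map = np.zeros(len(table))
    else:
        micro_mat = micro.loc[table.index, "mat_c"].to_numpy(float)
        micro_map = micro.loc[table.index, "map_mm"].to_numpy(float)
    clim_birth: dict[int, float | None] = {r: None for r in realm_list}
    if clim_split_times:
        for (p, q), s in clim_split_times.items():
            for r in (p, q):
                if clim_birth[r] is None or s > clim_birth[r]:
                    clim_birth[r] = s
    paleoclim = []
    for t in times:
        # a realm's climate offset switches on once its lineage has split
        active = np.asarray(
            [clim_birth[r] is not None and t < clim_birth[r] for r in realm]
        )
        mat = (
            grad_mat
            + np.where(active, [off_mat[r] for r in realm], 0.0)
            + micro_mat
        )
        mapp = (
            grad_map
            + np.where(active, [off_map[r] for r in realm], 0.0)
            + micro_map
        )
        if clim_noise_sd > 0:
            mat = mat + rng.normal(
                0, clim_noise_sd * max(grad_mat.std(), 1.0), mat.shape
            )
            mapp = mapp + rng.normal(
                0, clim_noise_sd * max(grad_map.std(), 1.0), mapp.shape
            )
        frame = pd.DataFrame(
            {"mat_c": mat, "map_mm": np.maximum(mapp, 0.0)},
            index=table.index,
        )
        paleoclim.append(ClimateTable(frame=frame, time=t))
    return surfaces, paleoclim


def _realm_split_events(
    n_realms: int, split_ages: list[float]
) -> list[tuple[float, tuple[int, ...], tuple[int, ...]]]:
    """Top-down split schedule: at each age the largest group splits in two."""
    if len(split_ages) != n_realms - 1:
        raise InvalidParameterError(
            f"{n_realms} realms need {n_realms - 1} split times, "
            f"got {len(split_ages)}"
        )
    ages = sorted((float(a) for a in split_ages), reverse=True)
    if any(a <= 0 for a in ages):
        raise InvalidParameterError("split times must be positive")
    groups: list[tuple[int, ...]] = [tuple(range(1, n_realms + 1))]
    events = []
    for age in ages:
        groups.sort(key=lambda g: (-len(g), g))
        big = groups.pop(0)
        if len(big) < 2:
            raise InvalidParameterError("more split times than realm pairs")
        half = (len(big) + 1) // 2
        g1, g2 = big[:half], big[half:]
        events.append((age, g1, g2))
        groups.extend([g1, g2])
    return events


def _early_burst(tree: DatedTree, kappa: float) -> DatedTree:
    """Compress internal node ages toward the crown (adaptive-radiation shape).

    Each internal age a is remapped to crown * (a / crown)**kappa; kappa < 1
    concentrates divergences near the crown, which fattens terminal branches
    and so strengthens tip-level turnover relative to shared deep history.
    Tips stay at the present; the transform is monotone, so the tree remains
    a valid ultrametric.
    """
    if kappa == 1.0:
        return tree
    crown = tree.crown_age
    dtree = tree.dendropy_tree
    new_age = {}
    for node in dtree.preorder_node_iter():
        age = 0.0 if node.is_leaf() else node.florealm_age
        new_age[id(node)] = (
            0.0 if node.is_leaf() else crown * (age / crown) ** kappa
        )
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (
                new_age[id(node.parent_node)] - new_age[id(node)]
            )
    return DatedTree(dtree)


def _structured_tree(
    n_tips: int,
    n_realms: int,
    split_ages: list[float],
    seed: int,
    birth_rate: float = 0.2,
    subtree_depth_frac: float = 0.8,
    radiation_kappa: float = 0.2,
) -> tuple[DatedTree, dict[tuple[int, int], float]]:
    """A dated tree whose oldest clades diverge at the planted realm splits."""
    events = _realm_split_events(n_realms, split_ages)
    pair_times: dict[tuple[int, int], float] = {}
    birth_age = {tuple(range(1, n_realms + 1)): events[0][0]}
    for age, g1, g2 in events:
        for p in g1:
            for q in g2:
                pair_times[tuple(sorted((p, q)))] = age
        birth_age[g1] = age
        birth_age[g2] = age
    children = {}
    for age, g1, g2 in events:
        children[tuple(sorted(g1 + g2))] = (age, g1, g2)

    sizes = [
        n_tips // n_realms + (1 if i < n_tips % n_realms else 0)
        for i in range(n_realms)
    ]
    # realm crowns sit below the youngest backbone event, so the oldest
    # disjoint clades of the finished tree are exactly the realm clades
    crown_all = subtree_depth_frac * min(float(a) for a in split_ages)

    def subtree_newick(realm: int, stem_from_age: float) -> str:
        n_r = sizes[realm - 1]
        crown = min(crown_all, subtree_depth_frac * stem_from_age)
        if n_r == 1:
            return f"r{realm:02d}t001:{stem_from_age:.10g}"
        sub = gen_tree(
            n_r, crown, birth_rate=birth_rate, seed=int(seed) * 1000 + realm
        )
        sub = _early_burst(sub, radiation_kappa)
        nwk = sub.to_newick().strip().rstrip(";")
        if nwk.startswith("[&R]"):
            nwk = nwk[4:].strip()
        for i in range(n_r, 0, -1):
            nwk = nwk.replace(f"t{i:04d}", f"r{realm:02d}t{i:03d}")
        stem = stem_from_age - crown
        return f"{nwk.strip()}:{stem:.10g}"

    def emit(group: tuple[int, ...]) -> tuple[str, float]:
        """newick (without stem) and the age of this node."""
        if len(group) == 1:
            raise AssertionError("leaves handled by caller")
        age, g1, g2 = children[tuple(sorted(group))]
        parts = []
        for g in (g1, g2):
            if len(g) == 1:
                parts.append(subtree_newick(g[0], age))
            else:
                nwk, child_age = emit(g)
                parts.append(f"{nwk}:{age - child_age:.10g}")
        return f"({parts[0]},{parts[1]})", age

    nwk, root_age = emit(tuple(range(1, n_realms + 1)))
    tree = DatedTree.from_newick(nwk + ";")
    return tree, pair_times


@dataclass
class SyntheticWorld:
    """Bundle of one synthetic world's truth and generated data."""

    truth: WorldTruth
    gsu_table: pd.DataFrame
    tree: DatedTree
    occurrences: OccurrenceMatrix
    climate: ClimateTable
    surfaces: list[CostSurface] = field(default_factory=list)
    paleoclimate: list[ClimateTable] = field(default_factory=list)


def simulate_world(
    grid_dims: tuple[int, int] = (6, 6),
    n_realms: int = 4,
    n_tips: int = 200,
    realm_split_times: list[float] | None = None,
    affinity: float = 0.8,
    leakage: float = 0.02,
    gradient_align: float = 0.5,
    climate_noise_sd: float = 0.5,
    seed: int = 0,
    paleo_times: list[float] | None = None,
    climate_driven: bool = False,
    patch_frac: float = 1.0,
    subtree_depth_frac: float = 0.8,
    realm_weights: list[float] | None = None,
) -> SyntheticWorld:
    """Generate a complete synthetic world with planted realm structure.

    Defaults plant four realms on a 6x6 GSU lattice with 200 genera,
    realm divergences at 60 and 30 Ma (crown age 60 Ma), occupancy
    affinity 0.8 and leakage 0.02. With ``paleo_times`` given (ascending
    from 0), paleo-landscapes and paleoclimate are generated too; by
    default isolation carries the divergence signal (ocean strips opening
    at the planted splits) while paleoclimate is realm-blind. With
    ``climate_driven=True`` the roles are swapped: the landmass stays
    connected and the realm signal moves into paleoclimate.
    """
    if realm_split_times is None:
        base = [60.0, 30.0, 30.0]
        if n_realms - 1 <= len(base):
            realm_split_times = base[: n_realms - 1]
        else:
            realm_split_times = [
                60.0 * (1 - i / (n_realms - 1)) + 5.0
                for i in range(n_realms - 1)
            ]
    truth, gsu_table = gen_world(
        grid_dims,
        n_realms,
        seed=seed,
        affinity=affinity,
        leakage=leakage,
        realm_weights=realm_weights,
    )
    if n_realms >= 2:
        tree, pair_times = _structured_tree(
            n_tips,
            n_realms,
            realm_split_times,
            seed=seed,
            subtree_depth_frac=subtree_depth_frac,
        )
        truth.split_times = pair_times
        truth.crown_age = tree.crown_age
    else:
        tree = gen_tree(n_tips, crown_age=60.0, seed=seed)
        truth.crown_age = tree.crown_age
    # shared climate pieces so the leak field and the paleoclimate series
    # describe the same world
    rngc = _substream(seed, "climate")
    realm_list = sorted(set(truth.realm_of_gsu.values()))
    off_mat = {r: rngc.normal(0.0, 12.0) for r in realm_list}
    off_map = {r: rngc.normal(0.0, 900.0) for r in realm_list}
    gsu_sorted = sorted(truth.realm_of_gsu)
    micro = pd.DataFrame(
        {
            "mat_c": rngc.normal(0.0, 6.0, len(gsu_sorted)),
            "map_mm": rngc.normal(0.0, 450.0, len(gsu_sorted)),
        },
        index=pd.Index(gsu_sorted, name="gsu_id"),
    )

    if paleo_times is not None and climate_driven:
        realm_arr = [truth.realm_of_gsu[g] for g in gsu_sorted]
        clim_field = pd.DataFrame(
            {
                "mat_c": [off_mat[r] for r in realm_arr]
                + micro["mat_c"].to_numpy(),
                "map_mm": [off_map[r] for r in realm_arr]
                + micro["map_mm"].to_numpy(),
            },
            index=micro.index,
        )
        occ = gen_ranges(
            tree,
            truth,
            patch_frac=patch_frac,
            leakage_mode="climate",
            clim_field=clim_field,
            clim_sigma=0.75,
        )
    elif paleo_times is not None:
        occ = gen_ranges(
            tree, truth, patch_frac=patch_frac, leakage_mode="distance"
        )
    else:
        occ = gen_ranges(tree, truth, patch_frac=patch_frac)
    climate = gen_climate(
        truth,
        gsu_table,
        gradient_align=gradient_align,
        noise_sd=climate_noise_sd,
        seed=seed,
    )
    surfaces: list[CostSurface] = []
    paleoclim: list[ClimateTable] = []
    if paleo_times is not None:
        if climate_driven:
            surfaces, paleoclim = gen_paleo(
                truth,
                gsu_table,
                paleo_times,
                seed=seed,
                geo_split_times={},
                clim_split_times=dict(truth.split_times),
                realm_offsets=(off_mat, off_map),
                micro=micro,
                clim_noise_sd=0.05,
            )
        else:
            surfaces, paleoclim = gen_paleo(
                truth,
                gsu_table,
                paleo_times,
                seed=seed,
                micro=micro,
                clim_noise_sd=0.05,
            )
    return SyntheticWorld(
        truth=truth,
        gsu_table=gsu_table,
        tree=tree,
        occurrences=occ,
        climate=climate,
        surfaces=surfaces,
        paleoclimate=paleoclim,
    )
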