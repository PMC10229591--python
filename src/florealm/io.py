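"""File formats: newick trees, CSV tables, ESRI ASCII grids, GeoJSON.

Every reader is a total function over its declared format: malformed input
raises :class:`~florealm.errors.FormatError`, never a silently wrong object.
Write-then-read is the identity on the domain value for every type with
both directions. Identifier order is lexicographic throughout.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    ClimateTable,
    CostSurface,
    OccurrenceMatrix,
    Partition,
)
from .errors import ConsistencyError, FormatError
from .tree import DatedTree, read_tree, write_tree  # noqa: F401  (re-export)

logger = logging.getLogger("florealm")

__all__ = [
    "read_tree",
    "write_tree",
    "read_occurrences",
    "write_occurrences",
    "read_climate",
    "write_climate",
    "read_gsu_table",
    "write_gsu_table",
    "read_cost_surfaces",
    "write_cost_surface",
    "read_beta_matrix",
    "write_beta_matrix",
    "write_regionalization",
    "read_regionalization",
    "write_truth",
]


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(
            f"{path}: missing columns {sorted(missing)} "
            f"(found {list(frame.columns)})"
        )
    return frame


def read_occurrences(path, tree: DatedTree | None = None) -> OccurrenceMatrix:
    """Read long-format occurrences (genus_id,gsu_id) into a binary matrix.

    Duplicate records are collapsed and counted in the log; when a tree is
    supplied, genera absent from its tips are dropped (logged), mirroring the
    intersection of the phylogeny with the distribution data.
    """
    frame = _read_csv(path, {"genus_id", "gsu_id"})
    if frame.empty:
        raise FormatError(f"{path}: no occurrence records")
    n_raw = len(frame)
    frame = frame.drop_duplicates(["genus_id", "gsu_id"])
    n_dup = n_raw - len(frame)
    if n_dup:
        logger.info("collapsed %d duplicate occurrence records", n_dup)
    if tree is not None:
        tips = set(tree.tip_labels)
        keep = frame["genus_id"].isin(tips)
        n_dropped = int((~keep).sum())
        if n_dropped:
            dropped_genera = sorted(set(frame.loc[~keep, "genus_id"]))
            logger.info(
                "dropped %d records of %d genera absent from the tree",
                n_dropped,
                len(dropped_genera),
            )
            frame = frame[keep]
        if frame.empty:
            raise FormatError(
                f"{path}: no genus overlaps the supplied tree's tips"
            )
    return OccurrenceMatrix.from_pairs(
        list(zip(frame["genus_id"], frame["gsu_id"]))
    )


def write_occurrences(occ: OccurrenceMatrix, path) -> None:
    pd.DataFrame(occ.to_pairs(), columns=["genus_id", "gsu_id"]).to_csv(
        path, index=False
    )


def read_climate(path, time: float = 0.0) -> ClimateTable:
    frame = _read_csv(path, {"gsu_id", "mat_c", "map_mm"})
    try:
        out = frame.set_index("gsu_id")[["mat_c", "map_mm"]].astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric climate value: {exc}") from exc
    return ClimateTable(frame=out.sort_index(), time=time)


def write_climate(climate: ClimateTable, path) -> None:
    climate.frame.sort_index().rename_axis("gsu_id").to_csv(path)


def read_gsu_table(path) -> pd.DataFrame:
    frame = _read_csv(path, {"gsu_id", "lon", "lat"})
    for col in ("lon", "lat", "area_km2"):
        if col in frame.columns:
            frame[col] = frame[col].astype(float)
    if "true_realm" in frame.columns:
        frame["true_realm"] = frame["true_realm"].astype(int)
    return frame.sort_values("gsu_id").reset_index(drop=True)


def write_gsu_table(table: pd.DataFrame, path) -> None:
    table.sort_values("gsu_id").to_csv(path, index=False)


# -- ESRI ASCII grids ------------------------------------------------------

_PALEO_RE = re.compile(r"paleo_(\d+(?:\.\d+)?)ma_(mask|elev)\.asc$")


def _read_asc(path) -> tuple[np.ndarray, float, float, float, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 7:
        raise FormatError(f"{path}: truncated ASCII grid")
    for line in lines[:6]:
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed header line {line!r}")
        header[parts[0].lower()] = float(parts[1])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing header field {key}")
    try:
        grid = np.loadtxt(lines[6:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: bad grid values: {exc}") from exc
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(
            f"{path}: grid shape {grid.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid[grid == nodata] = np.nan
    return (
        grid,
        header["cellsize"],
        header["xllcorner"],
        header["yllcorner"],
        nodata if nodata is not None else np.nan,
    )


def _write_asc(
    grid: np.ndarray,
    cellsize: float,
    xll: float,
    yll: float,
    path,
    nodata: float = -9999.0,
) -> None:
    out = np.where(np.isfinite(grid), grid, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {xll:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_cost_surfaces(directory) -> list[CostSurface]:
    """Read paired ``paleo_<t>ma_{mask,elev}.asc`` grids, sorted by time.

    NODATA cells in the mask are treated as ocean (logged).
    """
    directory = Path(directory)
    found: dict[float, dict[str, Path]] = {}
    for path in sorted(directory.glob("*.asc")):
        m = _PALEO_RE.search(path.name)
        if not m:
            continue
        t = float(m.group(1))
        found.setdefault(t, {})[m.group(2)] = path
    if not found:
        raise FormatError(f"no paleo_<t>ma_{{mask,elev}}.asc files in {directory}")
    surfaces = []
    for t in sorted(found):
        pair = found[t]
        if set(pair) != {"mask", "elev"}:
            raise FormatError(
                f"unpaired paleo grids at t={t:g} Ma: found {sorted(pair)}"
            )
        mask_grid, cs1, xll1, yll1, _ = _read_asc(pair["mask"])
        elev_grid, cs2, xll2, yll2, _ = _read_asc(pair["elev"])
        if mask_grid.shape != elev_grid.shape:
            raise FormatError(
                f"t={t:g} Ma: mask {mask_grid.shape} and elevation "
                f"{elev_grid.shape} are not congruent"
            )
        if (cs1, xll1, yll1) != (cs2, xll2, yll2):
            raise FormatError(f"t={t:g} Ma: mask/elevation georeference differs")
        n_nodata = int(np.isnan(mask_grid).sum())
        if n_nodata:
            logger.info(
                "t=%g Ma: %d NODATA mask cells treated as ocean", t, n_nodata
            )
        mask = np.nan_to_num(mask_grid, nan=0.0) > 0.5
        elev = np.where(mask, np.nan_to_num(elev_grid, nan=0.0), 0.0)
        surfaces.append(
            CostSurface(
                time=t,
                mask=mask,
                elevation=elev,
                cellsize=cs1,
                xllcorner=xll1,
                yllcorner=yll1,
            )
        )
    return surfaces


def write_cost_surface(surface: CostSurface, directory) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = surface.time
    stamp = f"{t:g}"
    mask_path = directory / f"paleo_{stamp}ma_mask.asc"
    elev_path = directory / f"paleo_{stamp}ma_elev.asc"
    _write_asc(
        surface.mask.astype(float),
        surface.cellsize,
        surface.xllcorner,
        surface.yllcorner,
        mask_path,
    )
    _write_asc(
        surface.elevation,
        surface.cellsize,
        surface.xllcorner,
        surface.yllcorner,
        elev_path,
    )
    return mask_path, elev_path


# -- beta matrices ---------------------------------------------------------


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    frame = pd.DataFrame(
        beta.values, index=beta.gsu_ids, columns=beta.gsu_ids
    )
    frame.rename_axis("gsu_id").to_csv(path, float_format="%.12g")


def read_beta_matrix(path) -> BetaMatrix:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    if list(frame.index) != list(frame.columns):
        raise FormatError(f"{path}: row and column GSU ids differ")
    try:
        return BetaMatrix(list(frame.index), frame.to_numpy(dtype=float))
    except (ConsistencyError, ValueError) as exc:
        raise FormatError(f"{path}: not a valid beta matrix: {exc}") from exc


# -- regionalizations ------------------------------------------------------


def write_regionalization(
    realms: Partition,
    subrealms: Partition,
    gsu_table: pd.DataFrame,
    path_csv,
    path_geojson=None,
    super_realms: Partition | None = None,
    silhouette: pd.Series | None = None,
) -> None:
    """Write nested realm labels per GSU as CSV (and optional GeoJSON points).

    Raises :class:`ConsistencyError` if any GSU is unassigned at any level
    or the sub-realms do not nest within realms.
    """
    gsus = sorted(set(realms.labels))
    if set(subrealms.labels) != set(gsus):
        raise ConsistencyError("realm and sub-realm partitions cover different GSUs")
    if not subrealms.refines(realms):
        raise ConsistencyError("sub-realms do not nest within realms")
    table = gsu_table.set_index("gsu_id")
    missing = [g for g in gsus if g not in table.index]
    if missing:
        raise ConsistencyError(f"GSU table missing ids: {missing[:5]}")
    rows = []
    for g in gsus:
        rows.append(
            {
                "gsu_id": g,
                "super_realm": (
                    super_realms.labels[g] if super_realms else ""
                ),
                "realm": realms.labels[g],
                "sub_realm": subrealms.labels[g],
                "silhouette": (
                    float(silhouette[g]) if silhouette is not None else ""
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path_csv, index=False)
    if path_geojson is not None:
        features = []
        for g in gsus:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [
                            float(table.loc[g, "lon"]),
                            float(table.loc[g, "lat"]),
                        ],
                    },
                    "properties": {
                        "gsu_id": g,
                        "realm": int(realms.labels[g]),
                        "sub_realm": int(subrealms.labels[g]),
                    },
                }
            )
        with open(path_geojson, "w") as fh:
            json.dump(
                {"type": "FeatureCollection", "features": features}, fh
            )


def read_regionalization(path_csv) -> tuple[Partition, Partition]:
    frame = _read_csv(path_csv, {"gsu_id", "realm", "sub_realm"})
    realms = Partition(
        dict(zip(frame["gsu_id"], frame["realm"].astype(int)))
    )
    subrealms = Partition(
        dict(zip(frame["gsu_id"], frame["sub_realm"].astype(int)))
    )
    return realms, subrealms


def write_truth(truth, path) -> None:
    """Serialize a WorldTruth (split times, parameters, seed) as JSON."""
    payload = {
        "grid_dims": list(truth.grid_dims),
        "realm_of_gsu": truth.realm_of_gsu,
        "split_times": {
            f"{p}-{q}": t for (p, q), t in truth.split_times.items()
        },
        "affinity": truth.affinity,
        "leakage": truth.leakage,
        "seed": truth.seed,
        "crown_age": truth.crown_age,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
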