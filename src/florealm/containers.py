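"""In-memory domain containers shared by every stage.

All downstream modules operate on these types only; file formats are handled
in :mod:`florealm.io`. Identifier ordering is lexicographic everywhere so
matrix indices are deterministic across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, InvalidParameterError

__all__ = [
    "OccurrenceMatrix",
    "ClimateTable",
    "CostSurface",
    "BetaMatrix",
    "Partition",
]


class OccurrenceMatrix:
    """Binary genus x geographic-standard-unit (GSU) presence matrix.

    Invariants: no duplicate (genus, GSU) pair; every genus occupies at least
    one GSU and every GSU hosts at least one genus. Rows are genera, columns
    GSUs, both lexicographically ordered.
    """

    def __init__(self, genus_ids, gsu_ids, data: np.ndarray):
        self.genus_ids = list(genus_ids)
        self.gsu_ids = list(gsu_ids)
        self.data = np.asarray(data, dtype=bool)
        if self.data.shape != (len(self.genus_ids), len(self.gsu_ids)):
            raise ConsistencyError("occurrence matrix shape mismatch")
        if len(set(self.genus_ids)) != len(self.genus_ids):
            raise ConsistencyError("duplicate genus ids")
        if len(set(self.gsu_ids)) != len(self.gsu_ids):
            raise ConsistencyError("duplicate GSU ids")
        if self.data.size:
            empty_gen = ~self.data.any(axis=1)
            if empty_gen.any():
                bad = [g for g, e in zip(self.genus_ids, empty_gen) if e]
                raise ConsistencyError(f"genera with no occurrences: {bad[:5]}")
            empty_gsu = ~self.data.any(axis=0)
            if empty_gsu.any():
                bad = [g for g, e in zip(self.gsu_ids, empty_gsu) if e]
                raise ConsistencyError(f"GSUs with no genera: {bad[:5]}")
        self._genus_index = {g: i for i, g in enumerate(self.genus_ids)}
        self._gsu_index = {g: i for i, g in enumerate(self.gsu_ids)}

    @classmethod
    def from_pairs(cls, pairs) -> "OccurrenceMatrix":
        """Build from an iterable of (genus_id, gsu_id); duplicates collapse."""
        pairs = list(pairs)
        if not pairs:
            raise FormatError("no occurrence records")
        genus_ids = sorted({p[0] for p in pairs})
        gsu_ids = sorted({p[1] for p in pairs})
        gi = {g: i for i, g in enumerate(genus_ids)}
        si = {s: i for i, s in enumerate(gsu_ids)}
        data = np.zeros((len(genus_ids), len(gsu_ids)), dtype=bool)
        for genus, gsu in pairs:
            data[gi[genus], si[gsu]] = True
        return cls(genus_ids, gsu_ids, data)

    @property
    def n_genera(self) -> int:
        return len(self.genus_ids)

    @property
    def n_gsus(self) -> int:
        return len(self.gsu_ids)

    @property
    def n_records(self) -> int:
        return int(self.data.sum())

    def genus_index(self, genus_id: str) -> int:
        try:
            return self._genus_index[genus_id]
        except KeyError:
            raise KeyError(f"unknown genus id {genus_id!r}") from None

    def gsu_index(self, gsu_id: str) -> int:
        try:
            return self._gsu_index[gsu_id]
        except KeyError:
            raise KeyError(f"unknown GSU id {gsu_id!r}") from None

    def genus_set(self, gsu_id: str) -> set[str]:
        """Genera present in one GSU."""
        col = self.data[:, self.gsu_index(gsu_id)]
        return {g for g, p in zip(self.genus_ids, col) if p}

    def gsu_set(self, genus_id: str) -> set[str]:
        """GSUs occupied by one genus."""
        row = self.data[self.genus_index(genus_id), :]
        return {s for s, p in zip(self.gsu_ids, row) if p}

    def restrict_genera(self, keep) -> "OccurrenceMatrix":
        keep = set(keep)
        rows = [i for i, g in enumerate(self.genus_ids) if g in keep]
        sub = self.data[rows, :]
        occupied = sub.any(axis=0)
        return OccurrenceMatrix(
            [self.genus_ids[i] for i in rows],
            [s for s, o in zip(self.gsu_ids, occupied) if o],
            sub[:, occupied],
        )

    def to_pairs(self) -> list[tuple[str, str]]:
        out = []
        rows, cols = np.nonzero(self.data)
        for r, c in zip(rows, cols):
            out.append((self.genus_ids[r], self.gsu_ids[c]))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"OccurrenceMatrix({self.n_genera} genera x {self.n_gsus} GSUs, "
            f"{self.n_records} presences)"
        )


@dataclass
class ClimateTable:
    """Per-GSU climate: annual mean temperature (degC) and precipitation (mm).

    ``time`` stamps paleoclimate tables (Ma before present); contemporary
    tables carry ``time=0``.
    """

    frame: pd.DataFrame  # index gsu_id, columns mat_c, map_mm
    time: float = 0.0

    def __post_init__(self):
        required = {"mat_c", "map_mm"}
        if not required.issubset(self.frame.columns):
            raise FormatError(
                f"climate table needs columns {sorted(required)}"
            )
        if self.frame.index.has_duplicates:
            raise FormatError("duplicate GSU rows in climate table")
        if (self.frame["map_mm"] < 0).any():
            raise FormatError("negative precipitation")

    @property
    def gsu_ids(self) -> list[str]:
        return list(self.frame.index)

    def values_for(self, gsu_ids) -> np.ndarray:
        missing = [g for g in gsu_ids if g not in self.frame.index]
        if missing:
            raise ConsistencyError(f"climate missing for GSUs: {missing[:5]}")
        return self.frame.loc[list(gsu_ids), ["mat_c", "map_mm"]].to_numpy(
            dtype=float
        )


@dataclass
class CostSurface:
    """A time-stamped land/ocean + elevation raster for route-cost isolation.

    Cell (0, 0) is the NW corner; cell centers sit half a cell size in from
    the lower-left origin, following ESRI ASCII-grid header semantics.
    """

    time: float  # Ma
    mask: np.ndarray  # bool, True = land
    elevation: np.ndarray  # metres; finite on land
    cellsize: float  # degrees
    xllcorner: float
    yllcorner: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.mask.shape != self.elevation.shape:
            raise FormatError(
                f"mask {self.mask.shape} and elevation "
                f"{self.elevation.shape} grids are not congruent"
            )
        if not np.isfinite(self.elevation[self.mask]).all():
            raise FormatError("non-finite elevation on land cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center."""
        nrows = self.mask.shape[0]
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (nrows - row - 0.5) * self.cellsize
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Cell containing a point; clipped to the grid."""
        nrows, ncols = self.mask.shape
        col = int(np.clip((lon - self.xllcorner) / self.cellsize, 0, ncols - 1))
        row_from_bottom = int(
            np.clip((lat - self.yllcorner) / self.cellsize, 0, nrows - 1)
        )
        return nrows - 1 - row_from_bottom, col


class BetaMatrix:
    """Symmetric pairwise Simpson dissimilarity among GSUs.

    Values in [0, 1], zero diagonal, no missing pairs.
    """

    def __init__(self, gsu_ids, values: np.ndarray):
        self.gsu_ids = list(gsu_ids)
        values = np.asarray(values, dtype=float)
        n = len(self.gsu_ids)
        if values.shape != (n, n):
            raise ConsistencyError("beta matrix shape mismatch")
        if np.isnan(values).any():
            raise ConsistencyError("beta matrix contains missing pairs")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ConsistencyError("beta matrix not symmetric")
        if np.abs(np.diag(values)).max(initial=0.0) > 1e-12:
            raise ConsistencyError("beta matrix diagonal not zero")
        if values.min(initial=0.0) < -1e-12 or values.max(initial=0.0) > 1 + 1e-12:
            raise ConsistencyError("beta values outside [0, 1]")
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(values, 0.0)
        self.values = values
        self._index = {g: i for i, g in enumerate(self.gsu_ids)}

    @property
    def n(self) -> int:
        return len(self.gsu_ids)

    def value(self, gsu1: str, gsu2: str) -> float:
        return float(self.values[self._index[gsu1], self._index[gsu2]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, gsu_ids) -> "BetaMatrix":
        idx = [self._index[g] for g in gsu_ids]
        return BetaMatrix(list(gsu_ids), self.values[np.ix_(idx, idx)])


class Partition:
    """Total assignment of GSUs to clusters labelled 1..k (none empty)."""

    def __init__(self, labels: dict[str, int]):
        if not labels:
            raise InvalidParameterError("empty partition")
        self.labels = dict(labels)
        used = sorted(set(self.labels.values()))
        if used != list(range(1, len(used) + 1)):
            # renumber to contiguous 1..k preserving order of first appearance
            remap = {}
            for gsu in sorted(self.labels):
                lab = self.labels[gsu]
                if lab not in remap:
                    remap[lab] = len(remap) + 1
            self.labels = {g: remap[v] for g, v in self.labels.items()}
        self.k = len(set(self.labels.values()))

    @property
    def gsu_ids(self) -> list[str]:
        return sorted(self.labels)

    def label_vector(self, gsu_ids) -> np.ndarray:
        try:
            return np.asarray([self.labels[g] for g in gsu_ids], dtype=int)
        except KeyError as exc:
            raise ConsistencyError(f"partition missing GSU {exc}") from exc

    def members(self, label: int) -> list[str]:
        return sorted(g for g, v in self.labels.items() if v == label)

    def refines(self, coarser: "Partition") -> bool:
        """True iff every cluster of self maps into one cluster of coarser."""
        for lab in range(1, self.k + 1):
            parents = {coarser.labels[g] for g in self.members(lab)}
            if len(parents) > 1:
                return False
        return True

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        if set(self.labels) != set(other.labels):
            return False
        gsus = sorted(self.labels)
        a = self.label_vector(gsus)
        b = other.label_vector(gsus)
        # label-permutation invariant equality
        pairing = {}
        for x, y in zip(a, b):
            if pairing.setdefault(x, y) != y:
                return False
        return len(set(pairing.values())) == len(pairing)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Partition(k={self.k}, n={len(self.labels)})"
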