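"""Realm chronology by phylogeny time-slicing.

Cutting the dated tree at a depth t (Ma before present) collapses every
branch that spans t into a single lineage; a lineage occupies a GSU iff any
of its member tips does. Re-running the beta-diversity clustering on the
collapsed matrix, with branch lengths of the truncated tree, yields the
floristic realms "as seen" at that phylogenetic depth. Matching each
slice's clusters to the present-day realms (optimal assignment on GSU
overlap) and Procrustes-aligning the per-slice NMDS configurations to the
present one traces when each realm boundary appears.

No ancestral-range estimation is attempted: a slice describes how deep
phylogenetic structure shapes present distributions, not where lineages
lived at time t.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.optimize import linear_sum_assignment

from .beta import pairwise_beta
from .containers import OccurrenceMatrix, Partition
from .errors import ConsistencyError, InvalidParameterError
from .regionalize import build_dendrogram, cut_at_pbeta, nmds, p_beta
from .tree import DatedTree

logger = logging.getLogger("florealm")

__all__ = [
    "TimeSlice",
    "slice_tree",
    "slice_assemblages",
    "match_realms",
    "chronology_run",
    "nmds_trajectory",
    "separation_time",
]


@dataclass
class TimeSlice:
    """One phylogenetic depth of the chronology."""

    t: float
    lineages: dict[str, list[str]]  # lineage id -> member tip labels
    occurrences: OccurrenceMatrix | None
    partition: Partition
    pbeta: float
    label_map: dict[int, str] = field(default_factory=dict)
    nmds_coords: pd.DataFrame | None = None
    nmds_stress: float | None = None

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)


def slice_tree(
    tree: DatedTree, t: float
) -> tuple[dict[str, list[str]], dict[str, str], DatedTree | None]:
    """Collapse the tree at depth ``t`` Ma before present.

    Returns ``(lineages, tip_to_lineage, sliced_tree)``. A lineage is a
    branch whose age interval spans t (older end > t >= younger end, tips
    pinned to 0); its id is the id of the branch's child node, so at t=0 the
    lineages are the tips themselves and the sliced tree is the original.
    The sliced tree is the original truncated below t with lineages as tips
    (edge lengths measured on the truncated tree); it is None when fewer
    than two lineages remain.
    """
    if t < 0:
        raise InvalidParameterError("slice depth must be >= 0 Ma")
    root = tree.dendropy_tree.seed_node
    crown = tree.crown_age

    if t >= crown - 1e-9:
        # everything collapses onto the root's children
        warnings.warn(
            f"slice depth {t:g} Ma is at or beyond the crown age "
            f"{crown:g} Ma; all tips collapse onto the root's children",
            stacklevel=2,
        )
        lineages = {
            child.florealm_id: tree.clade_tip_labels(child)
            for child in root.child_nodes()
        }
        tip_to_lineage = {
            tip: lid for lid, tips in lineages.items() for tip in tips
        }
        return lineages, tip_to_lineage, None

    lineages: dict[str, list[str]] = {}
    tip_to_lineage: dict[str, str] = {}

    def emit(node) -> str:
        """Newick of the subtree above t rooted at node (no stem)."""
        young = 0.0 if node.is_leaf() else node.florealm_age
        if young <= t:  # this branch spans t: collapse
            lid = node.florealm_id
            members = tree.clade_tip_labels(node)
            lineages[lid] = members
            for tip in members:
                tip_to_lineage[tip] = lid
            return lid
        parts = ",".join(
            f"{emit(ch)}:"
            f"{young - (0.0 if ch.is_leaf() else ch.florealm_age):.17g}"
            if (0.0 if ch.is_leaf() else ch.florealm_age) > t
            else f"{emit(ch)}:{young - t:.17g}"
            for ch in node.child_nodes()
        )
        return f"({parts})"

    newick = emit(root) + ";"
    sliced = DatedTree.from_newick(newick) if len(lineages) >= 2 else None
    return lineages, tip_to_lineage, sliced


def slice_assemblages(
    occ: OccurrenceMatrix, tip_to_lineage: dict[str, str]
) -> OccurrenceMatrix:
    """Collapse the genus x GSU matrix onto lineages (presence = union)."""
    unmapped = [g for g in occ.genus_ids if g not in tip_to_lineage]
    if unmapped:
        raise ConsistencyError(
            f"genera without a lineage at this slice: {unmapped[:5]}"
        )
    lineage_ids = sorted(set(tip_to_lineage[g] for g in occ.genus_ids))
    lidx = {lid: i for i, lid in enumerate(lineage_ids)}
    data = np.zeros((len(lineage_ids), occ.n_gsus), dtype=bool)
    for row, genus in enumerate(occ.genus_ids):
        data[lidx[tip_to_lineage[genus]]] |= occ.data[row]
    return OccurrenceMatrix(lineage_ids, occ.gsu_ids, data)


def match_realms(
    slice_partition: Partition,
    present: Partition,
    ancestral_jaccard: float = 0.5,
) -> dict[int, str]:
    """Map slice cluster labels to present realm labels by optimal overlap.

    The assignment maximises total shared-GSU counts (one-to-one); a slice
    cluster whose best-match Jaccard falls below ``ancestral_jaccard``
    receives a fresh ``ancestral<i>`` label instead, as do unassigned
    clusters when the slice has more clusters than the present partition.
    """
    shared = sorted(set(slice_partition.labels) & set(present.labels))
    if not shared:
        raise ConsistencyError("partitions share no GSUs")
    s_labels = sorted(set(slice_partition.labels[g] for g in shared))
    p_labels = sorted(set(present.labels[g] for g in shared))
    overlap = np.zeros((len(s_labels), len(p_labels)))
    s_sets = {
        lab: {g for g in shared if slice_partition.labels[g] == lab}
        for lab in s_labels
    }
    p_sets = {
        lab: {g for g in shared if present.labels[g] == lab}
        for lab in p_labels
    }
    for i, sl in enumerate(s_labels):
        for j, pl in enumerate(p_labels):
            overlap[i, j] = len(s_sets[sl] & p_sets[pl])
    rows, cols = linear_sum_assignment(-overlap)
    mapping: dict[int, str] = {}
    n_anc = 0
    assigned = dict(zip(rows, cols))
    for i, sl in enumerate(s_labels):
        j = assigned.get(i)
        if j is not None:
            inter = overlap[i, j]
            union = len(s_sets[sl] | p_sets[p_labels[j]])
            if union > 0 and inter / union >= ancestral_jaccard:
                mapping[sl] = str(p_labels[j])
                continue
        n_anc += 1
        mapping[sl] = f"ancestral{n_anc}"
    return mapping


def chronology_run(
    tree: DatedTree,
    occ: OccurrenceMatrix,
    times: list[float],
    pbeta: float = 0.80,
    linkage_method: str = "average",
    seed: int = 0,
    nmds_starts: int = 8,
) -> list[TimeSlice]:
    """Slice, collapse, re-cluster and match realms at each depth.

    ``times`` must include 0; slices are returned sorted ascending (present
    first). The t=0 slice reproduces the present-day regionalization
    exactly. Slices at or beyond the crown age yield a single realm.
    """
    times = sorted(float(t) for t in times)
    if 0.0 not in times:
        raise InvalidParameterError("the time grid must include 0 (present)")
    slices: list[TimeSlice] = []
    present_partition: Partition | None = None
    for t in times:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lineages, tip_map, sliced = slice_tree(tree, t)
        if sliced is None or len(lineages) < 2:
            part = Partition({g: 1 for g in occ.gsu_ids})
            slices.append(
                TimeSlice(
                    t=t,
                    lineages=lineages,
                    occurrences=None,
                    partition=part,
                    pbeta=0.0,
                )
            )
            logger.info(
                "slice t=%g Ma: %d lineage(s); single realm", t, len(lineages)
            )
            continue
        collapsed = slice_assemblages(occ, tip_map)
        if collapsed.n_gsus < 3:
            logger.warning(
                "slice t=%g Ma skipped: only %d GSUs remain",
                t,
                collapsed.n_gsus,
            )
            continue
        beta = pairwise_beta(collapsed, tree=sliced, mode="phylogenetic")
        dend = build_dendrogram(beta, linkage_method)
        part = cut_at_pbeta(dend, beta, pbeta)
        coords, stress = nmds(
            beta, n_starts=nmds_starts, seed=seed + int(round(t * 1000)) % 100000
        )
        slices.append(
            TimeSlice(
                t=t,
                lineages=lineages,
                occurrences=collapsed,
                partition=part,
                pbeta=p_beta(part, beta),
                nmds_coords=coords,
                nmds_stress=stress,
            )
        )
        if t == 0.0:
            present_partition = part
    if present_partition is None:
        present_partition = slices[0].partition
    for ts in slices:
        ts.label_map = match_realms(ts.partition, present_partition)
    nmds_trajectory(slices)
    return slices


def nmds_trajectory(slices: list[TimeSlice]) -> list[TimeSlice]:
    """Procrustes-align each slice's NMDS configuration to the present one.

    The full similarity transform (translation, scale, rotation/reflection)
    is fitted on the GSUs shared with the t=0 slice and applied to all of a
    slice's coordinates, in place.
    """
    reference = next(
        (s for s in slices if s.t == 0.0 and s.nmds_coords is not None), None
    )
    if reference is None:
        return slices
    ref = reference.nmds_coords
    for ts in slices:
        if ts.nmds_coords is None or ts is reference:
            continue
        shared = [g for g in ts.nmds_coords.index if g in ref.index]
        if len(shared) < 3:
            raise ConsistencyError(
                f"slice t={ts.t:g}: fewer than 3 GSUs shared with present"
            )
        x = ts.nmds_coords.loc[shared].to_numpy()
        y = ref.loc[shared].to_numpy()
        mx, my = x.mean(axis=0), y.mean(axis=0)
        xc, yc = x - mx, y - my
        norm_x = np.linalg.norm(xc)
        if norm_x == 0:
            continue
        rot, scale_num = orthogonal_procrustes(xc, yc)
        scale = scale_num / (norm_x**2)
        full = ts.nmds_coords.to_numpy()
        aligned = (full - mx) @ rot * scale + my
        ts.nmds_coords = pd.DataFrame(
            aligned, index=ts.nmds_coords.index, columns=ts.nmds_coords.columns
        )
    return slices


def separation_time(
    slices: list[TimeSlice], truth_partition: Partition, p: int, q: int
) -> float | None:
    """Oldest depth of the persistent separation of realms p and q.

    Two realms count as separate at a slice when the majority cluster of
    p's GSUs differs from that of q's. Scanning from the present backward,
    the separation time is the oldest slice of the unbroken run of
    separated slices that contains t=0; transient separations at deeper
    slices (clustering noise once few lineages remain) are ignored.
    Returns None if the realms are not separate at the present.
    """
    gsus_p = truth_partition.members(p)
    gsus_q = truth_partition.members(q)
    oldest: float | None = None
    for ts in sorted(slices, key=lambda s: s.t):
        lab_p = _majority(ts.partition, gsus_p)
        lab_q = _majority(ts.partition, gsus_q)
        if lab_p is None or lab_q is None or lab_p == lab_q:
            break
        oldest = ts.t
    return oldest


def _majority(partition: Partition, gsus: list[str]) -> int | None:
    labels = [partition.labels[g] for g in gsus if g in partition.labels]
    if not labels:
        return None
    vals, counts = np.unique(labels, return_counts=True)
    return int(vals[np.argmax(counts)])
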