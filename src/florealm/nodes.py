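"""Node-based geographic divergence of sister clades.

For an internal node with descendant clades A and B, the geographic node
divergence (GND) scores how little the two clades' occupied GSU sets
overlap, on a [0, 1] scale where 0 means identical ranges and 1 disjoint
ranges. The default metric is the Simpson-type range mismatch

    GND = 1 - |S_A & S_B| / (|S_A & S_B| + min(|S_A - S_B|, |S_B - S_A|))

(pluggable: any callable on the two occupied-GSU sets with the same
degenerate anchors may be supplied). Scores above 0.65 flag significant
distributional divergence.

Per-GSU specific overrepresentation scores (SOS) standardise the local
excess of clade-A tips against a null in which the A/B clade labels are
shuffled across the node's tips (preserving clade sizes and every tip's
range): positive SOS marks predominance of clade A, negative of clade B.

A clade's contribution to the division between two realms is the R^2 of a
one-way ANOVA of its SOS values with realm identity as the factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OccurrenceMatrix, Partition
from .errors import (
    InsufficientDataError,
    InvalidParameterError,
)

logger = logging.getLogger("florealm")

__all__ = [
    "NodeScores",
    "node_occupancy",
    "gnd_score",
    "simpson_range_mismatch",
    "sos_scores",
    "high_divergence_nodes",
    "clade_contribution",
]


@dataclass
class NodeScores:
    """GND and SOS for one internal node."""

    node_id: str
    node_age: float
    gnd: float
    sos: pd.Series  # index: GSUs occupied by the node's tips
    clade_a: list[str]
    clade_b: list[str]
    n_randomizations: int
    seed: int


def node_occupancy(
    tree, occ: OccurrenceMatrix, node
) -> pd.DataFrame:
    """Per-GSU counts of present tips from each descendant clade.

    ``node`` may be an internal node object or its id. Polytomies are
    scored as the split between the two largest children (by tip count,
    ties by smallest tip label); the remainder is ignored and logged. GSUs
    with no tip of the node are excluded.
    """
    if isinstance(node, str):
        node = tree.find_node(node)
    children = node.child_nodes()
    if len(children) < 2:
        raise InvalidParameterError(
            f"node {node.florealm_id!r} is not an internal bifurcation"
        )
    if len(children) > 2:
        children = sorted(
            children,
            key=lambda ch: (
                -len(tree.clade_tip_labels(ch)),
                min(tree.clade_tip_labels(ch)),
            ),
        )
        logger.info(
            "node %s is a polytomy; scoring its two largest children",
            node.florealm_id,
        )
    tips_a = [g for g in tree.clade_tip_labels(children[0]) if g in set(occ.genus_ids)]
    tips_b = [g for g in tree.clade_tip_labels(children[1]) if g in set(occ.genus_ids)]
    if not tips_a and not tips_b:
        raise InsufficientDataError(
            f"node {node.florealm_id!r}: no descendant tip occurs in the matrix"
        )
    rows_a = [occ.genus_index(g) for g in tips_a]
    rows_b = [occ.genus_index(g) for g in tips_b]
    count_a = occ.data[rows_a].sum(axis=0) if rows_a else np.zeros(occ.n_gsus, int)
    count_b = occ.data[rows_b].sum(axis=0) if rows_b else np.zeros(occ.n_gsus, int)
    occupied = (count_a + count_b) > 0
    frame = pd.DataFrame(
        {
            "count_a": count_a[occupied].astype(int),
            "count_b": count_b[occupied].astype(int),
        },
        index=pd.Index(
            [g for g, o in zip(occ.gsu_ids, occupied) if o], name="gsu_id"
        ),
    )
    frame.attrs["tips_a"] = tips_a
    frame.attrs["tips_b"] = tips_b
    rows = rows_a + rows_b
    frame.attrs["presence"] = occ.data[np.ix_(rows, np.nonzero(occupied)[0])]
    return frame


def simpson_range_mismatch(set_a: set, set_b: set) -> float:
    """Default GND metric: Simpson-type mismatch of occupied-GSU sets."""
    if not set_a or not set_b:
        raise InsufficientDataError("a clade with an empty range has no GND")
    a = len(set_a & set_b)
    m = min(len(set_a - set_b), len(set_b - set_a))
    if a + m == 0:
        return 0.0  # both ranges identical singletons
    return 1.0 - a / (a + m)


def gnd_score(occupancy: pd.DataFrame, metric=simpson_range_mismatch) -> float:
    """GND of a node from its occupancy table; metric pluggable."""
    set_a = set(occupancy.index[occupancy["count_a"] > 0])
    set_b = set(occupancy.index[occupancy["count_b"] > 0])
    score = float(metric(set_a, set_b))
    if not 0.0 <= score <= 1.0:
        raise InvalidParameterError(f"GND metric returned {score} outside [0, 1]")
    return score


def sos_scores(
    occupancy: pd.DataFrame, n_rand: int = 200, seed: int = 0
) -> pd.Series:
    """Per-GSU specific overrepresentation scores.

    The observed statistic in a GSU is the count of clade-A tips present;
    the null shuffles the A/B clade labels across the node's tips (sizes
    and ranges preserved) ``n_rand`` times. SOS = (observed - null mean) /
    null SD, with SOS = 0 where the null SD vanishes.
    """
    if n_rand < 20:
        raise InvalidParameterError("need at least 20 randomizations")
    tips_a = occupancy.attrs.get("tips_a")
    tips_b = occupancy.attrs.get("tips_b")
    if tips_a is None or tips_b is None:
        raise InvalidParameterError(
            "occupancy table lacks tip lists; build it with node_occupancy"
        )
    rng = np.random.default_rng(seed)
    pres = occupancy.attrs["presence"].astype(np.int64)  # node tips x GSUs
    n_tips = pres.shape[0]
    n_a = len(tips_a)
    observed = occupancy["count_a"].to_numpy(dtype=float)
    null = np.empty((n_rand, pres.shape[1]))
    for k in range(n_rand):
        pick = rng.permutation(n_tips)[:n_a]
        null[k] = pres[pick].sum(axis=0)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sos = np.where(sd > 0, (observed - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(sos, index=occupancy.index, name="sos")


def high_divergence_nodes(
    tree,
    occ: OccurrenceMatrix,
    threshold: float = 0.65,
    metric=simpson_range_mismatch,
) -> pd.DataFrame:
    """Score every internal node; return those with GND strictly above threshold.

    Sorted by GND descending, ties broken by node age descending.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InvalidParameterError("threshold must be in [0, 1]")
    rows = []
    present = set(occ.genus_ids)
    for node in tree.internal_nodes():
        if len(node.child_nodes()) < 2:
            continue
        tips = set(tree.clade_tip_labels(node))
        if not (tips & present):
            continue
        try:
            occupancy = node_occupancy(tree, occ, node)
            score = gnd_score(occupancy, metric=metric)
        except InsufficientDataError:
            continue
        rows.append(
            {
                "node_id": node.florealm_id,
                "node_age": tree.node_age(node),
                "gnd": score,
            }
        )
    table = pd.DataFrame(rows, columns=["node_id", "node_age", "gnd"])
    table = table.sort_values(
        ["gnd", "node_age"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    return table[table["gnd"] > threshold].reset_index(drop=True)


def clade_contribution(
    sos: pd.Series, partition: Partition, realm_pair: tuple[int, int]
) -> float:
    """ANOVA R^2 of SOS against realm identity for one realm pair.

    Only GSUs of the two realms with a defined SOS enter; the statistic is
    the between-realm sum of squares over the total sum of squares, which
    for two groups equals the squared point-biserial correlation. Constant
    SOS gives 0; fewer than 2 GSUs in either realm raises
    :class:`InsufficientDataError`.
    """
    p, q = realm_pair
    vals_p = [
        float(sos[g])
        for g in sos.index
        if partition.labels.get(g) == p and np.isfinite(sos[g])
    ]
    vals_q = [
        float(sos[g])
        for g in sos.index
        if partition.labels.get(g) == q and np.isfinite(sos[g])
    ]
    if len(vals_p) < 2 or len(vals_q) < 2:
        raise InsufficientDataError(
            f"realm pair {realm_pair}: need >= 2 scored GSUs per realm"
        )
    x = np.asarray(vals_p + vals_q)
    total = ((x - x.mean()) ** 2).sum()
    if total == 0:
        return 0.0
    between = 0.0
    for grp in (np.asarray(vals_p), np.asarray(vals_q)):
        between += len(grp) * (grp.mean() - x.mean()) ** 2
    return float(between / total)
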