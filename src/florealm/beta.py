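"""Simpson beta diversity, taxonomic and phylogenetic.

The turnover index is

    beta = 1 - a / (a + min(b, c))

with ``a`` the shared and ``b``, ``c`` the unique components of two
assemblages. In taxonomic mode the components count genera; in phylogenetic
mode they sum branch lengths of the phylogeny spanned by each assemblage
(a branch is present in a GSU iff at least one descendant tip occurs there;
the root contributes no stem branch). The index ignores richness differences
and nestedness, which is why it is the standard turnover measure for
bioregionalization.

The full-matrix path computes per-GSU branch (or genus) incidence once and
evaluates all pairs by matrix products; it is contractually equal to the
per-pair component path, which the test suite asserts against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BetaMatrix, OccurrenceMatrix
from .errors import InvalidParameterError, UndefinedBetaError
from .tree import DatedTree

__all__ = [
    "BetaComponents",
    "simpson",
    "taxonomic_components",
    "phylogenetic_components",
    "pairwise_beta",
]


@dataclass(frozen=True)
class BetaComponents:
    """Shared (a) and unique (b, c) richness or branch length of a pair."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise InvalidParameterError("beta components must be nonnegative")


def simpson(components: BetaComponents) -> float:
    """Simpson dissimilarity 1 - a/(a + min(b, c)); undefined when both are 0."""
    a = components.a
    m = min(components.b, components.c)
    denom = a + m
    if denom <= 0:
        raise UndefinedBetaError(
            "Simpson beta undefined: a + min(b, c) = 0 "
            "(empty or degenerate assemblages)"
        )
    return 1.0 - a / denom


def taxonomic_components(
    occ: OccurrenceMatrix, gsu1: str, gsu2: str
) -> BetaComponents:
    """Shared/unique genus counts for a GSU pair."""
    s1 = occ.genus_set(gsu1)
    s2 = occ.genus_set(gsu2)
    a = len(s1 & s2)
    return BetaComponents(a=a, b=len(s1) - a, c=len(s2) - a)


def phylogenetic_components(
    tree: DatedTree, occ: OccurrenceMatrix, gsu1: str, gsu2: str
) -> BetaComponents:
    """Shared/unique branch length for a GSU pair.

    Every genus of ``occ`` must be a tip of ``tree``.
    """
    _check_tips(tree, occ)
    genus_index = {g: i for i, g in enumerate(occ.genus_ids)}
    lengths, desc = tree.branch_incidence(genus_index)
    present = occ.data  # genus x gsu
    i1, i2 = occ.gsu_index(gsu1), occ.gsu_index(gsu2)
    # branch present iff >=1 descendant tip occurs in the GSU
    in1 = (desc & present[:, i1][None, :]).any(axis=1)
    in2 = (desc & present[:, i2][None, :]).any(axis=1)
    if not in1.any() or not in2.any():
        raise UndefinedBetaError(
            f"empty assemblage among GSUs {gsu1!r}, {gsu2!r}"
        )
    a = float(lengths[in1 & in2].sum())
    b = float(lengths[in1 & ~in2].sum())
    c = float(lengths[~in1 & in2].sum())
    return BetaComponents(a=a, b=b, c=c)


def pairwise_beta(
    occ: OccurrenceMatrix,
    tree: DatedTree | None = None,
    mode: str = "taxonomic",
) -> BetaMatrix:
    """Full GSU x GSU Simpson beta matrix.

    Parameters
    ----------
    occ:
        Presence matrix; every GSU must host at least one genus.
    tree:
        Required for ``mode='phylogenetic'``.
    mode:
        ``'taxonomic'`` (unit weight per genus) or ``'phylogenetic'``
        (branch-length weights on the tree spanned by each assemblage).
    """
    if mode not in ("taxonomic", "phylogenetic"):
        raise InvalidParameterError(f"unknown beta mode {mode!r}")
    if mode == "phylogenetic":
        if tree is None:
            raise InvalidParameterError("phylogenetic beta requires a tree")
        _check_tips(tree, occ)
        genus_index = {g: i for i, g in enumerate(occ.genus_ids)}
        lengths, desc = tree.branch_incidence(genus_index)
        incidence = (desc.astype(np.float64) @ occ.data) > 0  # branch x gsu
        weights = lengths
    else:
        incidence = occ.data  # genus x gsu
        weights = np.ones(occ.n_genera)

    inc = incidence.astype(np.float64)
    totals = weights @ inc  # per-GSU total weight
    if (totals <= 0).any():
        bad = [g for g, t in zip(occ.gsu_ids, totals) if t <= 0]
        raise UndefinedBetaError(f"GSUs with empty assemblages: {bad[:5]}")
    shared = (inc * weights[:, None]).T @ inc  # a for every pair
    b = totals[:, None] - shared
    c = totals[None, :] - shared
    denom = shared + np.minimum(b, c)
    undef = denom <= 0
    np.fill_diagonal(undef, False)
    if undef.any():
        i, j = np.argwhere(undef)[0]
        raise UndefinedBetaError(
            f"Simpson beta undefined for GSU pair "
            f"({occ.gsu_ids[i]!r}, {occ.gsu_ids[j]!r})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 - shared / np.where(denom > 0, denom, 1.0)
    np.fill_diagonal(values, 0.0)
    return BetaMatrix(occ.gsu_ids, values)


def _check_tips(tree: DatedTree, occ: OccurrenceMatrix) -> None:
    tips = set(tree.tip_labels)
    missing = [g for g in occ.genus_ids if g not in tips]
    if missing:
        raise InvalidParameterError(
            f"genera not on the tree: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
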