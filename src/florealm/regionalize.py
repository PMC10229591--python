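"""Delineation of floristic realms from a beta-diversity matrix.

The core procedure is agglomerative clustering of the GSU x GSU Simpson
dissimilarity matrix followed by cutting the dendrogram at the smallest
number of clusters whose explained turnover

    P_beta = (sum of beta over between-cluster GSU pairs)
             / (sum of beta over all GSU pairs)

reaches a threshold: 0.80 for realms and 0.95 for sub-realms by default.
Linkage methods are compared by performance (minimum clusters to reach
P_beta = 0.99) and accuracy (cophenetic correlation); average linkage
(UPGMA) is the expected winner on block-structured floras and is the
default. NMDS ordination, fuzzy c-means memberships and silhouette widths
quantify how hard the realm boundaries are, and the confinement statistic
reports the fraction of genera whose ranges never cross a realm boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_samples

from .containers import BetaMatrix, OccurrenceMatrix, Partition
from .errors import (
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "Dendrogram",
    "Regionalization",
    "MembershipMatrix",
    "p_beta",
    "build_dendrogram",
    "evaluate_linkages",
    "cut_at_pbeta",
    "cut_at_k",
    "nmds",
    "fuzzy_membership",
    "silhouette_widths",
    "boundary_confinement",
    "regionalize",
    "LINKAGE_METHODS",
]

# the seven classical agglomerative methods; 'mcquitty' is WPGMA
LINKAGE_METHODS = (
    "single",
    "complete",
    "average",
    "mcquitty",
    "ward",
    "centroid",
    "median",
)
_SCIPY_NAMES = {"mcquitty": "weighted", "upgma": "average"}


class Dendrogram:
    """An agglomerative clustering of GSUs with its nested cut sequence.

    The cut at k clusters undoes the last k-1 merges in merge order, which
    for monotone linkages coincides with cutting at descending merge height;
    ties in height are broken by merge order, making cuts deterministic.
    """

    def __init__(self, gsu_ids, merge_matrix: np.ndarray, method: str):
        self.gsu_ids = list(gsu_ids)
        self.merge_matrix = merge_matrix  # scipy linkage format
        self.method = method
        self._cut_cache: dict[int, np.ndarray] = {}

    @property
    def n(self) -> int:
        return len(self.gsu_ids)

    def cut_labels(self, k: int) -> np.ndarray:
        """Cluster labels (aligned to gsu_ids) for the nested cut at k."""
        if not 1 <= k <= self.n:
            raise InvalidParameterError(f"k={k} outside 1..{self.n}")
        if k in self._cut_cache:
            return self._cut_cache[k]
        n = self.n
        parent = np.arange(2 * n - 1)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        # apply the first n-k merges
        for m in range(n - k):
            left, right = int(self.merge_matrix[m, 0]), int(
                self.merge_matrix[m, 1]
            )
            new = n + m
            parent[find(left)] = new
            parent[find(right)] = new
        roots = np.asarray([find(i) for i in range(n)])
        _, labels = np.unique(roots, return_inverse=True)
        labels = labels + 1
        self._cut_cache[k] = labels
        return labels

    def cut_partition(self, k: int) -> Partition:
        labels = self.cut_labels(k)
        return Partition(dict(zip(self.gsu_ids, (int(v) for v in labels))))

    def cophenetic_correlation(self, beta: BetaMatrix) -> float:
        """Pearson correlation of input vs dendrogram-implied distances."""
        condensed = beta.subset(self.gsu_ids).condensed()
        coph = cophenet(self.merge_matrix)
        if np.std(coph) == 0 or np.std(condensed) == 0:
            return 1.0 if np.allclose(coph, condensed) else 0.0
        return float(pearsonr(condensed, coph)[0])

    def __repr__(self) -> str:  # pragma: no cover
        return f"Dendrogram(n={self.n}, method={self.method!r})"


def p_beta(partition: Partition, beta: BetaMatrix) -> float:
    """Proportion of total pairwise beta falling between clusters."""
    if beta.n < 2:
        raise InsufficientDataError("P_beta needs at least 2 GSUs")
    labels = partition.label_vector(beta.gsu_ids)
    iu = np.triu_indices(beta.n, k=1)
    vals = beta.values[iu]
    total = vals.sum()
    if total == 0:
        # a zero matrix has no turnover to explain; define P_beta = 0
        return 0.0
    between = labels[iu[0]] != labels[iu[1]]
    return float(vals[between].sum() / total)


def build_dendrogram(beta: BetaMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering of the beta matrix under a named linkage."""
    if method not in LINKAGE_METHODS and method not in _SCIPY_NAMES:
        raise InvalidParameterError(
            f"unknown linkage {method!r}; choose from {LINKAGE_METHODS}"
        )
    scipy_method = _SCIPY_NAMES.get(method, method)
    condensed = squareform(beta.values, checks=False)
    merge = linkage(condensed, method=scipy_method)
    return Dendrogram(beta.gsu_ids, merge, method)


def _pbeta_profile(dend: Dendrogram, beta: BetaMatrix) -> np.ndarray:
    """P_beta for every nested cut k = 1..n (index k-1)."""
    n = dend.n
    sub = beta.subset(dend.gsu_ids)
    iu = np.triu_indices(n, k=1)
    vals = sub.values[iu]
    total = vals.sum()
    out = np.empty(n)
    for k in range(1, n + 1):
        labels = dend.cut_labels(k)
        if total == 0:
            out[k - 1] = 0.0
        else:
            between = labels[iu[0]] != labels[iu[1]]
            out[k - 1] = vals[between].sum() / total
    return out


def evaluate_linkages(
    beta: BetaMatrix,
    methods=LINKAGE_METHODS,
    performance_threshold: float = 0.99,
) -> pd.DataFrame:
    """Compare linkage methods by performance and accuracy.

    Performance is the minimum number of clusters at which P_beta reaches
    ``performance_threshold`` along the nested cut sequence (fewer is
    better); accuracy is the cophenetic correlation with the input matrix
    (higher is better). The selected method minimises the cluster count,
    with ties broken by accuracy.
    """
    methods = list(methods)
    if len(methods) < 2:
        raise InvalidParameterError("need at least 2 methods to compare")
    rows = []
    for method in methods:
        dend = build_dendrogram(beta, method)
        profile = _pbeta_profile(dend, beta)
        reached = np.nonzero(profile >= performance_threshold)[0]
        min_k = int(reached[0]) + 1 if reached.size else dend.n
        rows.append(
            {
                "method": method,
                "min_clusters_at_threshold": min_k,
                "cophenetic_correlation": dend.cophenetic_correlation(beta),
            }
        )
    table = pd.DataFrame(rows)
    # exact ties on both criteria fall back to UPGMA, the field's default
    pref = {"average": 0}
    table["_pref"] = [pref.get(m, 1) for m in table["method"]]
    order = table.sort_values(
        ["min_clusters_at_threshold", "cophenetic_correlation", "_pref"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    table = table.drop(columns="_pref")
    table["selected"] = False
    table.loc[order.index[0], "selected"] = True
    return table


def cut_at_pbeta(
    dend: Dendrogram, beta: BetaMatrix, threshold: float
) -> Partition:
    """Smallest nested cut whose explained turnover reaches the threshold."""
    if not 0 <= threshold <= 1:
        raise InvalidParameterError("threshold must be in [0, 1]")
    sub = beta.subset(dend.gsu_ids)
    for k in range(1, dend.n + 1):
        part = dend.cut_partition(k)
        if p_beta(part, sub) >= threshold:
            return part
    return dend.cut_partition(dend.n)  # all singletons: P_beta = 1


def cut_at_k(dend: Dendrogram, k: int) -> Partition:
    """The nested cut with exactly k clusters (e.g. k=2 super-realms)."""
    return dend.cut_partition(k)


def nmds(
    beta: BetaMatrix,
    dims: int = 2,
    n_starts: int = 100,
    seed: int = 0,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, float]:
    """Nonmetric multidimensional scaling of the beta matrix.

    Returns centered coordinates (index = GSU ids) of the best of
    ``n_starts`` random initialisations and its Kruskal stress-1.
    """
    if beta.n < 3:
        raise InsufficientDataError("NMDS needs at least 3 GSUs")
    iu = np.triu_indices(beta.n, k=1)
    if np.allclose(beta.values[iu], beta.values[iu][0]):
        warnings.warn(
            "all dissimilarities equal: NMDS configuration is arbitrary",
            stacklevel=2,
        )
        # deterministic fallback: evenly spaced points on a circle
        angles = 2 * np.pi * np.arange(beta.n) / beta.n
        coords = np.zeros((beta.n, dims))
        coords[:, 0] = np.cos(angles)
        coords[:, 1 % dims] = np.sin(angles)
        coords -= coords.mean(axis=0, keepdims=True)
        frame = pd.DataFrame(
            coords,
            index=pd.Index(beta.gsu_ids, name="gsu_id"),
            columns=[f"nmds{i + 1}" for i in range(dims)],
        )
        return frame, 0.0
    model = MDS(
        n_components=dims,
        metric=False,
        n_init=n_starts,
        max_iter=max_iter,
        dissimilarity="precomputed",
        random_state=int(seed) % (2**31),
        normalized_stress=True,
        eps=1e-9,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(beta.values)
    coords = coords - coords.mean(axis=0, keepdims=True)
    frame = pd.DataFrame(
        coords,
        index=pd.Index(beta.gsu_ids, name="gsu_id"),
        columns=[f"nmds{i + 1}" for i in range(dims)],
    )
    return frame, float(model.stress_)


@dataclass
class MembershipMatrix:
    """Fuzzy cluster likelihoods per GSU; rows sum to one."""

    frame: pd.DataFrame  # index gsu_id, columns cluster labels 1..k
    fuzziness: float

    def __post_init__(self):
        sums = self.frame.to_numpy().sum(axis=1)
        if np.abs(sums - 1).max(initial=0.0) > 1e-9:
            raise InvalidParameterError("membership rows must sum to 1")

    def hard_partition(self) -> Partition:
        labels = self.frame.to_numpy().argmax(axis=1) + 1
        return Partition(
            dict(zip(self.frame.index, (int(v) for v in labels)))
        )


def fuzzy_membership(
    beta: BetaMatrix,
    k: int,
    fuzziness: float = 1.5,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> MembershipMatrix:
    """Dissimilarity-based fuzzy c-means memberships (FANNY-style).

    Minimises sum_v [ sum_ij u_iv^r u_jv^r d_ij / (2 sum_j u_jv^r) ] over
    row-stochastic memberships U by the classical alternating update, so it
    needs only the dissimilarity matrix, never coordinates.
    """
    n = beta.n
    if not 2 <= k <= n:
        raise InvalidParameterError(f"k={k} must satisfy 2 <= k <= n={n}")
    if fuzziness <= 1:
        raise InvalidParameterError("fuzziness exponent must exceed 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, k))
    u /= u.sum(axis=1, keepdims=True)
    d = beta.values
    r = fuzziness
    expo = -1.0 / (r - 1.0)
    eps = 1e-12
    for _ in range(max_iter):
        ur = u**r
        col = ur.sum(axis=0)
        col = np.maximum(col, eps)
        s1 = d @ ur  # sum_j u_jv^r d_ij
        quad = np.einsum("iv,ij,jv->v", ur, d, ur)
        a = s1 / col - quad / (2.0 * col**2)
        a = np.maximum(a, 0.0)
        new_u = np.empty_like(u)
        zero_rows = (a <= eps).any(axis=1)
        pos = ~zero_rows
        if pos.any():
            inv = a[pos] ** expo
            new_u[pos] = inv / inv.sum(axis=1, keepdims=True)
        if zero_rows.any():
            # a vanishing within-cluster cost pins the GSU to that cluster
            z = a[zero_rows] <= eps
            new_u[zero_rows] = z / z.sum(axis=1, keepdims=True)
        delta = np.abs(new_u - u).max()
        u = new_u
        if delta < tol:
            break
    frame = pd.DataFrame(
        u,
        index=pd.Index(beta.gsu_ids, name="gsu_id"),
        columns=list(range(1, k + 1)),
    )
    return MembershipMatrix(frame=frame, fuzziness=fuzziness)


def silhouette_widths(
    partition: Partition, beta: BetaMatrix
) -> pd.Series:
    """Silhouette width per GSU on the beta matrix; singleton clusters get 0."""
    if partition.k < 2:
        raise InsufficientDataError("silhouette needs at least 2 clusters")
    labels = partition.label_vector(beta.gsu_ids)
    widths = silhouette_samples(beta.values, labels, metric="precomputed")
    return pd.Series(
        widths, index=pd.Index(beta.gsu_ids, name="gsu_id"), name="silhouette"
    )


def boundary_confinement(
    occ: OccurrenceMatrix, partition: Partition
) -> float:
    """Fraction of genera whose entire range lies within one realm."""
    labels = partition.label_vector(occ.gsu_ids)
    onehot = labels[:, None] == np.unique(labels)[None, :]
    realms_per_genus = ((occ.data @ onehot.astype(int)) > 0).sum(axis=1)
    return float((realms_per_genus == 1).mean())


@dataclass
class Regionalization:
    """Nested realm / sub-realm partitions cut from one dendrogram."""

    realms: Partition
    realm_pbeta: float
    subrealms: Partition
    subrealm_pbeta: float
    dendrogram: Dendrogram
    linkage_evaluation: pd.DataFrame | None = None

    def __post_init__(self):
        if set(self.realms.labels) != set(self.subrealms.labels):
            raise InvalidParameterError(
                "realm and sub-realm partitions cover different GSUs"
            )
        if not self.subrealms.refines(self.realms):
            raise InvalidParameterError(
                "sub-realms do not nest within realms"
            )

    def super_realms(self, k: int = 2) -> Partition:
        return cut_at_k(self.dendrogram, k)


def regionalize(
    beta: BetaMatrix,
    pbeta_realm: float = 0.80,
    pbeta_subrealm: float = 0.95,
    linkage_method: str = "auto",
    selection_threshold: float = 0.99,
) -> Regionalization:
    """End-to-end realm delineation from a beta matrix.

    With ``linkage_method='auto'`` the seven classical linkages are compared
    and the best performer (ties by cophenetic accuracy) is used; otherwise
    the named linkage is used directly.
    """
    if not 0 < pbeta_realm < pbeta_subrealm <= 1:
        raise InvalidParameterError(
            "need 0 < realm threshold < sub-realm threshold <= 1"
        )
    evaluation = None
    if linkage_method == "auto":
        evaluation = evaluate_linkages(
            beta, performance_threshold=selection_threshold
        )
        linkage_method = evaluation.loc[
            evaluation["selected"], "method"
        ].iloc[0]
    dend = build_dendrogram(beta, linkage_method)
    realms = cut_at_pbeta(dend, beta, pbeta_realm)
    subrealms = cut_at_pbeta(dend, beta, pbeta_subrealm)
    return Regionalization(
        realms=realms,
        realm_pbeta=p_beta(realms, beta),
        subrealms=subrealms,
        subrealm_pbeta=p_beta(subrealms, beta),
        dendrogram=dend,
        linkage_evaluation=evaluation,
    )
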