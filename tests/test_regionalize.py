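"""Realm delineation: P_beta, dendrogram cuts, NMDS, fuzzy memberships,
silhouettes, confinement."""

import numpy as np
import pytest

from florealm.containers import BetaMatrix, OccurrenceMatrix, Partition
from florealm.errors import InsufficientDataError, InvalidParameterError
from florealm.regionalize import (
    boundary_confinement,
    build_dendrogram,
    cut_at_k,
    cut_at_pbeta,
    evaluate_linkages,
    fuzzy_membership,
    nmds,
    p_beta,
    regionalize,
    silhouette_widths,
)

from conftest import block_beta_matrix, random_beta_matrix


def _beta3(b12, b13, b23):
    vals = np.array([[0, b12, b13], [b12, 0, b23], [b13, b23, 0]], float)
    return BetaMatrix(["u1", "u2", "u3"], vals)


class TestPBeta:
    def test_direct_arithmetic(self):
        beta = _beta3(0.2, 0.6, 0.8)
        part = Partition({"u1": 1, "u2": 1, "u3": 2})
        assert p_beta(part, beta) == pytest.approx((0.6 + 0.8) / 1.6)

    def test_single_cluster_is_zero(self):
        beta = _beta3(0.2, 0.6, 0.8)
        assert p_beta(Partition({g: 1 for g in beta.gsu_ids}), beta) == 0.0

    def test_perfect_blocks_reach_one(self):
        beta = block_beta_matrix(2)
        part = Partition(
            {g: (1 if i < 2 else 2) for i, g in enumerate(beta.gsu_ids)}
        )
        assert p_beta(part, beta) == 1.0

    def test_nondecreasing_along_nested_cuts(self, rng):
        """P_beta grows with k along one dendrogram's nested cut sequence."""
        for _ in range(20):
            beta = random_beta_matrix(rng, 15)
            dend = build_dendrogram(beta, "average")
            profile = [
                p_beta(dend.cut_partition(k), beta) for k in range(1, 16)
            ]
            assert profile[0] == 0.0
            assert all(
                later >= earlier - 1e-12
                for earlier, later in zip(profile, profile[1:])
            )


class TestDendrogram:
    def test_first_merge_is_unique_minimum(self):
        beta = _beta3(0.1, 0.9, 0.9)
        for method in ("single", "complete", "average", "ward"):
            dend = build_dendrogram(beta, method)
            labels = dend.cut_labels(2)
            assert labels[0] == labels[1] != labels[2]

    def test_upgma_and_single_second_merge_heights(self):
        beta = _beta3(0.1, 0.9, 0.9)
        upgma = build_dendrogram(beta, "average")
        assert upgma.merge_matrix[1, 2] == pytest.approx(0.9)  # (0.9+0.9)/2
        single = build_dendrogram(beta, "single")
        assert single.merge_matrix[1, 2] == pytest.approx(0.9)

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_dendrogram(_beta3(0.1, 0.2, 0.3), "upmga")


class TestEvaluateLinkages:
    def test_block_matrix_all_methods_agree(self):
        beta = block_beta_matrix(3)
        table = evaluate_linkages(beta)
        assert (table["min_clusters_at_threshold"] == 2).all()
        assert np.allclose(table["cophenetic_correlation"], 1.0)
        # full tie falls back to UPGMA
        assert table.loc[table["selected"], "method"].iloc[0] == "average"

    def test_min_k_brackets_threshold(self, rng):
        beta = random_beta_matrix(rng, 12)
        table = evaluate_linkages(beta, methods=["average", "complete"])
        for _, row in table.iterrows():
            dend = build_dendrogram(beta, row["method"])
            k = int(row["min_clusters_at_threshold"])
            assert p_beta(dend.cut_partition(k), beta) >= 0.99
            if k > 1:
                assert p_beta(dend.cut_partition(k - 1), beta) < 0.99


class TestCutAtPbeta:
    def test_zero_threshold_gives_one_cluster(self, rng):
        beta = random_beta_matrix(rng, 8)
        dend = build_dendrogram(beta, "average")
        assert cut_at_pbeta(dend, beta, 0.0).k == 1

    def test_two_blocks_at_080(self):
        beta = block_beta_matrix(4)
        dend = build_dendrogram(beta, "average")
        part = cut_at_pbeta(dend, beta, 0.8)
        assert part.k == 2
        labels = part.label_vector(beta.gsu_ids)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_subrealm_cut_refines_realm_cut(self, default_beta):
        reg = regionalize(default_beta, linkage_method="average")
        assert reg.subrealms.refines(reg.realms)
        assert reg.realm_pbeta >= 0.80 and reg.subrealm_pbeta >= 0.95
        assert reg.super_realms(2).k == 2


class TestNMDS:
    def test_recovers_planar_configuration(self, rng):
        pts = rng.random((6, 2)) * 2
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dist /= dist.max()
        beta = BetaMatrix([f"u{i}" for i in range(6)], dist)
        coords, stress = nmds(beta, n_starts=8, seed=3)
        assert stress <= 0.01
        assert np.allclose(coords.to_numpy().mean(axis=0), 0, atol=1e-9)

    def test_deterministic_under_seed(self, rng):
        beta = random_beta_matrix(rng, 7)
        a, sa = nmds(beta, n_starts=4, seed=9)
        b, sb = nmds(beta, n_starts=4, seed=9)
        assert sa == sb and np.array_equal(a.to_numpy(), b.to_numpy())

    def test_degenerate_equal_matrix_warns(self):
        n = 5
        vals = np.ones((n, n)) * 0.5
        np.fill_diagonal(vals, 0)
        beta = BetaMatrix([f"u{i}" for i in range(n)], vals)
        with pytest.warns(UserWarning):
            coords, _ = nmds(beta, n_starts=2, seed=0)
        with pytest.warns(UserWarning):
            coords2, _ = nmds(beta, n_starts=2, seed=0)
        assert coords.shape == (n, 2)
        # arbitrary but deterministic layout
        assert np.array_equal(coords.to_numpy(), coords2.to_numpy())


class TestFuzzyMembership:
    def test_two_blocks_crisp(self):
        beta = block_beta_matrix(4)
        mem = fuzzy_membership(beta, 2, seed=0)
        assert (mem.frame.to_numpy().max(axis=1) >= 0.99).all()
        hard = mem.hard_partition()
        labels = hard.label_vector(beta.gsu_ids)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1

    def test_rows_sum_to_one(self, rng):
        beta = random_beta_matrix(rng, 9)
        mem = fuzzy_membership(beta, 3, seed=1)
        assert np.allclose(mem.frame.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("k", [1, 99])
    def test_bad_k_rejected(self, rng, k):
        beta = random_beta_matrix(rng, 6)
        with pytest.raises(InvalidParameterError):
            fuzzy_membership(beta, k)


class TestSilhouette:
    def test_perfect_blocks_width_one(self):
        beta = block_beta_matrix(3)
        part = Partition(
            {g: (1 if i < 3 else 2) for i, g in enumerate(beta.gsu_ids)}
        )
        assert np.allclose(silhouette_widths(part, beta), 1.0)

    def test_matches_direct_formula(self, rng):
        beta = random_beta_matrix(rng, 10)
        labels = {g: (i % 3) + 1 for i, g in enumerate(beta.gsu_ids)}
        part = Partition(labels)
        widths = silhouette_widths(part, beta)
        d = beta.values
        lab = part.label_vector(beta.gsu_ids)
        for i, g in enumerate(beta.gsu_ids):
            own = np.where((lab == lab[i]) & (np.arange(10) != i))[0]
            if own.size == 0:
                assert widths[g] == 0.0
                continue
            a = d[i, own].mean()
            b = min(
                d[i, lab == other].mean()
                for other in set(lab) if other != lab[i]
            )
            expect = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
            assert widths[g] == pytest.approx(expect, abs=1e-12)

    def test_single_cluster_undefined(self, rng):
        beta = random_beta_matrix(rng, 4)
        with pytest.raises(InsufficientDataError):
            silhouette_widths(Partition({g: 1 for g in beta.gsu_ids}), beta)


class TestBoundaryConfinement:
    def test_counting(self):
        occ = OccurrenceMatrix.from_pairs(
            [("A", "g1"), ("B", "g2"), ("C", "g1"), ("C", "g2")]
        )
        part = Partition({"g1": 1, "g2": 2})
        assert boundary_confinement(occ, part) == pytest.approx(2 / 3)

    def test_single_realm_is_one(self):
        occ = OccurrenceMatrix.from_pairs([("A", "g1"), ("B", "g2")])
        part = Partition({"g1": 1, "g2": 1})
        assert boundary_confinement(occ, part) == 1.0


def test_cut_at_k_exposes_requested_rank(default_beta):
    dend = build_dendrogram(default_beta, "average")
    for k in (1, 2, 5):
        assert cut_at_k(dend, k).k == k
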