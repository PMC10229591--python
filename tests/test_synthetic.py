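"""Synthetic world generator: planted structure and determinism."""

import numpy as np
import pytest

from florealm.beta import pairwise_beta, phylogenetic_components, simpson
from florealm.drivers import least_cost_isolation
from florealm.errors import InvalidParameterError
from florealm.regionalize import boundary_confinement
from florealm.synthetic import (
    gen_climate,
    gen_paleo,
    gen_ranges,
    gen_tree,
    gen_world,
    simulate_world,
)


class TestGenTree:
    def test_two_tips_at_crown_depth(self):
        tree = gen_tree(2, 100.0, seed=1)
        assert tree.n_tips == 2
        for leaf in tree.dendropy_tree.leaf_node_iter():
            assert leaf.florealm_depth == pytest.approx(100.0, abs=1e-9)

    def test_same_seed_byte_identical(self):
        a = gen_tree(20, 80.0, seed=42).to_newick()
        b = gen_tree(20, 80.0, seed=42).to_newick()
        assert a == b

    def test_rescaled_to_requested_crown(self):
        tree = gen_tree(50, 140.0, seed=7)
        assert tree.crown_age == pytest.approx(140.0, abs=1e-9)
        depths = [
            leaf.florealm_depth
            for leaf in tree.dendropy_tree.leaf_node_iter()
        ]
        assert max(depths) - min(depths) < 1e-9  # ultrametric

    def test_too_few_tips_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_tree(1, 10.0)


class TestGenWorld:
    def test_equal_blocks_4x4(self):
        truth, table = gen_world((4, 4), 4)
        counts = table["true_realm"].value_counts()
        assert sorted(counts) == [4, 4, 4, 4]

    def test_column_world_contiguous_bands(self):
        truth, table = gen_world((6, 1), 2)
        labels = [
            truth.realm_of_gsu[f"gsu{r:02d}x00"] for r in range(6)
        ]
        assert labels == [1, 1, 1, 2, 2, 2]

    def test_single_realm(self):
        truth, _ = gen_world((3, 3), 1)
        assert set(truth.realm_of_gsu.values()) == {1}

    def test_too_many_realms_rejected(self):
        with pytest.raises(InvalidParameterError):
            gen_world((2, 2), 5)

    def test_weighted_bands(self):
        truth, table = gen_world((6, 6), 3, realm_weights=(3, 2, 1))
        counts = table["true_realm"].value_counts().sort_index()
        assert list(counts) == [18, 12, 6]


class TestGenRanges:
    def test_zero_leakage_confines_all_genera(self):
        world = simulate_world(
            grid_dims=(4, 4), n_realms=2, n_tips=40, leakage=0.0, seed=2
        )
        conf = boundary_confinement(
            world.occurrences, world.truth.realm_partition()
        )
        assert conf == 1.0

    def test_full_affinity_zero_leakage_zero_within_beta(self):
        world = simulate_world(
            grid_dims=(4, 4), n_realms=2, n_tips=40,
            affinity=1.0, leakage=0.0, seed=3,
        )
        beta = pairwise_beta(world.occurrences, mode="taxonomic")
        part = world.truth.realm_partition()
        labels = part.label_vector(beta.gsu_ids)
        iu = np.triu_indices(beta.n, 1)
        within = beta.values[iu][labels[iu[0]] == labels[iu[1]]]
        assert np.allclose(within, 0.0)

    def test_between_exceeds_within_phylo_beta(self):
        """Planted clade->realm structure raises between-realm turnover,
        checked by direct computation with the per-pair oracle."""
        world = simulate_world(seed=3)  # 200 tips, 6x6, 4 realms
        occ, tree = world.occurrences, world.tree
        labels = {g: world.truth.realm_of_gsu[g] for g in occ.gsu_ids}
        rng = np.random.default_rng(0)
        gsus = occ.gsu_ids
        within, between = [], []
        for _ in range(40):
            g1, g2 = rng.choice(gsus, size=2, replace=False)
            val = simpson(phylogenetic_components(tree, occ, g1, g2))
            (within if labels[g1] == labels[g2] else between).append(val)
        assert np.mean(between) > np.mean(within)

    def test_determinism(self):
        a = simulate_world(seed=9).occurrences
        b = simulate_world(seed=9).occurrences
        assert np.array_equal(a.data, b.data)

    def test_bad_leakage_mode(self, default_world):
        with pytest.raises(InvalidParameterError):
            gen_ranges(
                default_world.tree, default_world.truth, leakage_mode="osmosis"
            )


class TestGenClimate:
    def test_latitude_only_when_unaligned(self):
        world = simulate_world(grid_dims=(4, 4), n_realms=2, n_tips=30, seed=1)
        clim = gen_climate(
            world.truth, world.gsu_table, gradient_align=0.0, noise_sd=0.0
        )
        frame = clim.frame.join(
            world.gsu_table.set_index("gsu_id")[["lat"]]
        )
        for _, grp in frame.groupby("lat"):
            assert grp["mat_c"].nunique() == 1
            assert grp["map_mm"].nunique() == 1

    def test_constant_within_realm_when_aligned(self):
        world = simulate_world(grid_dims=(4, 4), n_realms=2, n_tips=30, seed=1)
        clim = gen_climate(
            world.truth, world.gsu_table, gradient_align=1.0, noise_sd=0.0
        )
        for realm in (1, 2):
            gsus = [
                g for g, r in world.truth.realm_of_gsu.items() if r == realm
            ]
            assert clim.frame.loc[gsus, "mat_c"].nunique() == 1

    def test_deterministic(self):
        world = simulate_world(grid_dims=(4, 4), n_realms=2, n_tips=30, seed=4)
        a = gen_climate(world.truth, world.gsu_table, seed=4)
        b = gen_climate(world.truth, world.gsu_table, seed=4)
        assert a.frame.equals(b.frame)


@pytest.fixture(scope="module")
def paleo_world():
    return simulate_world(
        grid_dims=(4, 4), n_realms=2, n_tips=40,
        realm_split_times=[60.0], seed=5,
        paleo_times=[0.0, 40.0, 80.0],
    )


class TestGenPaleo:

    def test_strip_rule(self, paleo_world):
        by_time = {s.time: s for s in paleo_world.surfaces}
        assert not by_time[0.0].mask.all()  # ocean strip present after split
        assert by_time[80.0].mask.all()  # one landmass before the split

    def test_isolation_rises_after_split(self, paleo_world):
        cent = paleo_world.gsu_table
        labels = paleo_world.truth.realm_of_gsu
        young = least_cost_isolation(paleo_world.surfaces[0], cent)
        old = least_cost_isolation(paleo_world.surfaces[-1], cent)
        cross = [
            (a, b)
            for a in labels
            for b in labels
            if a < b and labels[a] != labels[b]
        ]
        assert all(
            young.value(a, b) > old.value(a, b) for a, b in cross
        )

    def test_split_outside_window_rejected(self, paleo_world):
        with pytest.raises(InvalidParameterError):
            gen_paleo(
                paleo_world.truth,
                paleo_world.gsu_table,
                times=[0.0, 10.0],
                geo_split_times={(1, 2): 60.0},
            )


def test_substreams_reproducible_per_stage():
    """Regenerating only the climate leaves tree and ranges untouched."""
    w1 = simulate_world(seed=6)
    w2 = simulate_world(seed=6, gradient_align=0.9)
    assert w1.tree.to_newick() == w2.tree.to_newick()
    assert np.array_equal(w1.occurrences.data, w2.occurrences.data)
    assert not w1.climate.frame.equals(w2.climate.frame)


def test_planted_split_times_match_tree_mrca(default_world):
    truth = default_world.truth
    assert truth.split_times[(1, 2)] == pytest.approx(30.0)
    assert truth.split_times[(1, 3)] == pytest.approx(60.0)
    assert default_world.tree.crown_age == pytest.approx(60.0, abs=1e-6)
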