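"""Phylogeny time-slicing, realm matching and NMDS trajectories."""

import numpy as np
import pandas as pd
import pytest

from florealm.beta import pairwise_beta
from florealm.chronology import (
    chronology_run,
    match_realms,
    nmds_trajectory,
    separation_time,
    slice_assemblages,
    slice_tree,
)
from florealm.containers import OccurrenceMatrix, Partition
from florealm.errors import ConsistencyError, InvalidParameterError
from florealm.regionalize import build_dendrogram, cut_at_pbeta
from florealm.synthetic import simulate_world


class TestSliceTree:
    def test_identity_at_present(self, toy_tree):
        lineages, tip_map, sliced = slice_tree(toy_tree, 0.0)
        assert sorted(lineages) == ["A", "B", "C"]
        assert tip_map == {"A": "A", "B": "B", "C": "C"}
        assert sliced.crown_age == pytest.approx(2.0)

    def test_mid_depth_collapses_cherry(self, toy_tree):
        # AB stem spans [1, 2]; C's branch spans [0, 2]
        lineages, tip_map, sliced = slice_tree(toy_tree, 1.5)
        groups = sorted(sorted(v) for v in lineages.values())
        assert groups == [["A", "B"], ["C"]]
        assert tip_map["A"] == tip_map["B"] != tip_map["C"]
        # truncated branches: both lineages cut at depth 1.5
        assert sliced.crown_age == pytest.approx(0.5)

    def test_beyond_crown_warns_and_collapses_to_root_children(self, toy_tree):
        with pytest.warns(UserWarning):
            lineages, _, sliced = slice_tree(toy_tree, 3.0)
        assert len(lineages) == 2
        assert sliced is None

    def test_negative_depth_rejected(self, toy_tree):
        with pytest.raises(InvalidParameterError):
            slice_tree(toy_tree, -1.0)


class TestSliceAssemblages:
    def test_union_rule(self):
        occ = OccurrenceMatrix.from_pairs([("A", "g1"), ("B", "g2")])
        collapsed = slice_assemblages(occ, {"A": "L", "B": "L"})
        assert collapsed.genus_ids == ["L"]
        assert collapsed.genus_set("g1") == {"L"} == collapsed.genus_set("g2")

    def test_column_support_never_increases(self, default_world):
        occ = default_world.occurrences
        _, tip_map, _ = slice_tree(default_world.tree, 20.0)
        collapsed = slice_assemblages(occ, tip_map)
        assert (
            collapsed.data.sum(axis=0) <= occ.data.sum(axis=0)
        ).all()

    def test_unmapped_genus_rejected(self):
        occ = OccurrenceMatrix.from_pairs([("A", "g1"), ("B", "g2")])
        with pytest.raises(ConsistencyError):
            slice_assemblages(occ, {"A": "L"})


class TestMatchRealms:
    def test_identity(self):
        part = Partition({"a": 1, "b": 1, "c": 2})
        assert match_realms(part, part) == {1: "1", 2: "2"}

    def test_recovers_permutation(self):
        slice_part = Partition({"a": 2, "b": 2, "c": 1})
        present = Partition({"a": 1, "b": 1, "c": 2})
        assert match_realms(slice_part, present) == {2: "1", 1: "2"}

    def test_merged_realms_flagged_ancestral(self):
        # slice merges two present realms of 2 GSUs each: Jaccard 0.5
        # against either, which meets the default threshold for one match
        slice_part = Partition({g: 1 for g in "abcd"})
        present = Partition({"a": 1, "b": 1, "c": 2, "d": 2})
        mapping = match_realms(slice_part, present)
        assert list(mapping) == [1]
        # at a stricter threshold the union is ancestral
        strict = match_realms(slice_part, present, ancestral_jaccard=0.6)
        assert strict[1].startswith("ancestral")


@pytest.fixture(scope="module")
def chrono_world():
    return simulate_world(
        n_realms=3, leakage=0.002, seed=4, realm_weights=(3, 2, 1)
    )


@pytest.fixture(scope="module")
def chrono_slices(chrono_world):
    times = [float(t) for t in range(0, 90, 10)]
    return chronology_run(
        chrono_world.tree, chrono_world.occurrences, times, nmds_starts=2
    )


class TestChronologyRun:
    def test_requires_present_slice(self, chrono_world):
        with pytest.raises(InvalidParameterError):
            chronology_run(
                chrono_world.tree, chrono_world.occurrences, [10.0, 20.0]
            )

    def test_lineage_count_nonincreasing(self, chrono_slices):
        counts = [ts.n_lineages for ts in chrono_slices]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_present_slice_equals_present_pipeline(
        self, chrono_world, chrono_slices
    ):
        beta = pairwise_beta(
            chrono_world.occurrences, tree=chrono_world.tree,
            mode="phylogenetic",
        )
        dend = build_dendrogram(beta, "average")
        present = cut_at_pbeta(dend, beta, 0.80)
        assert chrono_slices[0].t == 0.0
        assert chrono_slices[0].partition == present

    def test_deep_slice_single_realm(self, chrono_slices):
        deepest = chrono_slices[-1]
        assert deepest.t == 80.0
        assert deepest.partition.k == 1

    def test_separation_tracks_planted_splits(self, chrono_world, chrono_slices):
        truth = chrono_world.truth.realm_partition()
        sep_deep = separation_time(chrono_slices, truth, 1, 3)
        sep_shallow = separation_time(chrono_slices, truth, 1, 2)
        assert abs(sep_deep - 60.0) <= 10.0
        assert abs(sep_shallow - 30.0) <= 10.0


class TestNmdsTrajectory:
    def test_identity_alignment_zero_residual(self, chrono_slices):
        ref = next(s for s in chrono_slices if s.t == 0.0)
        assert ref.nmds_coords is not None

    def test_rotation_recovered_exactly(self, chrono_slices):
        from florealm.chronology import TimeSlice

        ref = next(s for s in chrono_slices if s.t == 0.0)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        fake = TimeSlice(
            t=5.0,
            lineages={},
            occurrences=None,
            partition=ref.partition,
            pbeta=ref.pbeta,
            nmds_coords=pd.DataFrame(
                ref.nmds_coords.to_numpy() @ rot,
                index=ref.nmds_coords.index,
                columns=ref.nmds_coords.columns,
            ),
        )
        nmds_trajectory([ref, fake])
        assert np.allclose(
            fake.nmds_coords.to_numpy(), ref.nmds_coords.to_numpy(), atol=1e-9
        )

    def test_alignment_needs_shared_gsus(self, chrono_slices):
        from florealm.chronology import TimeSlice

        ref = next(s for s in chrono_slices if s.t == 0.0)
        orphan = TimeSlice(
            t=5.0,
            lineages={},
            occurrences=None,
            partition=ref.partition,
            pbeta=0.0,
            nmds_coords=pd.DataFrame(
                np.zeros((3, 2)),
                index=["x1", "x2", "x3"],
                columns=["nmds1", "nmds2"],
            ),
        )
        with pytest.raises(ConsistencyError):
            nmds_trajectory([ref, orphan])
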