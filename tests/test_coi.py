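import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lucifind.coi import (
    CoiAlignment,
    DistanceMatrix,
    distance_matrix,
    flag_misidentified,
    group_range,
    nj_tree,
    p_distance,
    threshold_clusters,
)

from .oracles import random_additive_tree


def _tip_distances(newick):
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances()
    return {
        (a, b): dm[a, b] for a in dm.ids for b in dm.ids if a != b
    }


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("AC-T", "ACGT", 0.0),  # gap site dropped: 3 comparable, 0 diff
            ("ACNT", "ACGT", 0.0),  # N treated like a gap
            ("A-GT", "ACG-", 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_sites_is_undefined(self):
        with pytest.raises(ValueError):
            p_distance("--NN", "AC--")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            p_distance("ACG", "AC")

    @given(perm_seed=st.integers(0, 10**6))
    @settings(max_examples=25)
    def test_invariant_under_column_permutation(self, perm_seed):
        a = "ACGTACGTAC-TNCGT"
        b = "ACGAACTTACGTACG-"
        rng = np.random.default_rng(perm_seed)
        perm = rng.permutation(len(a))
        pa = "".join(a[i] for i in perm)
        pb = "".join(b[i] for i in perm)
        assert p_distance(pa, pb) == pytest.approx(p_distance(a, b))


class TestDistanceMatrix:
    def test_identical_rows(self):
        aln = CoiAlignment(taxa=["a", "b"], rows=["ACGT", "ACGT"])
        dm = distance_matrix(aln)
        assert np.allclose(dm.d, 0.0)

    def test_three_row_hand_count(self):
        aln = CoiAlignment(
            taxa=["a", "b", "c"],
            rows=["ACGTACGT", "ACGTACGA", "TCGTACGA"],
        )
        dm = distance_matrix(aln)
        assert dm.get("a", "b") == pytest.approx(1 / 8)
        assert dm.get("a", "c") == pytest.approx(2 / 8)
        assert dm.get("b", "c") == pytest.approx(1 / 8)

    def test_complete_deletion_drops_gapped_columns(self):
        aln = CoiAlignment(
            taxa=["a", "b", "c"],
            rows=["ACGT", "AC-T", "ACGA"],
        )
        pairwise = distance_matrix(aln)
        complete = distance_matrix(aln, complete_deletion=True)
        # column 2 removed for everyone; column 3 mismatch a/c remains
        assert complete.get("a", "c") == pytest.approx(1 / 3)
        assert pairwise.get("a", "c") == pytest.approx(1 / 4)

    def test_alignment_validation(self):
        with pytest.raises(ValueError):
            CoiAlignment(taxa=["a", "a"], rows=["AC", "AC"])
        with pytest.raises(ValueError):
            CoiAlignment(taxa=["a", "b"], rows=["AC", "ACG"])


class TestGroupRange:
    def _dm(self):
        d = np.array(
            [
                [0.0, 0.02, 0.12, 0.14],
                [0.02, 0.0, 0.11, 0.13],
                [0.12, 0.11, 0.0, 0.01],
                [0.14, 0.13, 0.01, 0.0],
            ]
        )
        return DistanceMatrix(taxa=["a1", "a2", "b1", "b2"], d=d)

    def test_cross_group_min_max(self):
        lo, hi = group_range(self._dm(), ["a1", "a2"], ["b1", "b2"])
        assert lo == pytest.approx(0.11)
        assert hi == pytest.approx(0.14)

    def test_singleton_groups(self):
        lo, hi = group_range(self._dm(), ["a1"], ["b2"])
        assert lo == hi == pytest.approx(0.14)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            group_range(self._dm(), ["a1", "b1"], ["b1"])
        with pytest.raises(ValueError):
            group_range(self._dm(), [], ["b1"])


class TestThresholdClusters:
    def test_all_apart_gives_singletons(self):
        d = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])
        dm = DistanceMatrix(taxa=["a", "b", "c"], d=d)
        assert threshold_clusters(dm, 0.03) == [["a"], ["b"], ["c"]]

    def test_single_linkage_chain(self):
        d = np.array(
            [[0.0, 0.02, 0.04], [0.02, 0.0, 0.02], [0.04, 0.02, 0.0]]
        )
        dm = DistanceMatrix(taxa=["a", "b", "c"], d=d)
        assert threshold_clusters(dm, 0.03) == [["a", "b", "c"]]

    def test_cutoff_one_would_merge_everything(self):
        d = np.array([[0.0, 0.9], [0.9, 0.0]])
        dm = DistanceMatrix(taxa=["a", "b"], d=d)
        assert threshold_clusters(dm, 0.999) == [["a", "b"]]

    def test_cutoff_validation(self):
        d = np.zeros((2, 2))
        dm = DistanceMatrix(taxa=["a", "b"], d=d)
        with pytest.raises(ValueError):
            threshold_clusters(dm, 0.0)
        with pytest.raises(ValueError):
            threshold_clusters(dm, 1.0)


class TestNjTree:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> pairwise path lengths
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 5.0, 7.0, 8.0],
                [5.0, 0.0, 8.0, 9.0],
                [7.0, 8.0, 0.0, 9.0],
                [8.0, 9.0, 9.0, 0.0],
            ]
        ) / 10.0  # scale into [0, 1] to satisfy the p-distance container
        dm = DistanceMatrix(taxa=taxa, d=d)
        tips = _tip_distances(nj_tree(dm))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if a != b:
                    assert tips[(a, b)] == pytest.approx(d[i, j], abs=1e-9)

    def test_three_taxon_star_closed_form(self):
        d = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.4], [0.4, 0.4, 0.0]])
        dm = DistanceMatrix(taxa=["A", "B", "C"], d=d)
        tips = _tip_distances(nj_tree(dm))
        assert tips[("A", "B")] == pytest.approx(0.2, abs=1e-9)
        assert tips[("A", "C")] == pytest.approx(0.4, abs=1e-9)
        assert tips[("B", "C")] == pytest.approx(0.4, abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(taxa=["a", "b"], d=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            nj_tree(dm)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=10)
    def test_random_additive_metrics_recovered(self, seed):
        labels, dist = random_additive_tree(6, seed)
        scale = max(dist.values()) or 1.0
        n = len(labels)
        d = np.array(
            [[dist[(a, b)] / scale for b in labels] for a in labels]
        )
        dm = DistanceMatrix(taxa=labels, d=d)
        tips = _tip_distances(nj_tree(dm))
        for a in labels:
            for b in labels:
                if a != b:
                    assert tips[(a, b)] == pytest.approx(
                        dist[(a, b)] / scale, abs=1e-9
                    )

    def test_agrees_with_skbio_topology(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        labels, dist = random_additive_tree(8, 42)
        scale = max(dist.values())
        d = np.array(
            [[dist[(a, b)] / scale for b in labels] for a in labels]
        )
        ours = _tip_distances(nj_tree(DistanceMatrix(taxa=labels, d=d)))
        theirs_tree = skbio_nj(SkbioDM(d, ids=labels))
        theirs = theirs_tree.tip_tip_distances()
        for a in labels:
            for b in labels:
                if a != b:
                    assert ours[(a, b)] == pytest.approx(
                        theirs[a, b], abs=1e-6
                    )


class TestMisidentificationFlag:
    def test_mislabeled_sequence_flagged(self):
        # x sits inside the "lucens" cluster but carries the label "gerlachei"
        taxa = ["l1", "l2", "x", "p1", "p2"]
        base = np.array(
            [
                [0.0, 0.01, 0.01, 0.13, 0.13],
                [0.01, 0.0, 0.01, 0.13, 0.13],
                [0.01, 0.01, 0.0, 0.13, 0.13],
                [0.13, 0.13, 0.13, 0.0, 0.01],
                [0.13, 0.13, 0.13, 0.01, 0.0],
            ]
        )
        dm = DistanceMatrix(taxa=taxa, d=base)
        labels = {
            "l1": "lucens",
            "l2": "lucens",
            "x": "gerlachei",
            "p1": "pacifica",
            "p2": "pacifica",
        }
        flags = flag_misidentified(dm, labels, cutoff=0.03)
        assert flags == [("x", "gerlachei", "lucens")]

    def test_consistent_labels_not_flagged(self):
        taxa = ["l1", "l2", "p1", "p2"]
        d = np.array(
            [
                [0.0, 0.01, 0.13, 0.13],
                [0.01, 0.0, 0.13, 0.13],
                [0.13, 0.13, 0.0, 0.01],
                [0.13, 0.13, 0.01, 0.0],
            ]
        )
        dm = DistanceMatrix(taxa=taxa, d=d)
        labels = {"l1": "a", "l2": "a", "p1": "b", "p2": "b"}
        assert flag_misidentified(dm, labels, cutoff=0.03) == []
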