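import numpy as np
import pytest

from gagmap.poses import (
    NOISE,
    ClusterParams,
    ClusterResult,
    Pose,
    classify_orientation,
    cluster_loop_conformations,
    cluster_representatives,
    dbscan_cluster,
    filter_bound_poses,
    pairwise_rmsd,
    pose_distance_matrix,
    rmsatd,
)
from gagmap.structio import AtomRecord, ResidueKey, StructureEnsemble
from gagmap.synth import PoseSpec, SynthSpec, gen_pose_set, gen_toy_complex_ensemble

from _oracles import (
    dbscan_labels_compatible,
    exhaustive_rmsatd,
    labels_agree_up_to_permutation,
    sklearn_dbscan_labels,
)


def _pose(coords, elements=None, keys=None):
    coords = np.asarray(coords, float)
    elements = elements or ["C"] * len(coords)
    atoms = [
        AtomRecord(i + 1, f"{el}{i}", el, c) for i, (el, c) in enumerate(zip(elements, coords))
    ]
    if keys is None:
        keys = [ResidueKey("B", 101, "SGN", "glycan")] * len(atoms)
    return Pose(atoms=atoms, residue_keys=keys)


def _random_pose(rng, n=10, elements=None):
    return _pose(rng.normal(size=(n, 3)) * 3, elements=elements)


class TestRmsd:
    def test_identical_poses_zero(self):
        rng = np.random.default_rng(0)
        p = _random_pose(rng)
        assert pairwise_rmsd(p, p) == 0.0

    def test_translation_three_angstrom(self):
        rng = np.random.default_rng(1)
        p = _random_pose(rng)
        q = _pose(p.coords + [3.0, 0.0, 0.0])
        assert pairwise_rmsd(p, q) == pytest.approx(3.0, abs=1e-12)
        assert pairwise_rmsd(p, q, superpose=True) == pytest.approx(0.0, abs=1e-7)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        p, q = _random_pose(rng), _random_pose(rng)
        direct = np.sqrt(np.mean(np.sum((p.coords - q.coords) ** 2, axis=1)))
        assert pairwise_rmsd(p, q) == pytest.approx(float(direct), rel=1e-12)

    def test_count_mismatch_errors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_rmsd(_random_pose(rng, 5), _random_pose(rng, 6))


class TestRmsatd:
    def test_permuted_order_within_types_is_zero(self):
        rng = np.random.default_rng(4)
        elements = ["C", "C", "O", "O", "N", "C"]
        p = _random_pose(rng, 6, elements)
        perm = [1, 0, 3, 2, 4, 5]  # swaps within element classes only
        q = _pose(p.coords[perm], elements=[elements[i] for i in perm])
        assert rmsatd(p, q) == pytest.approx(0.0, abs=1e-12)

    def test_crossed_pairing_found(self):
        # two atoms of one type where the crossed pairing is nearer
        p = _pose([[0, 0, 0], [10, 0, 0]], ["S", "S"])
        q = _pose([[9, 0, 0], [1, 0, 0]], ["S", "S"])
        by_index = pairwise_rmsd(p, q)
        crossed = rmsatd(p, q)
        assert crossed == pytest.approx(1.0, abs=1e-12)
        assert by_index == pytest.approx(9.0, abs=1e-12)

    def test_matches_exhaustive_minimum_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n_c = rng.integers(1, 5)
            n_o = rng.integers(1, 4)
            elements = ["C"] * n_c + ["O"] * n_o
            p = _random_pose(rng, len(elements), elements)
            q = _random_pose(rng, len(elements), elements)
            expected = exhaustive_rmsatd(p.coords, q.coords, elements, elements)
            assert rmsatd(p, q) == pytest.approx(expected, rel=1e-10)

    def test_never_exceeds_ordered_rmsd(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            elements = ["C"] * 4 + ["O"] * 3
            p = _random_pose(rng, 7, elements)
            q = _random_pose(rng, 7, elements)
            assert rmsatd(p, q) <= pairwise_rmsd(p, q) + 1e-12

    def test_symmetric(self):
        rng = np.random.default_rng(7)
        elements = ["C", "C", "N"]
        p = _random_pose(rng, 3, elements)
        q = _random_pose(rng, 3, elements)
        assert rmsatd(p, q) == pytest.approx(rmsatd(q, p), rel=1e-12)

    def test_unequal_counts_reported(self):
        p = _pose([[0, 0, 0], [1, 0, 0]], ["C", "C"])
        q = _pose([[0, 0, 0]], ["C"])
        value, details = rmsatd(p, q, return_details=True)
        assert details["unmatched"] == {"C": 1}
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_no_common_elements_errors(self):
        with pytest.raises(ValueError, match="element"):
            rmsatd(_pose([[0, 0, 0]], ["C"]), _pose([[0, 0, 0]], ["O"]))


class TestOrientation:
    def _chain_pose(self, direction):
        direction = np.asarray(direction, float)
        keys = []
        coords = []
        for j in range(1, 3):
            key = ResidueKey("B", 100 + j, "SGN" if j == 1 else "IDS", "glycan")
            base = direction * 9.0 * (j - 1)
            for off in ([0, 0, 0], [0.5, 0, 0], [0, 0.5, 0]):
                keys.append(key)
                coords.append(base + off)
        from gagmap.structio import GlycanAnnotation, GlycanRing

        ann = GlycanAnnotation(
            rings=[
                GlycanRing(key=ResidueKey("B", 101, "SGN", "glycan"), ring_type="GlcNS",
                           sulfation=frozenset(), ring_index=1),
                GlycanRing(key=ResidueKey("B", 102, "IDS", "glycan"), ring_type="IdoA2S",
                           sulfation=frozenset({"2S"}), ring_index=2),
            ]
        )
        return _pose(coords, keys=keys), ann

    @pytest.mark.parametrize(
        "direction,expected",
        [
            ([1, 0, 0], "parallel"),
            ([-1, 0, 0], "antiparallel"),
            ([0, 1, 0], "perpendicular"),
        ],
    )
    def test_cardinal_directions(self, direction, expected):
        pose, ann = self._chain_pose(direction)
        assert classify_orientation(pose, np.array([1.0, 0, 0]), ann) == expected

    def test_invariant_under_joint_rotation(self):
        from scipy.spatial.transform import Rotation

        pose, ann = self._chain_pose([1, 0, 0])
        rot = Rotation.from_euler("xyz", [33, -51, 140], degrees=True)
        rotated = _pose(rot.apply(pose.coords), keys=pose.residue_keys)
        ref = rot.apply(np.array([1.0, 0, 0]))
        assert classify_orientation(rotated, ref, ann) == "parallel"


class TestBoundFilter:
    def test_nine_kept_eleven_discarded(self):
        anchor = np.zeros(3)
        near = _pose([[9.0, 0, 0]])
        far = _pose([[11.0, 0, 0]])
        kept = filter_bound_poses([near, far], anchor, 10.0)
        assert kept == [near]

    def test_subset_preserving_order(self):
        rng = np.random.default_rng(8)
        poses = [_pose(rng.normal(scale=15.0, size=(4, 3))) for _ in range(30)]
        anchor = np.zeros(3)
        kept = filter_bound_poses(poses, anchor, 10.0)
        # brute-force oracle
        expected = [
            p for p in poses
            if min(np.linalg.norm(c - anchor) for c in p.coords) <= 10.0
        ]
        assert kept == expected


class TestDbscan:
    def test_single_point_is_noise(self):
        result = dbscan_cluster(np.zeros((1, 1)), ClusterParams(1.0, 2))
        assert result.labels.tolist() == [NOISE]

    def test_two_well_separated_blobs(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(50, 0.3, (10, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        result = dbscan_cluster(d, ClusterParams(3.0, 4))
        assert result.n_clusters() == 2
        assert NOISE not in result.labels
        assert sorted(result.populations.values()) == [10, 10]

    def test_asymmetric_matrix_errors(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            dbscan_cluster(d, ClusterParams(1.0, 2))

    def test_permutation_invariance_up_to_relabelling(self):
        rng = np.random.default_rng(10)
        pts = np.vstack([rng.normal(0, 0.5, (8, 3)), rng.normal(30, 0.5, (8, 3)),
                         rng.uniform(100, 200, (4, 3))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        base = dbscan_cluster(d, ClusterParams(3.0, 3))
        perm = rng.permutation(len(pts))
        permuted = dbscan_cluster(d[np.ix_(perm, perm)], ClusterParams(3.0, 3))
        assert labels_agree_up_to_permutation(base.labels[perm], permuted.labels)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 10, (60, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        for eps in (0.8, 1.5, 2.5):
            for minpts in (2, 4, 6):
                ours = dbscan_cluster(d, ClusterParams(eps, minpts)).labels
                ref = sklearn_dbscan_labels(d, eps, minpts)
                assert dbscan_labels_compatible(d, eps, minpts, ours, ref)

    def test_planted_pose_clusters_recovered(self):
        pose_set = gen_pose_set(SynthSpec(seed=14))
        d = pose_distance_matrix(pose_set.poses)
        result = dbscan_cluster(d, ClusterParams(3.0, 4))
        assert labels_agree_up_to_permutation(pose_set.true_labels, result.labels)


class TestRepresentatives:
    def test_singleton_cluster(self):
        d = np.zeros((1, 1))
        result = ClusterResult(labels=np.array([0]), populations={0: 1})
        assert cluster_representatives(result, d) == {0: 0}

    def test_middle_of_three_collinear_points(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        d = np.abs(pts - pts.T)
        result = ClusterResult(labels=np.array([0, 0, 0]), populations={0: 3})
        assert cluster_representatives(result, d) == {0: 1}

    def test_matches_exhaustive_medoid_search(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(20, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = np.array([0] * 10 + [1] * 10)
        result = ClusterResult(labels=labels, populations={0: 10, 1: 10})
        reps = cluster_representatives(result, d)
        for c in (0, 1):
            members = np.nonzero(labels == c)[0]
            best = min(members, key=lambda i: (d[i, members].sum(), i))
            assert reps[c] == best


class TestLoopClustering:
    def test_identical_frames_single_cluster(self):
        toy = gen_toy_complex_ensemble(
            SynthSpec(seed=15, n_frames=5, jitter_sd=0.0,
                      planted_hbond_pairs=[], planted_hot_pairs=[])
        )
        loops, result = cluster_loop_conformations(
            toy.ensemble, [(1, 3)], ClusterParams(0.5, 2)
        )
        assert len(loops) == 1
        assert loops[0].population == 5
        assert loops[0].representative_frame == 0

    def test_three_planted_conformers_recovered(self):
        toy = gen_toy_complex_ensemble(
            SynthSpec(seed=16, n_frames=30, jitter_sd=0.0,
                      planted_hbond_pairs=[], planted_hot_pairs=[])
        )
        ens = toy.ensemble
        # plant 3 loop conformers: shift residues 1-3 by a per-conformer offset
        # deform the loop internally (move residue 1 only, within the 1-3 loop)
        # so the conformers differ after superposition, not by a rigid shift
        res_idx = ens.residue_atom_indices()
        sel = res_idx[ens.protein_residues()[0].key]
        truth = np.array([f % 3 for f in range(ens.n_frames)])
        offsets = {0: [0, 0, 0], 1: [4.0, 0, 0], 2: [0, 4.0, 0]}
        frames = ens.frames.copy()
        for f in range(ens.n_frames):
            frames[f][sel] += offsets[truth[f]]
        planted = StructureEnsemble(residues=ens.residues, frames=frames)
        loops, result = cluster_loop_conformations(
            planted, [(1, 3)], ClusterParams(0.92, 2), top_n=10
        )
        assert len(loops) == 3
        assert labels_agree_up_to_permutation(truth, result.labels)
        assert sorted(l.population for l in loops) == [10, 10, 10]

    def test_missing_residue_errors_by_name(self, toy_complex):
        with pytest.raises(ValueError, match="999"):
            cluster_loop_conformations(
                toy_complex.ensemble, [(999, 999)], ClusterParams(1.0, 2)
            )

    def test_top_n_larger_than_cluster_count(self, toy_complex):
        loops, result = cluster_loop_conformations(
            toy_complex.ensemble, [(1, 2)], ClusterParams(5.0, 2), top_n=50
        )
        assert len(loops) == result.n_clusters()


class TestPoseGenerator:
    def test_unbound_fraction_removed_exactly(self):
        pose_set = gen_pose_set(SynthSpec(seed=17))
        kept = filter_bound_poses(pose_set.poses, pose_set.anchor, 10.0)
        assert len(kept) == 70
        assert int(pose_set.bound.sum()) == 70

    def test_zero_spread_collapses_clusters(self):
        spec = SynthSpec(seed=18, pose_spec=PoseSpec(within_sd=0.0, unbound_fraction=0.0))
        pose_set = gen_pose_set(spec)
        d = pose_distance_matrix(pose_set.poses)
        for c in range(3):
            members = np.nonzero(pose_set.true_labels == c)[0]
            assert np.allclose(d[np.ix_(members, members)], 0.0, atol=1e-9)

    def test_loop_superposition_rotation_invariance(self):
        # rotating every frame rigidly must not split loop clusters
        from scipy.spatial.transform import Rotation

        toy = gen_toy_complex_ensemble(
            SynthSpec(seed=19, n_frames=8, planted_hbond_pairs=[], planted_hot_pairs=[])
        )
        ens = toy.ensemble
        rng = np.random.default_rng(20)
        frames = np.array(
            [Rotation.random(rng=rng).apply(f) + rng.normal(scale=5.0, size=3)
             for f in ens.frames]
        )
        rotated = StructureEnsemble(residues=ens.residues, frames=frames)
        loops, _ = cluster_loop_conformations(rotated, [(1, 5)], ClusterParams(0.5, 2))
        assert len(loops) == 1 and loops[0].population == 8
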