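"""Pose geometry metrics and density-based clustering.

Covers the geometric side of multipose docking analysis: plain and
superposed RMSD, atom-type-matched RMSD (RMSatd — atoms paired within each
chemical element by optimal assignment rather than by index), ligand
orientation relative to a reference axis, the bound-pose distance filter,
and DBSCAN clustering of poses or binding-loop conformations with medoid
representatives.

DBSCAN conventions here (implementations differ, so they are fixed):
a point's ε-neighbourhood includes the point itself, so ``minpoints = 2``
means "at least one other point within ε"; border points join the first
core cluster that reaches them in an ascending-index scan; unreachable
non-core points are noise (label −1).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structio import AtomRecord, GlycanAnnotation, ResidueKey, StructureEnsemble

__all__ = [
    "NOISE",
    "Pose",
    "ClusterParams",
    "ClusterResult",
    "pairwise_rmsd",
    "rmsatd",
    "classify_orientation",
    "filter_bound_poses",
    "pose_distance_matrix",
    "dbscan_cluster",
    "cluster_representatives",
    "cluster_loop_conformations",
    "LoopCluster",
    "poses_from_ensemble",
    "write_cluster_result",
]

NOISE = -1


@dataclass
class Pose:
    """One ligand pose: atoms with coordinates, parallel residue keys, and an
    optional score (kcal/mol, more negative = better)."""

    atoms: list[AtomRecord]
    residue_keys: list[ResidueKey]
    score: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a pose needs at least one atom")
        if len(self.residue_keys) != len(self.atoms):
            raise ValueError("residue_keys must parallel atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=int)


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters in distance-matrix space (Å)."""

    epsilon: float
    minpoints: int

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.minpoints < 1:
            raise ValueError("minpoints must be >= 1")


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-item cluster id, NOISE (-1) for noise
    populations: dict[int, int]
    representatives: dict[int, int] = field(default_factory=dict)

    def n_clusters(self) -> int:
        return len(self.populations)

    def clusters_by_population(self) -> list[int]:
        """Cluster ids, most populated first; ties by lowest id."""
        return sorted(self.populations, key=lambda c: (-self.populations[c], c))


# ---------------------------------------------------------------------------
# Geometry metrics
# ---------------------------------------------------------------------------

def _kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares superposed RMSD of two (n, 3) coordinate sets."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    _, rssd = Rotation.align_vectors(xc, yc)
    return float(rssd / np.sqrt(len(x)))


def pairwise_rmsd(a: Pose, b: Pose, superpose: bool = False) -> float:
    """RMSD over ordered atom pairs; optional least-squares superposition."""
    if len(a.atoms) != len(b.atoms):
        raise ValueError(f"atom count mismatch: {len(a.atoms)} vs {len(b.atoms)}")
    x, y = a.coords, b.coords
    if superpose:
        return _kabsch_rmsd(x, y)
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def rmsatd(a: Pose, b: Pose, return_details: bool = False):
    """Atom-type-matched RMSD.

    Within each chemical element, atoms of ``a`` are paired one-to-one with
    atoms of ``b`` by minimum total squared distance (optimal assignment, not
    greedy); the RMSatd is the RMS over all matched pairs.  When the two
    poses carry unequal counts of some element, the surplus atoms are left
    unmatched and reported in the details.
    """
    by_el_a: dict[str, list[int]] = {}
    by_el_b: dict[str, list[int]] = {}
    for i, at in enumerate(a.atoms):
        by_el_a.setdefault(at.element.upper(), []).append(i)
    for i, at in enumerate(b.atoms):
        by_el_b.setdefault(at.element.upper(), []).append(i)
    common = sorted(set(by_el_a) & set(by_el_b))
    if not common:
        raise ValueError("poses share no chemical element types")

    xa, xb = a.coords, b.coords
    sq_sum = 0.0
    n_matched = 0
    unmatched: dict[str, int] = {}
    matches: list[tuple[int, int]] = []
    for el in common:
        ia = np.array(by_el_a[el])
        ib = np.array(by_el_b[el])
        d2 = cdist(xa[ia], xb[ib], metric="sqeuclidean")
        rows, cols = linear_sum_assignment(d2)
        sq_sum += float(d2[rows, cols].sum())
        n_matched += len(rows)
        if len(ia) != len(ib):
            unmatched[el] = abs(len(ia) - len(ib))
        matches.extend((int(ia[r]), int(ib[c])) for r, c in zip(rows, cols))
    for el in set(by_el_a) ^ set(by_el_b):
        unmatched[el] = len(by_el_a.get(el, by_el_b.get(el, [])))

    value = float(np.sqrt(sq_sum / n_matched))
    if return_details:
        return value, {"n_matched": n_matched, "unmatched": unmatched, "matches": matches}
    return value


def _ring_centroid(pose: Pose, key: ResidueKey) -> np.ndarray:
    idx = [
        i
        for i, (k, at) in enumerate(zip(pose.residue_keys, pose.atoms))
        if k == key and not at.is_hydrogen
    ]
    if not idx:
        raise ValueError(f"pose has no heavy atoms for ring residue {key.label()}")
    return pose.coords[idx].mean(axis=0)


def classify_orientation(
    pose: Pose,
    reference_axis: np.ndarray,
    annotation: GlycanAnnotation,
    parallel_max: float = 45.0,
    antiparallel_min: float = 135.0,
) -> str:
    """Classify the ligand axis against a reference direction.

    The ligand axis runs from the first (non-reducing) to the last ring heavy
    -atom centroid.  Angle θ to the reference: θ ≤ 45° parallel, θ ≥ 135°
    antiparallel, otherwise perpendicular (thresholds configurable).
    """
    if annotation.dp < 2:
        raise ValueError("orientation needs at least 2 rings")
    ring_res = annotation.residue_of_ring()
    first = _ring_centroid(pose, ring_res[1])
    last = _ring_centroid(pose, ring_res[annotation.dp])
    axis = last - first
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("coincident first/last ring centroids; ligand axis undefined")
    ref = np.asarray(reference_axis, dtype=float)
    rnorm = np.linalg.norm(ref)
    if rnorm == 0:
        raise ValueError("zero reference axis")
    cos = float(np.clip(np.dot(axis / norm, ref / rnorm), -1.0, 1.0))
    theta = np.degrees(np.arccos(cos))
    if theta <= parallel_max:
        return "parallel"
    if theta >= antiparallel_min:
        return "antiparallel"
    return "perpendicular"


def filter_bound_poses(
    poses: list[Pose],
    anchor: np.ndarray,
    cutoff: float = 10.0,
    annotation: GlycanAnnotation | None = None,
) -> list[Pose]:
    """Keep poses with at least one sugar heavy atom within ``cutoff`` Å of the
    anchor point (e.g. the Cα of a marker binding-site residue), preserving
    input order.  With an annotation, only atoms of annotated ring residues
    count; otherwise every heavy ligand atom does."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    anchor = np.asarray(anchor, dtype=float)
    allowed = set(r.key for r in annotation.rings) if annotation is not None else None
    kept = []
    for pose in poses:
        idx = [
            i
            for i, (k, at) in enumerate(zip(pose.residue_keys, pose.atoms))
            if not at.is_hydrogen and (allowed is None or k in allowed)
        ]
        if not idx:
            continue
        d = np.linalg.norm(pose.coords[idx] - anchor, axis=1)
        if float(d.min()) <= cutoff:
            kept.append(pose)
    return kept


def pose_distance_matrix(poses: list[Pose], metric: str = "rmsd", superpose: bool = False) -> np.ndarray:
    """Symmetric pose-pose distance matrix (``rmsd`` or ``rmsatd``)."""
    n = len(poses)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "rmsd":
                v = pairwise_rmsd(poses[i], poses[j], superpose=superpose)
            elif metric == "rmsatd":
                v = rmsatd(poses[i], poses[j])
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = v
    return d


# ---------------------------------------------------------------------------
# DBSCAN on a precomputed distance matrix
# ---------------------------------------------------------------------------

def dbscan_cluster(distance_matrix: np.ndarray, params: ClusterParams) -> ClusterResult:
    """Density-based clustering with the conventions in the module docstring."""
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    neighbors = [np.nonzero(d[i] <= params.epsilon)[0] for i in range(n)]
    core = np.array([len(nb) >= params.minpoints for nb in neighbors])

    labels = np.full(n, NOISE, dtype=int)
    cid = 0
    for seed in range(n):
        if labels[seed] != NOISE or not core[seed]:
            continue
        labels[seed] = cid
        queue = deque([seed])
        while queue:
            p = queue.popleft()
            for q in neighbors[p]:
                if labels[q] == NOISE:
                    labels[q] = cid
                    if core[q]:
                        queue.append(q)
        cid += 1

    populations = {c: int((labels == c).sum()) for c in range(cid)}
    result = ClusterResult(labels=labels, populations=populations)
    result.representatives = cluster_representatives(result, d)
    return result


def cluster_representatives(result: ClusterResult, distance_matrix: np.ndarray) -> dict[int, int]:
    """Medoid per cluster: the member minimizing summed in-cluster distance;
    ties go to the lowest index."""
    d = np.asarray(distance_matrix, dtype=float)
    reps: dict[int, int] = {}
    for c in result.populations:
        members = np.nonzero(result.labels == c)[0]
        sums = d[np.ix_(members, members)].sum(axis=1)
        reps[c] = int(members[int(np.argmin(sums))])
    return reps


# ---------------------------------------------------------------------------
# Binding-loop conformation clustering
# ---------------------------------------------------------------------------

@dataclass
class LoopCluster:
    cluster_id: int
    population: int
    representative_frame: int


def cluster_loop_conformations(
    ensemble: StructureEnsemble,
    loop_residues: list[tuple[int, int]],
    params: ClusterParams,
    top_n: int = 10,
) -> tuple[list[LoopCluster], ClusterResult]:
    """Cluster binding-loop conformations across frames.

    ``loop_residues`` lists inclusive residue-number ranges (e.g.
    ``[(17, 19), (112, 114), (118, 122), (126, 129)]``).  Frames are compared
    by loop-heavy-atom RMSD after pairwise least-squares superposition on
    those same atoms, clustered with DBSCAN, and the medoids of the ``top_n``
    most populated clusters are returned (descending population, ties by
    lowest cluster id).
    """
    wanted = set()
    for lo, hi in loop_residues:
        wanted.update(range(lo, hi + 1))
    res_idx = ensemble.residue_atom_indices()
    atoms = ensemble.atoms
    sel: list[int] = []
    present: set[int] = set()
    for res in ensemble.protein_residues():
        if res.key.resnum in wanted:
            present.add(res.key.resnum)
            sel.extend(i for i in res_idx[res.key] if not atoms[i].is_hydrogen)
    missing = sorted(wanted - present)
    if missing:
        raise ValueError(f"loop residue(s) missing from the topology: {missing}")

    sel_arr = np.array(sel, dtype=int)
    nf = ensemble.n_frames
    d = np.zeros((nf, nf))
    for i in range(nf):
        for j in range(i + 1, nf):
            d[i, j] = d[j, i] = _kabsch_rmsd(
                ensemble.frames[i][sel_arr], ensemble.frames[j][sel_arr]
            )
    result = dbscan_cluster(d, params)
    ordered = result.clusters_by_population()[:top_n]
    loops = [
        LoopCluster(
            cluster_id=c,
            population=result.populations[c],
            representative_frame=result.representatives[c],
        )
        for c in ordered
    ]
    return loops, result


# ---------------------------------------------------------------------------
# Pose I/O helpers
# ---------------------------------------------------------------------------

def poses_from_ensemble(ensemble: StructureEnsemble, glycan_only: bool = True,
                        scores: list[float] | None = None) -> list[Pose]:
    """One pose per frame, taking the (glycan) ligand atoms of each model —
    the natural reading of a multi-model PDB of docking solutions."""
    residues = ensemble.glycan_residues() if glycan_only else ensemble.residues
    res_idx = ensemble.residue_atom_indices()
    idx = np.concatenate([res_idx[r.key] for r in residues])
    keys = [r.key for r in residues for _ in res_idx[r.key]]
    template = [ensemble.atoms[i] for i in idx]
    poses = []
    for f in range(ensemble.n_frames):
        frame_atoms = [
            AtomRecord(
                serial=a.serial,
                name=a.name,
                element=a.element,
                coords=ensemble.frames[f][i],
                partial_charge=a.partial_charge,
                lj_rmin_half=a.lj_rmin_half,
                lj_epsilon=a.lj_epsilon,
                bonded_hydrogens=list(a.bonded_hydrogens),
            )
            for a, i in zip(template, idx)
        ]
        poses.append(
            Pose(
                atoms=frame_atoms,
                residue_keys=list(keys),
                score=None if scores is None else scores[f],
                source=f"model {f}",
            )
        )
    return poses


def write_cluster_result(result: ClusterResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("item\tlabel\tis_representative\n")
        reps = set(result.representatives.values())
        for i, label in enumerate(result.labels):
            fh.write(f"{i}\t{int(label)}\t{int(i in reps and label != NOISE)}\n")
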