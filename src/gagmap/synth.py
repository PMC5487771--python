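"""Synthetic fixtures with known ground truth.

Every generator here returns its planted truth alongside the data, so tests
never re-infer truth from the data they are checking.  The toy complexes are
geometric, not physical: protein residues are four-atom fragments (backbone
carbon, an amide-like donor N-H, and a charged side-chain nitrogen) lining a
pocket, and glycan rings are four-atom fragments (two ring carbons, a
hydroxyl-like acceptor oxygen and a charged sulfate/carboxylate oxygen) on a
chain running non-reducing -> reducing.  The fragments exist to exercise the
geometric H-bond criteria and the pairwise energy definitions, not to fold
plausibly.

Planted H-bond occupancies are realised by toggling the donor group in or
out of the 3.0 Å / 135° window per frame — Bernoulli per frame by default
(matching a time-fraction statistic), with an exact deterministic mode and a
Markov-switching stress mode.  Planted hot energy pairs are realised by
placing opposite charges across the interface and calibrating the
side-chain charge so the pair's electrostatic energy lands near the
requested mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModelParams, atom_pair_energies
from .hbond import HBondOccupancyTable
from .poses import Pose
from .ranking import DeltaGSamples
from .structio import (
    RING_RESNAMES,
    AtomRecord,
    GlycanAnnotation,
    GlycanRing,
    PairEnergy,
    PairEnergyTable,
    Residue,
    ResidueKey,
    StructureEnsemble,
    parse_glycan_pattern,
)

__all__ = [
    "PoseSpec",
    "DeltaGSpec",
    "SynthSpec",
    "ToyComplex",
    "PoseSet",
    "DecompFixture",
    "gen_toy_complex_ensemble",
    "gen_pose_set",
    "gen_decomp_fixture",
    "gen_deltaG_samples",
]

_RING_SPACING = 9.0  # Å between ring centroids along the chain axis
_PROTEIN_RESNAMES = ["LYS", "ARG", "ASN", "GLN", "SER", "THR", "HIS", "GLY", "ALA", "GLU"]
_MIN_ATOM_SEPARATION = 0.8  # Å; closer contacts are an infeasible geometry
_MAX_RETRIES = 5


@dataclass(frozen=True)
class PoseSpec:
    """Planted docking-pose ensemble structure.

    ``center_spread`` is a floor on the separation of cluster centers in
    pose-RMSD space; clusters are realised as distinct rigid placements near
    the anchor so every clustered pose stays bound.
    """

    n_clusters: int = 3
    n_poses: int = 100
    center_spread: float = 20.0
    within_sd: float = 0.5
    unbound_fraction: float = 0.3
    bound_cutoff: float = 10.0


@dataclass(frozen=True)
class DeltaGSpec:
    """Planted per-ligand binding free-energy distributions (kcal/mol).

    Defaults emulate five derivatives with affinities spaced 5 kcal/mol at
    SD 10 and 100 values per ligand (per grouping when grouped).
    """

    labels: tuple[str, ...] = ("HE1", "HE2", "HE3", "HE4", "HE5")
    means: tuple[float, ...] = (-60.0, -55.0, -50.0, -45.0, -40.0)
    sd: float = 10.0
    n: int = 100
    n_groups: int | None = None


@dataclass
class SynthSpec:
    """Master knob set for all generators; deterministic for a fixed seed."""

    seed: int = 0
    n_protein_residues: int = 10
    glycan_pattern: str = "GlcNS6S-IdoA2S-GlcNS6S-IdoA2S-GlcNS6S-IdoA2S"
    n_frames: int = 100
    planted_hbond_pairs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(1, 1, 0.9), (3, 2, 0.8), (5, 3, 0.6), (7, 4, 0.4), (9, 5, 0.2)]
    )
    planted_hot_pairs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(1, 1, -8.0), (3, 2, -8.0), (5, 3, -8.0), (7, 4, -8.0), (9, 5, -8.0)]
    )
    noise_sd: float = 1.0
    occupancy_mode: str = "bernoulli"  # "bernoulli" | "exact" | "markov"
    markov_persistence: float = 0.8
    jitter_sd: float = 0.02
    pose_spec: PoseSpec = field(default_factory=PoseSpec)
    deltaG_spec: DeltaGSpec = field(default_factory=DeltaGSpec)

    def __post_init__(self) -> None:
        for _, _, occ in self.planted_hbond_pairs:
            if not 0.0 <= occ <= 1.0:
                raise ValueError("planted occupancies must lie in [0, 1]")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.occupancy_mode not in ("bernoulli", "exact", "markov"):
            raise ValueError(f"unknown occupancy mode {self.occupancy_mode!r}")


@dataclass
class PlantedHBond:
    protein_key: ResidueKey
    ring_index: int
    donor_atom: str
    acceptor_atom: str
    target_occupancy: float
    on_frames: np.ndarray  # boolean per frame


@dataclass
class PlantedHotPair:
    protein_key: ResidueKey
    ring_index: int
    mean_energy: float


@dataclass
class ToyComplex:
    ensemble: StructureEnsemble
    annotation: GlycanAnnotation
    energy_params: EnergyModelParams
    hbond_truth: list[PlantedHBond]
    hot_truth: list[PlantedHotPair]


def _on_frames(rng: np.random.Generator, p: float, n: int, mode: str,
               persistence: float) -> np.ndarray:
    if mode == "bernoulli":
        return rng.random(n) < p
    if mode == "exact":
        k = int(round(p * n))
        on = np.zeros(n, dtype=bool)
        if k > 0:
            on[np.rint(np.linspace(0, n - 1, k)).astype(int)] = True
        return on
    # two-state Markov chain with stationary probability p
    on = np.zeros(n, dtype=bool)
    state = rng.random() < p
    # switching rates preserving stationarity: P(off->on) = (1-a) p / (1-p)-free form
    stay = persistence
    for i in range(n):
        on[i] = state
        if state:
            state = rng.random() < stay + (1 - stay) * p
        else:
            state = rng.random() < (1 - stay) * p
    return on


def gen_toy_complex_ensemble(spec: SynthSpec) -> ToyComplex:
    """Build a toy protein-glycan ensemble with planted H-bond occupancies
    and planted hot energy pairs (see module docstring for the geometry)."""
    decoded = parse_glycan_pattern(spec.glycan_pattern)
    dp = len(decoded)
    n_res = spec.n_protein_residues
    hb_map = {(r, g): occ for r, g, occ in spec.planted_hbond_pairs}
    hot_map = {(r, g): e for r, g, e in spec.planted_hot_pairs}
    for (r, g) in list(hb_map) + list(hot_map):
        if not (1 <= r <= n_res):
            raise ValueError(f"planted residue {r} outside 1..{n_res}")
        if not (1 <= g <= dp):
            raise ValueError(f"planted ring {g} outside 1..{dp}")
    ring_of_res = {}
    for (r, g) in list(hb_map) + list(hot_map):
        if ring_of_res.setdefault(r, g) != g:
            raise ValueError(f"residue {r} planted against two different rings")
    res_of_ring: dict[int, int] = {}
    for r, g in ring_of_res.items():
        if res_of_ring.setdefault(g, r) != r:
            raise ValueError(f"ring {g} planted against two different residues")

    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng([spec.seed, 101, attempt])
        toy = _build_toy(spec, decoded, dp, n_res, hb_map, hot_map, ring_of_res, rng)
        if _min_separation(toy.ensemble) >= _MIN_ATOM_SEPARATION:
            return toy
    raise RuntimeError(
        f"infeasible toy geometry: atoms closer than {_MIN_ATOM_SEPARATION} Å "
        f"after {_MAX_RETRIES} attempts"
    )


def _build_toy(spec, decoded, dp, n_res, hb_map, hot_map, ring_of_res, rng) -> ToyComplex:
    serial = [0]

    def new_atom(name, element, coords, q, rmh, eps):
        serial[0] += 1
        return AtomRecord(
            serial=serial[0], name=name, element=element, coords=np.asarray(coords, float),
            partial_charge=q, lj_rmin_half=rmh, lj_epsilon=eps,
        )

    heavy_lj = (1.7, 0.12)
    h_lj = (0.6, 0.0157)
    # donor/acceptor heavy atoms: LJ minimum at the 2.8 Å planted contact, so
    # planted pairs are attractive in the vdW channel too
    contact_lj = (1.4, 0.12)
    born: dict[int, float] = {}

    # --- protein residues --------------------------------------------------
    protein_residues: list[Residue] = []
    res_atoms: dict[int, dict[str, AtomRecord]] = {}
    for i in range(1, n_res + 1):
        resname = _PROTEIN_RESNAMES[(i - 1) % len(_PROTEIN_RESNAMES)]
        key = ResidueKey("A", i, resname, "protein")
        if i in ring_of_res:
            x = (ring_of_res[i] - 1) * _RING_SPACING
            base_y = 0.0
        else:
            x = (i - 1) * _RING_SPACING
            base_y = -30.0  # pocket rim, far from the glycan
        atoms = {
            "CA": new_atom("CA", "C", (x, base_y - 5.8, 0.9), 0.01, *heavy_lj),
            "N": new_atom("N", "N", (x, base_y - 4.3, 0.0), -0.05, *contact_lj),
            "H": new_atom("H", "H", (x, base_y - 3.3, 0.0), 0.05, *h_lj),
            "NZ": new_atom("NZ", "N", (x, base_y - 3.8, -3.4), 0.05, *heavy_lj),
        }
        atoms["N"].bonded_hydrogens = [atoms["H"].serial]
        for name, a in atoms.items():
            born[a.serial] = 1.2 if name == "H" else 1.5
        protein_residues.append(Residue(key=key, atoms=list(atoms.values())))
        res_atoms[i] = atoms

    # --- glycan chain along +x, non-reducing -> reducing -------------------
    glycan_residues: list[Residue] = []
    rings: list[GlycanRing] = []
    ring_atoms: dict[int, dict[str, AtomRecord]] = {}
    for j in range(1, dp + 1):
        c = np.array([(j - 1) * _RING_SPACING, 0.0, 0.0])
        ring_type, flags = decoded[j - 1]
        key = ResidueKey("B", 100 + j, RING_RESNAMES[ring_type], "glycan")
        atoms = {
            "C1": new_atom("C1", "C", c + (-0.7, 0.0, 0.4), 0.01, *heavy_lj),
            "C2": new_atom("C2", "C", c + (0.7, 0.0, 0.4), 0.01, *heavy_lj),
            "OA": new_atom("OA", "O", c + (0.0, -1.5, 0.0), -0.05, *contact_lj),
            "OX": new_atom("OX", "O", c + (0.0, -1.0, -2.2), -0.5, *heavy_lj),
        }
        for a in atoms.values():
            born[a.serial] = 1.5
        glycan_residues.append(Residue(key=key, atoms=list(atoms.values())))
        rings.append(GlycanRing(key=key, ring_type=ring_type, sulfation=flags, ring_index=j))
        ring_atoms[j] = atoms
    annotation = GlycanAnnotation(rings=rings)
    params = EnergyModelParams(born_radii=born)

    # --- calibrate hot-pair side-chain charges -----------------------------
    hot_truth = []
    for (r, g), target in hot_map.items():
        nz, ox = res_atoms[r]["NZ"], ring_atoms[g]["OX"]
        dist = float(np.linalg.norm(nz.coords - ox.coords))
        _, vac_unit, rf_unit = atom_pair_energies(
            _unit_charge(nz, born), _unit_charge(ox, born), dist, params
        )
        ele_unit = vac_unit + rf_unit  # kcal/mol per unit charge product
        nz.partial_charge = target / (ele_unit * ox.partial_charge)
        hot_truth.append(
            PlantedHotPair(protein_key=protein_residues[r - 1].key, ring_index=g,
                           mean_energy=target)
        )

    # --- frames ------------------------------------------------------------
    residues = protein_residues + glycan_residues
    topo_atoms = [a for res in residues for a in res.atoms]
    base = np.array([a.coords for a in topo_atoms])
    index = {a.serial: k for k, a in enumerate(topo_atoms)}

    fixed = set()  # atoms excluded from jitter: planted donor groups + acceptors
    hbond_truth = []
    toggles = []
    for (r, g), occ in hb_map.items():
        on = _on_frames(rng, occ, spec.n_frames, spec.occupancy_mode, spec.markov_persistence)
        n_idx = index[res_atoms[r]["N"].serial]
        h_idx = index[res_atoms[r]["H"].serial]
        oa_idx = index[ring_atoms[g]["OA"].serial]
        fixed.update((n_idx, h_idx, oa_idx))
        toggles.append((n_idx, h_idx, oa_idx, on))
        hbond_truth.append(
            PlantedHBond(
                protein_key=protein_residues[r - 1].key, ring_index=g,
                donor_atom="N", acceptor_atom="OA", target_occupancy=occ, on_frames=on,
            )
        )

    frames = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    if spec.jitter_sd > 0:
        jitter = rng.normal(0.0, spec.jitter_sd, frames.shape)
        jitter[:, sorted(fixed), :] = 0.0
        frames += jitter
    for n_idx, h_idx, oa_idx, on in toggles:
        oa = base[oa_idx]
        direction = base[n_idx] - oa
        direction /= np.linalg.norm(direction)
        n_on = oa + 2.8 * direction
        n_off = oa + 3.6 * direction
        for f in range(spec.n_frames):
            n_pos = n_on if on[f] else n_off
            frames[f, n_idx] = n_pos
            frames[f, h_idx] = n_pos - 1.0 * direction  # on the N->OA line: angle 180°

    ensemble = StructureEnsemble(residues=residues, frames=frames)
    return ToyComplex(
        ensemble=ensemble, annotation=annotation, energy_params=params,
        hbond_truth=hbond_truth, hot_truth=hot_truth,
    )


def _unit_charge(atom: AtomRecord, born: dict[int, float]) -> AtomRecord:
    return AtomRecord(
        serial=atom.serial, name=atom.name, element=atom.element, coords=atom.coords,
        partial_charge=1.0, lj_rmin_half=0.0, lj_epsilon=0.0,
    )


def _min_separation(ensemble: StructureEnsemble) -> float:
    from scipy.spatial.distance import pdist

    return min(float(pdist(ensemble.frames[f]).min()) for f in range(ensemble.n_frames))


# ---------------------------------------------------------------------------
# Docking pose sets
# ---------------------------------------------------------------------------

@dataclass
class PoseSet:
    poses: list[Pose]
    true_labels: np.ndarray  # planted cluster id; -1 for unbound scatter
    bound: np.ndarray  # boolean
    anchor: np.ndarray


def _sphere_dirs(n: int) -> np.ndarray:
    """Deterministic well-spread unit directions (golden-angle spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def _glycan_template(pattern: str) -> tuple[np.ndarray, list[AtomRecord], list[ResidueKey]]:
    decoded = parse_glycan_pattern(pattern)
    atoms: list[AtomRecord] = []
    keys: list[ResidueKey] = []
    serial = 0
    for j, (ring_type, _) in enumerate(decoded, start=1):
        c = np.array([(j - 1) * _RING_SPACING, 0.0, 0.0])
        key = ResidueKey("B", 100 + j, RING_RESNAMES[ring_type], "glycan")
        for name, off in (("C1", (-0.7, 0, 0.4)), ("C2", (0.7, 0, 0.4)),
                          ("OA", (0, -1.5, 0)), ("OX", (0, -1.0, -2.2))):
            serial += 1
            atoms.append(AtomRecord(serial=serial, name=name, element=name[0],
                                    coords=c + np.asarray(off, float)))
            keys.append(key)
    return np.array([a.coords for a in atoms]), atoms, keys


def gen_pose_set(spec: SynthSpec) -> PoseSet:
    """Docking-pose ensemble with planted cluster structure and an unbound tail.

    Bound clusters are distinct rigid placements of the glycan template with
    its non-reducing ring pinned near the anchor (so each clustered pose
    passes the bound filter); cluster membership is blurred with isotropic
    Gaussian coordinate noise.  Unbound poses sit on radial shells well
    beyond the cutoff, mutually separated so they cluster as noise.
    """
    from scipy.spatial.transform import Rotation

    ps = spec.pose_spec
    rng = np.random.default_rng([spec.seed, 202])
    template, atoms, keys = _glycan_template(spec.glycan_pattern)
    ring1_centroid = template[:4][[a.name != "H" for a in atoms[:4]]].mean(axis=0)
    anchor = np.zeros(3)

    n_unbound = int(round(ps.n_poses * ps.unbound_fraction))
    n_bound = ps.n_poses - n_unbound
    sizes = [n_bound // ps.n_clusters] * ps.n_clusters
    for i in range(n_bound % ps.n_clusters):
        sizes[i] += 1

    dirs = _sphere_dirs(max(ps.n_clusters, 4))
    extent = float(np.linalg.norm(template - template.mean(axis=0), axis=1).max())

    poses: list[Pose] = []
    labels: list[int] = []
    bound_flags: list[bool] = []
    for c in range(ps.n_clusters):
        # distinct placement: rotation about z spreads clusters far apart in
        # RMSD space for any chain longer than one ring
        rot = Rotation.from_euler("z", 360.0 * c / ps.n_clusters, degrees=True)
        offset = anchor + dirs[c] * 4.0
        base = rot.apply(template - ring1_centroid) + offset
        for _ in range(sizes[c]):
            coords = base + rng.normal(0.0, ps.within_sd, base.shape)
            poses.append(_make_pose(atoms, keys, coords, rng, source=f"cluster{c}"))
            labels.append(c)
            bound_flags.append(True)
    u_dirs = _sphere_dirs(max(n_unbound, 4))
    for u in range(n_unbound):
        radius = ps.bound_cutoff + 20.0 + 8.0 * u
        rot = Rotation.random(rng=rng)
        center = u_dirs[u] * (radius + extent)
        coords = rot.apply(template - template.mean(axis=0)) + center
        poses.append(_make_pose(atoms, keys, coords, rng, source=f"unbound{u}"))
        labels.append(-1)
        bound_flags.append(False)

    order = rng.permutation(len(poses))
    poses = [poses[i] for i in order]
    labels_arr = np.array(labels)[order]
    bound_arr = np.array(bound_flags)[order]
    _check_pose_set(poses, labels_arr, bound_arr, anchor, ps)
    return PoseSet(poses=poses, true_labels=labels_arr, bound=bound_arr, anchor=anchor)


def _make_pose(atoms, keys, coords, rng, source) -> Pose:
    new_atoms = [
        AtomRecord(serial=a.serial, name=a.name, element=a.element, coords=coords[i])
        for i, a in enumerate(atoms)
    ]
    return Pose(atoms=new_atoms, residue_keys=list(keys),
                score=float(rng.normal(-70.0, 5.0)), source=source)


def _check_pose_set(poses, labels, bound, anchor, ps: PoseSpec) -> None:
    for pose, is_bound in zip(poses, bound):
        dmin = float(np.linalg.norm(pose.coords - anchor, axis=1).min())
        ok = dmin <= ps.bound_cutoff if is_bound else dmin > ps.bound_cutoff
        if not ok:
            raise RuntimeError("pose generator violated its bound/unbound construction")


# ---------------------------------------------------------------------------
# Energy-table fixtures
# ---------------------------------------------------------------------------

@dataclass
class DecompFixture:
    table: PairEnergyTable
    occupancy: HBondOccupancyTable
    annotation: GlycanAnnotation
    hot_pairs: list[tuple[ResidueKey, int]]


def gen_decomp_fixture(spec: SynthSpec, vdw_ele_split: float = 1.6) -> DecompFixture:
    """Planted hot cells on a noisy favorable background, per channel.

    Background cells: −|N(0, noise_sd)| kcal/mol in the electrostatic and
    van der Waals components and low uniform H-bond occupancies; hot cells
    sit at their planted means (default −8 kcal/mol) with matching noise and
    high occupancy.  The vacuum/reaction-field split of the electrostatic
    total uses ``ele_vac = split·total, ele_rf = (1−split)·total``, mimicking
    partial solvent screening of the vacuum term.
    """
    rng = np.random.default_rng([spec.seed, 303])
    decoded = parse_glycan_pattern(spec.glycan_pattern)
    dp = len(decoded)
    rings = [
        GlycanRing(
            key=ResidueKey("B", 100 + j, RING_RESNAMES[decoded[j - 1][0]], "glycan"),
            ring_type=decoded[j - 1][0], sulfation=decoded[j - 1][1], ring_index=j,
        )
        for j in range(1, dp + 1)
    ]
    annotation = GlycanAnnotation(rings=rings)
    protein = [
        ResidueKey("A", i, _PROTEIN_RESNAMES[(i - 1) % len(_PROTEIN_RESNAMES)], "protein")
        for i in range(1, spec.n_protein_residues + 1)
    ]
    hot = {(r, g): e for r, g, e in spec.planted_hot_pairs}

    entries: dict[tuple[ResidueKey, int], PairEnergy] = {}
    occ_entries = {}
    hot_keys: list[tuple[ResidueKey, int]] = []
    for i, key in enumerate(protein, start=1):
        for j in range(1, dp + 1):
            if (i, j) in hot:
                mean = hot[(i, j)]
                ele_total = rng.normal(mean, spec.noise_sd)
                vdw = rng.normal(mean, spec.noise_sd)
                frac = float(rng.uniform(0.75, 0.95))
                hot_keys.append((key, j))
            else:
                ele_total = -abs(rng.normal(0.0, spec.noise_sd))
                vdw = -abs(rng.normal(0.0, spec.noise_sd))
                frac = float(rng.uniform(0.0, 0.15))
            entries[(key, j)] = PairEnergy(
                vdw=float(vdw),
                ele_vac=float(vdw_ele_split * ele_total),
                ele_rf=float((1.0 - vdw_ele_split) * ele_total),
                hbond_fraction=frac,
            )
            ring_key = annotation.residue_of_ring()[j]
            occ_entries[((key, "N"), (ring_key, "OA"))] = frac
    table = PairEnergyTable(entries=entries, provenance="ingested", n_frames_averaged=1)
    occupancy = HBondOccupancyTable(entries=occ_entries, n_frames=spec.n_frames)
    return DecompFixture(table=table, occupancy=occupancy, annotation=annotation,
                         hot_pairs=hot_keys)


# ---------------------------------------------------------------------------
# ΔG sample sets
# ---------------------------------------------------------------------------

def gen_deltaG_samples(spec: SynthSpec) -> tuple[DeltaGSamples, list[str]]:
    """Per-ligand normal ΔG draws at the planted means/SD; returns the samples
    and the true affinity order (strongest binder first).

    With ``n_groups`` set, each grouping gets an independent fresh draw of
    ``n`` values per ligand, emulating per-receptor-conformation docking
    batches.
    """
    dg = spec.deltaG_spec
    if len(dg.labels) != len(dg.means):
        raise ValueError("labels and means length mismatch")
    rng = np.random.default_rng([spec.seed, 404])
    values: dict[str, np.ndarray] = {}
    groups: dict[str, np.ndarray] | None = None
    if dg.n_groups is None:
        for label, mean in zip(dg.labels, dg.means):
            values[label] = rng.normal(mean, dg.sd, dg.n)
    else:
        groups = {}
        for label, mean in zip(dg.labels, dg.means):
            values[label] = rng.normal(mean, dg.sd, dg.n * dg.n_groups)
            groups[label] = np.repeat(np.arange(dg.n_groups), dg.n)
    true_order = [label for _, label in sorted(zip(dg.means, dg.labels))]
    return DeltaGSamples(values=values, groups=groups), true_order
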