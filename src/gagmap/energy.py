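"""Per-residue-pair interaction energy components.

The primary route for production data is ingesting externally computed
MM-GBSA-style decomposition tables (see :mod:`gagmap.structio`).  This module
adds a self-contained pairwise energy engine producing physically-shaped
tables for synthetic complexes: Lennard-Jones van der Waals, vacuum Coulomb
electrostatics and a generalized-Born-style reaction-field screening term
with *supplied* (not solved-for) Born radii.  The engine exists so the
downstream site-mapping mathematics can be exercised against a source whose
component sums are exactly conservation-checkable; it is not a solvation
model fit for production free energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structio import (
    AtomRecord,
    GlycanAnnotation,
    PairEnergy,
    PairEnergyTable,
    ResidueKey,
    StructureEnsemble,
)

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyModelParams",
    "atom_pair_energies",
    "residue_pair_decomposition",
    "total_intermolecular_energy",
    "average_decomposition",
]

#: Coulomb's constant in kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0636


@dataclass
class EnergyModelParams:
    """Parameters of the internal pairwise engine.

    ``born_radii`` maps atom serial -> effective Born radius (Å) and must be
    supplied; radii are inputs here, never computed.  Defaults: vacuum
    interior (ε_in = 1) against aqueous solvent (ε_solv = 78.5).
    """

    coulomb_constant: float = COULOMB_CONSTANT
    interior_dielectric: float = 1.0
    solvent_dielectric: float = 78.5
    born_radii: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.interior_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectric constants must be > 0")
        for serial, radius in self.born_radii.items():
            if radius <= 0:
                raise ValueError(f"Born radius for atom serial {serial} must be > 0")


def atom_pair_energies(
    a1: AtomRecord, a2: AtomRecord, r: float, params: EnergyModelParams
) -> tuple[float, float, float]:
    """Interaction components of one atom pair at separation ``r`` Å.

    Returns ``(vdw, ele_vac, ele_rf)`` in kcal/mol:

    * ``vdw``: Lennard-Jones in the r_min/2 + ε convention with
      Lorentz-Berthelot combining,
      ``ε_ij ((r_min,ij/r)^12 − 2 (r_min,ij/r)^6)``.
    * ``ele_vac``: screened vacuum Coulomb, ``k q₁ q₂ / (ε_in r)``.
    * ``ele_rf``: generalized-Born reaction field,
      ``−k (1/ε_in − 1/ε_solv) q₁ q₂ / f_GB`` with
      ``f_GB = sqrt(r² + R₁R₂ exp(−r²/(4 R₁R₂)))``.
    """
    if r <= 0:
        raise ValueError("atom separation must be > 0")
    for a in (a1, a2):
        if a.partial_charge is None or a.lj_rmin_half is None or a.lj_epsilon is None:
            raise ValueError(f"atom serial {a.serial} lacks charge/LJ parameters")
        if a.serial not in params.born_radii:
            raise ValueError(f"atom serial {a.serial} lacks a Born radius")

    rmin = a1.lj_rmin_half + a2.lj_rmin_half
    eps = np.sqrt(a1.lj_epsilon * a2.lj_epsilon)
    x6 = (rmin / r) ** 6
    vdw = eps * (x6 * x6 - 2.0 * x6)

    k = params.coulomb_constant
    qq = a1.partial_charge * a2.partial_charge
    ele_vac = k * qq / (params.interior_dielectric * r)

    rr = params.born_radii[a1.serial] * params.born_radii[a2.serial]
    f_gb = np.sqrt(r * r + rr * np.exp(-r * r / (4.0 * rr)))
    ele_rf = -k * (1.0 / params.interior_dielectric - 1.0 / params.solvent_dielectric) * qq / f_gb
    return float(vdw), float(ele_vac), float(ele_rf)


def _gather_params(atoms: list[AtomRecord], params: EnergyModelParams):
    missing = [
        a.serial
        for a in atoms
        if a.partial_charge is None
        or a.lj_rmin_half is None
        or a.lj_epsilon is None
        or a.serial not in params.born_radii
    ]
    if missing:
        raise ValueError(
            "missing charge/LJ/Born parameters for atom serial(s): "
            + ", ".join(map(str, missing))
        )
    q = np.array([a.partial_charge for a in atoms])
    rmh = np.array([a.lj_rmin_half for a in atoms])
    eps = np.array([a.lj_epsilon for a in atoms])
    born = np.array([params.born_radii[a.serial] for a in atoms])
    return q, rmh, eps, born


def _component_matrices(coords_p, coords_g, qp, qg, rmhp, rmhg, epsp, epsg,
                        bornp, borng, params: EnergyModelParams):
    """Vectorized per-atom-pair component matrices (protein × glycan)."""
    r = cdist(coords_p, coords_g)
    if np.any(r == 0):
        raise ValueError("coincident protein/glycan atoms (r = 0)")
    rmin = rmhp[:, None] + rmhg[None, :]
    eps = np.sqrt(epsp[:, None] * epsg[None, :])
    x6 = (rmin / r) ** 6
    vdw = eps * (x6 * x6 - 2.0 * x6)

    k = params.coulomb_constant
    qq = qp[:, None] * qg[None, :]
    ele_vac = k * qq / (params.interior_dielectric * r)

    rr = bornp[:, None] * borng[None, :]
    f_gb = np.sqrt(r * r + rr * np.exp(-(r * r) / (4.0 * rr)))
    ele_rf = -k * (1.0 / params.interior_dielectric - 1.0 / params.solvent_dielectric) * qq / f_gb
    return vdw, ele_vac, ele_rf


def residue_pair_decomposition(
    ensemble: StructureEnsemble,
    annotation: GlycanAnnotation,
    params: EnergyModelParams,
) -> PairEnergyTable:
    """Frame-averaged (protein residue × glycan ring) component table.

    Each cell sums :func:`atom_pair_energies` over all inter-molecular atom
    pairs of that residue/ring (no distance cutoff), averaged over frames.
    By construction the component-wise sum over cells equals the total
    protein-glycan interaction energy of the complex.
    """
    res_idx = ensemble.residue_atom_indices()
    protein = [r.key for r in ensemble.protein_residues()]
    ring_of = annotation.ring_of_residue()

    atoms = ensemble.atoms
    p_atom_idx = np.concatenate([res_idx[k] for k in protein]) if protein else np.array([], int)
    g_keys = [r.key for r in ensemble.glycan_residues()]
    for k in g_keys:
        if k not in ring_of:
            raise ValueError(f"glycan residue {k.label()} missing from the annotation")
    g_atom_idx = np.concatenate([res_idx[k] for k in g_keys]) if g_keys else np.array([], int)

    p_atoms = [atoms[i] for i in p_atom_idx]
    g_atoms = [atoms[i] for i in g_atom_idx]
    qp, rmhp, epsp, bornp = _gather_params(p_atoms, params)
    qg, rmhg, epsg, borng = _gather_params(g_atoms, params)

    # group ids: protein residue index per protein atom, ring index per glycan atom
    p_group = np.concatenate(
        [np.full(len(res_idx[k]), i) for i, k in enumerate(protein)]
    ).astype(int)
    g_group = np.concatenate(
        [np.full(len(res_idx[k]), ring_of[k] - 1) for k in g_keys]
    ).astype(int)
    n_p, n_r = len(protein), annotation.dp

    sums = {c: np.zeros((n_p, n_r)) for c in ("vdw", "ele_vac", "ele_rf")}
    for f in range(ensemble.n_frames):
        coords = ensemble.frames[f]
        vdw, ele_vac, ele_rf = _component_matrices(
            coords[p_atom_idx], coords[g_atom_idx],
            qp, qg, rmhp, rmhg, epsp, epsg, bornp, borng, params,
        )
        for name, mat in (("vdw", vdw), ("ele_vac", ele_vac), ("ele_rf", ele_rf)):
            # two-stage group reduction: atoms -> residue rows, atoms -> ring cols
            rows = np.zeros((n_p, mat.shape[1]))
            np.add.at(rows, p_group, mat)
            cells = np.zeros((n_p, n_r))
            np.add.at(cells.T, g_group, rows.T)
            sums[name] += cells

    n = ensemble.n_frames
    entries: dict[tuple[ResidueKey, int], PairEnergy] = {}
    for i, key in enumerate(protein):
        for j in range(n_r):
            entries[(key, j + 1)] = PairEnergy(
                vdw=sums["vdw"][i, j] / n,
                ele_vac=sums["ele_vac"][i, j] / n,
                ele_rf=sums["ele_rf"][i, j] / n,
            )
    return PairEnergyTable(entries=entries, provenance="internal_engine", n_frames_averaged=n)


def total_intermolecular_energy(
    ensemble: StructureEnsemble,
    params: EnergyModelParams,
) -> tuple[float, float, float]:
    """Frame-averaged whole-complex protein-glycan (vdw, ele_vac, ele_rf)."""
    res_idx = ensemble.residue_atom_indices()
    atoms = ensemble.atoms
    p_idx = np.concatenate([res_idx[r.key] for r in ensemble.protein_residues()])
    g_idx = np.concatenate([res_idx[r.key] for r in ensemble.glycan_residues()])
    qp, rmhp, epsp, bornp = _gather_params([atoms[i] for i in p_idx], params)
    qg, rmhg, epsg, borng = _gather_params([atoms[i] for i in g_idx], params)
    totals = np.zeros(3)
    for f in range(ensemble.n_frames):
        coords = ensemble.frames[f]
        mats = _component_matrices(
            coords[p_idx], coords[g_idx], qp, qg, rmhp, rmhg, epsp, epsg, bornp, borng, params
        )
        totals += [m.sum() for m in mats]
    totals /= ensemble.n_frames
    return float(totals[0]), float(totals[1]), float(totals[2])


def average_decomposition(tables: list[PairEnergyTable]) -> PairEnergyTable:
    """Arithmetic per-cell mean of tables sharing one key set.

    ``n_frames_averaged`` accumulates so downstream consumers can see how
    many frames stand behind the averaged numbers.
    """
    if not tables:
        raise ValueError("no tables to average")
    keys = set(tables[0].entries)
    for t in tables[1:]:
        if set(t.entries) != keys:
            raise ValueError("tables have mismatching (residue, ring) key sets")
    n = len(tables)
    entries = {}
    for key in keys:
        entries[key] = PairEnergy(
            vdw=sum(t.entries[key].vdw for t in tables) / n,
            ele_vac=sum(t.entries[key].ele_vac for t in tables) / n,
            ele_rf=sum(t.entries[key].ele_rf for t in tables) / n,
        )
    return PairEnergyTable(
        entries=entries,
        provenance=tables[0].provenance,
        n_frames_averaged=sum(t.n_frames_averaged for t in tables),
    )
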