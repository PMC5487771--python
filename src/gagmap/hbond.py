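"""Geometric hydrogen-bond detection and occupancy aggregation.

An H-bond is counted when the heavy-atom donor-acceptor distance is at most
3.0 Å and the donor-H...acceptor angle is at least 135 deg for at least one
hydrogen covalently bonded to the donor (AMBER-style defaults).  Occupancies
are time fractions: the share of ensemble frames in which a given
donor-atom/acceptor-atom pair satisfies the geometry.  Multiple qualifying
hydrogens on one donor count once per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structio import AtomRecord, ResidueKey, StructureEnsemble

__all__ = [
    "HBondCriteria",
    "HBond",
    "HBondOccupancyTable",
    "classify_donors_acceptors",
    "detect_hbonds_frame",
    "occupancy_table",
    "select_top_bonds",
    "residue_pair_occupancy",
    "write_occupancy_table",
    "read_occupancy_table",
]

_NO_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond definition: heavy-atom distance and D-H...A angle cutoffs."""

    heavy_distance_cutoff: float = 3.0  # Å
    dha_angle_cutoff: float = 135.0  # degrees

    def __post_init__(self) -> None:
        if self.heavy_distance_cutoff <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not 0 < self.dha_angle_cutoff <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class HBond:
    """One detected bond: donor heavy atom, the qualifying hydrogen (serial,
    None in distance-only mode) and the acceptor heavy atom."""

    donor_serial: int
    hydrogen_serial: int | None
    acceptor_serial: int


#: key type of occupancy entries: ((donor residue, donor atom), (acceptor residue, acceptor atom))
PairKey = tuple[tuple[ResidueKey, str], tuple[ResidueKey, str]]


@dataclass
class HBondOccupancyTable:
    """(donor atom, acceptor atom) pair -> fraction of frames bonded."""

    entries: dict[PairKey, float]
    n_frames: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, frac in self.entries.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"occupancy {frac} out of [0, 1] for {pair}")


def classify_donors_acceptors(
    atoms: list[AtomRecord], require_hydrogens: bool = True
) -> tuple[set[int], set[int]]:
    """Partition N/O heavy atoms into donor and acceptor serials.

    Donors are N/O atoms carrying at least one bonded hydrogen; acceptors are
    all N/O heavy atoms (sulfate and carboxylate oxygens included).  An atom
    may be both.  With ``require_hydrogens=False`` (distance-only fallback for
    hydrogen-free structures) every N/O atom is treated as a potential donor.
    """
    donors: set[int] = set()
    acceptors: set[int] = set()
    for a in atoms:
        if a.is_hydrogen or a.element.upper() not in _NO_ELEMENTS:
            continue
        acceptors.add(a.serial)
        if a.bonded_hydrogens or not require_hydrogens:
            donors.add(a.serial)
    return donors, acceptors


def detect_hbonds_frame(
    ensemble: StructureEnsemble,
    frame: int | np.ndarray,
    donors: set[int],
    acceptors: set[int],
    criteria: HBondCriteria = HBondCriteria(),
    distance_only: bool = False,
    intermolecular_only: bool = True,
) -> set[HBond]:
    """Detect all qualifying H-bonds in one frame.

    ``frame`` is a frame index or an (n_atoms, 3) coordinate array in the
    ensemble's atom order.  Donor and acceptor must belong to different
    residues; with ``intermolecular_only`` only protein-glycan pairs are kept.
    Without ``distance_only``, a donor lacking bonded hydrogens is a hard
    error (set the flag for hydrogen-free crystal structures).
    """
    coords = ensemble.frames[frame] if isinstance(frame, (int, np.integer)) else np.asarray(frame)
    index = ensemble.atom_index()
    residue_of = ensemble.residue_of_atom()
    atoms = ensemble.atoms

    donor_list = sorted(donors)
    acceptor_list = sorted(acceptors)
    if not donor_list or not acceptor_list:
        return set()
    if not distance_only:
        bare = [s for s in donor_list if not atoms[index[s]].bonded_hydrogens]
        if bare:
            labels = ", ".join(
                f"{residue_of[index[s]].label()}/{atoms[index[s]].name}" for s in bare
            )
            raise ValueError(
                "donor atom(s) without bonded hydrogens and distance-only fallback "
                f"unset: {labels}"
            )

    d_idx = np.array([index[s] for s in donor_list])
    a_idx = np.array([index[s] for s in acceptor_list])
    dist = cdist(coords[d_idx], coords[a_idx])
    cos_cut = np.cos(np.deg2rad(criteria.dha_angle_cutoff))

    found: set[HBond] = set()
    for i, j in zip(*np.nonzero(dist <= criteria.heavy_distance_cutoff)):
        ds, as_ = donor_list[i], acceptor_list[j]
        di, ai = d_idx[i], a_idx[j]
        rd, ra = residue_of[di], residue_of[ai]
        if rd == ra:
            continue
        if intermolecular_only and rd.role == ra.role:
            continue
        if distance_only:
            found.add(HBond(ds, None, as_))
            continue
        for hs in atoms[di].bonded_hydrogens:
            h = coords[index[hs]]
            vd = coords[di] - h
            va = coords[ai] - h
            nd, na = np.linalg.norm(vd), np.linalg.norm(va)
            if nd == 0 or na == 0:
                continue
            # D-H...A angle >= cutoff  <=>  cos(angle at H) <= cos(cutoff)
            if float(np.dot(vd, va) / (nd * na)) <= cos_cut + 1e-12:
                found.add(HBond(ds, hs, as_))
                break
    return found


def occupancy_table(
    ensemble: StructureEnsemble,
    criteria: HBondCriteria = HBondCriteria(),
    distance_only: bool | None = None,
    intermolecular_only: bool = True,
) -> HBondOccupancyTable:
    """Aggregate per-frame detections into time fractions over the ensemble.

    With ``distance_only=None`` the angle criterion is applied when the
    structure carries hydrogens and skipped (with a metadata warning) when it
    does not, so hydrogen-free crystal structures remain analysable.
    """
    metadata: dict = {}
    if distance_only is None:
        distance_only = not ensemble.has_hydrogens()
    if distance_only:
        metadata["warning"] = (
            "distance-only H-bond criterion (no angle check): structure lacks "
            "explicit hydrogens or fallback was requested"
        )
    donors, acceptors = classify_donors_acceptors(
        ensemble.atoms, require_hydrogens=not distance_only
    )
    index = ensemble.atom_index()
    residue_of = ensemble.residue_of_atom()
    atoms = ensemble.atoms

    counts: dict[PairKey, int] = {}
    for f in range(ensemble.n_frames):
        bonds = detect_hbonds_frame(
            ensemble, f, donors, acceptors, criteria,
            distance_only=distance_only, intermolecular_only=intermolecular_only,
        )
        frame_pairs = {
            (
                (residue_of[index[b.donor_serial]], atoms[index[b.donor_serial]].name),
                (residue_of[index[b.acceptor_serial]], atoms[index[b.acceptor_serial]].name),
            )
            for b in bonds
        }
        for pair in frame_pairs:
            counts[pair] = counts.get(pair, 0) + 1

    n = ensemble.n_frames
    entries = {pair: c / n for pair, c in counts.items()}
    metadata["criteria"] = criteria
    return HBondOccupancyTable(entries=entries, n_frames=n, metadata=metadata)


def _sort_key(item: tuple[PairKey, float]):
    (dk, dn), (ak, an) = item[0]
    return (-item[1], dk.resnum, ak.resnum, dn, an, dk.chain_id, ak.chain_id)


def select_top_bonds(table: HBondOccupancyTable, k: int) -> HBondOccupancyTable:
    """Keep the ``k`` most frequent bonds (the paper-style 'top 33' selection).

    Ties break deterministically by donor residue number, acceptor residue
    number, then atom names.  ``k`` larger than the table returns everything.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    ranked = sorted(table.entries.items(), key=_sort_key)[:k]
    return HBondOccupancyTable(
        entries=dict(ranked), n_frames=table.n_frames, metadata=dict(table.metadata)
    )


def residue_pair_occupancy(table: HBondOccupancyTable) -> dict[tuple[ResidueKey, ResidueKey], float]:
    """Residue-level occupancy: max over the residue pair's atom pairs.

    The maximum (rather than the sum) avoids counting one physical contact
    several times when it is seen through multiple donor/acceptor atoms.
    """
    out: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for ((dk, _), (ak, _)), frac in table.entries.items():
        pair = (dk, ak)
        out[pair] = max(out.get(pair, 0.0), frac)
    return out


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

_COLS = [
    "donor_chain", "donor_resnum", "donor_resname", "donor_role", "donor_atom",
    "acceptor_chain", "acceptor_resnum", "acceptor_resname", "acceptor_role", "acceptor_atom",
    "fraction",
]


def write_occupancy_table(table: HBondOccupancyTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_frames = {table.n_frames}\n")
        if "warning" in table.metadata:
            fh.write(f"# warning = {table.metadata['warning']}\n")
        fh.write("\t".join(_COLS) + "\n")
        for ((dk, dn), (ak, an)), frac in sorted(table.entries.items(), key=_sort_key):
            fh.write(
                f"{dk.chain_id}\t{dk.resnum}\t{dk.resname}\t{dk.role}\t{dn}\t"
                f"{ak.chain_id}\t{ak.resnum}\t{ak.resname}\t{ak.role}\t{an}\t"
                f"{repr(float(frac))}\n"
            )


def read_occupancy_table(path) -> HBondOccupancyTable:
    import pandas as pd

    n_frames = 1
    metadata: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("#").split("=", 1)
                if k.strip() == "n_frames":
                    n_frames = int(v.strip())
                elif k.strip() == "warning":
                    metadata["warning"] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    entries: dict[PairKey, float] = {}
    for _, row in df.iterrows():
        dk = ResidueKey(str(row["donor_chain"]), int(row["donor_resnum"]),
                        str(row["donor_resname"]), str(row["donor_role"]))
        ak = ResidueKey(str(row["acceptor_chain"]), int(row["acceptor_resnum"]),
                        str(row["acceptor_resname"]), str(row["acceptor_role"]))
        entries[((dk, str(row["donor_atom"])), (ak, str(row["acceptor_atom"])))] = float(
            row["fraction"]
        )
    return HBondOccupancyTable(entries=entries, n_frames=n_frames, metadata=metadata)
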