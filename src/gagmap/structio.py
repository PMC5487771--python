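"""Structural data model and file I/O for protein-glycosaminoglycan complexes.

The shared containers used across the package live here: atoms, residues,
multi-frame structural ensembles, glycan ring annotations and per-residue-pair
interaction energy tables.  Conventions throughout: Ångström, kcal/mol,
elementary charge units, degrees.  Residue numbering from the source PDB is
preserved so protein residues keep their literature labels (e.g. Lys 118);
glycan rings additionally receive 1-based indices counted from the
non-reducing end, the order in which sulfation patterns are written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "Residue",
    "StructureEnsemble",
    "GlycanRing",
    "GlycanAnnotation",
    "PairEnergy",
    "PairEnergyTable",
    "parse_structure_ensemble",
    "write_structure_ensemble",
    "annotate_glycan",
    "parse_glycan_pattern",
    "subsample_tail",
    "parse_decomp_table",
    "write_decomp_table",
    "read_ff_params",
    "write_ff_params",
    "read_config",
    "write_config",
]

RING_TYPES = ("GlcNS", "GlcN", "IdoA", "IdoA2S", "other")

#: PDB residue names used when toy glycan rings are written out, by ring type.
RING_RESNAMES = {"GlcNS": "SGN", "GlcN": "GCS", "IdoA": "IDU", "IdoA2S": "IDS", "other": "UNK"}

# Covalent H-heavy atom bond detection cutoff, Å.
_H_BOND_LENGTH_CUTOFF = 1.2


@dataclass
class AtomRecord:
    """One atom of the topology.

    ``coords`` holds the reference (first frame) position; per-frame positions
    live in :class:`StructureEnsemble.frames`.  Force-field attributes are
    optional — they are absent for plain crystal structures and supplied for
    synthetic complexes or via a parameter table.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    partial_charge: float | None = None
    lj_rmin_half: float | None = None
    lj_epsilon: float | None = None
    bonded_hydrogens: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom serial {self.serial}: element must be non-empty")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom serial {self.serial}: coords must be a finite 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue; (chain_id, resnum) is unique within a structure."""

    chain_id: str
    resnum: int
    resname: str
    role: str  # "protein" | "glycan"

    def __post_init__(self) -> None:
        if self.role not in ("protein", "glycan"):
            raise ValueError(f"invalid role {self.role!r}")

    def label(self) -> str:
        return f"{self.resname} {self.resnum}"


@dataclass
class Residue:
    key: ResidueKey
    atoms: list[AtomRecord]


@dataclass
class StructureEnsemble:
    """Topology plus an ordered stack of coordinate frames for one complex.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å, atom order matching the
    flattened topology.  Every frame must carry exactly the topology's atom
    count and at least one frame must be present.
    """

    residues: list[Residue]
    frames: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n_frames, n_atoms, 3) array")
        if self.frames.shape[1] != self.n_atoms or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames shape {self.frames.shape} inconsistent with topology "
                f"({self.n_atoms} atoms)"
            )
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within the topology")
        keys = [(r.key.chain_id, r.key.resnum) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("(chain_id, resnum) must be unique within the structure")

    # -- topology helpers -------------------------------------------------

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def atom_index(self) -> dict[int, int]:
        """Map atom serial -> flat index into a frame's coordinate array."""
        return {a.serial: i for i, a in enumerate(self.atoms)}

    def residue_atom_indices(self) -> dict[ResidueKey, np.ndarray]:
        out: dict[ResidueKey, np.ndarray] = {}
        i = 0
        for r in self.residues:
            out[r.key] = np.arange(i, i + len(r.atoms))
            i += len(r.atoms)
        return out

    def residue_of_atom(self) -> list[ResidueKey]:
        return [r.key for r in self.residues for _ in r.atoms]

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.key.role == "protein"]

    def glycan_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.key.role == "glycan"]

    def has_hydrogens(self) -> bool:
        return any(a.is_hydrogen for a in self.atoms)


@dataclass(frozen=True)
class GlycanRing:
    key: ResidueKey
    ring_type: str
    sulfation: frozenset[str]
    ring_index: int  # 1-based from the non-reducing end


@dataclass
class GlycanAnnotation:
    """Ordered ring annotation of a glycan chain, non-reducing -> reducing."""

    rings: list[GlycanRing]

    def __post_init__(self) -> None:
        indices = [r.ring_index for r in self.rings]
        if indices != list(range(1, len(self.rings) + 1)):
            raise ValueError("ring_index must be contiguous 1..dp from the non-reducing end")
        if len({r.key for r in self.rings}) != len(self.rings):
            raise ValueError("each ring must map to exactly one residue")
        for r in self.rings:
            if r.ring_type not in RING_TYPES:
                raise ValueError(f"unknown ring type {r.ring_type!r}")

    @property
    def dp(self) -> int:
        return len(self.rings)

    def ring_of_residue(self) -> dict[ResidueKey, int]:
        return {r.key: r.ring_index for r in self.rings}

    def residue_of_ring(self) -> dict[int, ResidueKey]:
        return {r.ring_index: r.key for r in self.rings}

    def pattern(self) -> str:
        """Canonical descriptor string, e.g. ``GlcNS6S-IdoA2S-GlcNS``."""
        return "-".join(_encode_ring(r.ring_type, r.sulfation) for r in self.rings)


# ---------------------------------------------------------------------------
# Glycan pattern grammar
# ---------------------------------------------------------------------------

def _decode_token(token: str) -> tuple[str, frozenset[str]]:
    """Parse one ring token into (ring_type, sulfation flags).

    Grammar: base ``GlcN`` or ``IdoA`` followed by sulfation codes — a bare
    ``S`` right after ``GlcN`` is the N-sulfate, positional codes are like
    ``2S``, ``3S``, ``6S``.  Unknown bases map to ring type ``other``.
    """
    t = token.strip()
    for base in ("GlcN", "IdoA"):
        if t.startswith(base):
            rest = t[len(base):]
            flags: set[str] = set()
            if base == "GlcN" and rest.startswith("S"):
                flags.add("NS")
                rest = rest[1:]
            while rest:
                if len(rest) >= 2 and rest[0].isdigit() and rest[1] == "S":
                    flags.add(rest[:2])
                    rest = rest[2:]
                else:
                    raise ValueError(f"cannot parse sulfation codes in ring token {token!r}")
            if base == "GlcN":
                ring_type = "GlcNS" if "NS" in flags else "GlcN"
            else:
                ring_type = "IdoA2S" if "2S" in flags else "IdoA"
            return ring_type, frozenset(flags)
    return "other", frozenset()


def _encode_ring(ring_type: str, sulfation: frozenset[str]) -> str:
    if ring_type == "other":
        return "X"
    base = "GlcN" if ring_type.startswith("GlcN") else "IdoA"
    s = ""
    if "NS" in sulfation:
        s += "S"
    for code in sorted(f for f in sulfation if f != "NS"):
        s += code
    return base + s


def parse_glycan_pattern(pattern: str) -> list[tuple[str, frozenset[str]]]:
    """Split a ``-``-separated descriptor into (ring_type, flags) per ring,
    ordered non-reducing -> reducing."""
    tokens = [t for t in pattern.split("-") if t]
    if not tokens:
        raise ValueError("empty glycan pattern")
    return [_decode_token(t) for t in tokens]


def annotate_glycan(ensemble: StructureEnsemble, pattern: str) -> GlycanAnnotation:
    """Attach ring types / sulfation flags to the ensemble's glycan residues.

    Glycan residues are taken in topology order, which is assumed to run from
    the non-reducing to the reducing end (the order sulfation patterns are
    written).  The pattern length must equal the number of glycan residues.
    """
    glycan = ensemble.glycan_residues()
    decoded = parse_glycan_pattern(pattern)
    if len(decoded) != len(glycan):
        raise ValueError(
            f"pattern has {len(decoded)} rings but the structure has "
            f"{len(glycan)} glycan residues"
        )
    rings = [
        GlycanRing(key=res.key, ring_type=rt, sulfation=flags, ring_index=i + 1)
        for i, (res, (rt, flags)) in enumerate(zip(glycan, decoded))
    ]
    return GlycanAnnotation(rings=rings)


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def parse_structure_ensemble(
    path: str | Path,
    protein_chains: Iterable[str],
    glycan_resnames: Iterable[str],
) -> StructureEnsemble:
    """Read a multi-model PDB file into a :class:`StructureEnsemble`.

    One frame is produced per MODEL record; all models must share the atom
    ordering of the first.  Residues are partitioned into protein/glycan by
    chain id and residue name respectively (a glycan residue name wins over a
    protein chain).  Hydrogens are attached to their heavy atom by covalent
    distance (< 1.2 Å in the first frame).
    """
    from Bio.PDB import PDBParser

    protein_chains = set(protein_chains)
    glycan_resnames = set(glycan_resnames)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ensemble", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")

    residues: list[Residue] = []
    flat_atoms: list = []  # Biopython atoms of model 0, in file order
    for chain in models[0]:
        for res in chain:
            resname = res.get_resname().strip()
            chain_id = chain.id
            if resname in glycan_resnames:
                role = "glycan"
            elif chain_id in protein_chains:
                role = "protein"
            else:
                raise ValueError(
                    f"{path}: residue {resname} {res.id[1]} in chain {chain_id!r} is in "
                    "neither protein_chains nor glycan_resnames"
                )
            key = ResidueKey(chain_id=chain_id, resnum=res.id[1], resname=resname, role=role)
            atoms = []
            for atom in res:
                element = (atom.element or "").strip() or atom.get_name().strip()[0]
                atoms.append(
                    AtomRecord(
                        serial=atom.serial_number,
                        name=atom.get_name().strip(),
                        element=element.capitalize(),
                        coords=np.asarray(atom.coord, dtype=float),
                    )
                )
                flat_atoms.append(atom)
            residues.append(Residue(key=key, atoms=atoms))

    if not any(r.key.role == "glycan" for r in residues):
        raise ValueError(f"{path}: no glycan residues matched {sorted(glycan_resnames)}")

    n_atoms = len(flat_atoms)
    frames = np.empty((len(models), n_atoms, 3), dtype=float)
    frames[0] = np.array([a.coord for a in flat_atoms], dtype=float)
    for m, model in enumerate(models[1:], start=1):
        coords = [atom.coord for chain in model for res in chain for atom in res]
        if len(coords) != n_atoms:
            raise ValueError(
                f"{path}: model {model.id} has {len(coords)} atoms, expected {n_atoms}"
            )
        frames[m] = np.asarray(coords, dtype=float)

    ensemble = StructureEnsemble(residues=residues, frames=frames)
    _infer_bonded_hydrogens(ensemble)
    return ensemble


def _infer_bonded_hydrogens(ensemble: StructureEnsemble) -> None:
    """Assign each hydrogen to its nearest heavy atom within the covalent
    cutoff, within the same residue, using first-frame coordinates."""
    idx = 0
    frame0 = ensemble.frames[0]
    for res in ensemble.residues:
        n = len(res.atoms)
        coords = frame0[idx: idx + n]
        heavy = [i for i, a in enumerate(res.atoms) if not a.is_hydrogen]
        hydro = [i for i, a in enumerate(res.atoms) if a.is_hydrogen]
        for a in res.atoms:
            a.bonded_hydrogens = []
        if heavy and hydro:
            d = cdist(coords[hydro], coords[heavy])
            for hi, row in zip(hydro, d):
                j = int(np.argmin(row))
                if row[j] < _H_BOND_LENGTH_CUTOFF:
                    res.atoms[heavy[j]].bonded_hydrogens.append(res.atoms[hi].serial)
        idx += n


def write_structure_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB file (one MODEL per frame)."""
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure("ens")
    for f in range(ensemble.n_frames):
        builder.init_model(f)
        seen_chains: set[str] = set()
        i = 0
        for res in ensemble.residues:
            cid = res.key.chain_id
            if cid not in seen_chains:
                builder.init_chain(cid)
                seen_chains.add(cid)
            builder.init_seg("    ")
            builder.init_residue(res.key.resname, " ", res.key.resnum, " ")
            for a in res.atoms:
                name = a.name
                fullname = name if len(name) >= 4 else f" {name:<3s}"
                builder.init_atom(
                    name,
                    np.asarray(ensemble.frames[f, i], dtype=float),
                    0.0,
                    1.0,
                    " ",
                    fullname,
                    a.serial,
                    element=a.element.upper(),
                )
                i += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# Frame subsampling
# ---------------------------------------------------------------------------

def subsample_tail(ensemble: StructureEnsemble, tail_frames: int, count: int) -> StructureEnsemble:
    """Pick ``count`` evenly spaced frames from the final ``tail_frames`` window.

    First and last frames of the window are included whenever ``count >= 2``,
    mirroring the convention of taking evenly distributed analysis frames from
    the last stretch of a trajectory.
    """
    n = ensemble.n_frames
    if tail_frames > n:
        raise ValueError(f"tail_frames={tail_frames} exceeds total frames ({n})")
    if count > tail_frames:
        raise ValueError(f"count={count} exceeds tail_frames={tail_frames}")
    if count < 1:
        raise ValueError("count must be >= 1")
    start = n - tail_frames
    if count == 1:
        indices = np.array([n - 1])
    else:
        indices = start + np.rint(np.linspace(0, tail_frames - 1, count)).astype(int)
    times = None if ensemble.frame_times is None else ensemble.frame_times[indices]
    return StructureEnsemble(
        residues=ensemble.residues, frames=ensemble.frames[indices], frame_times=times
    )


# ---------------------------------------------------------------------------
# Pair energy tables
# ---------------------------------------------------------------------------

@dataclass
class PairEnergy:
    """Interaction components of one (protein residue, glycan ring) cell,
    kcal/mol.  ``ele_total`` is always vacuum + reaction-field."""

    vdw: float
    ele_vac: float
    ele_rf: float
    hbond_fraction: float | None = None

    @property
    def ele_total(self) -> float:
        return self.ele_vac + self.ele_rf


@dataclass
class PairEnergyTable:
    """(protein residue, ring index) -> interaction energy components."""

    entries: dict[tuple[ResidueKey, int], PairEnergy]
    provenance: str = "ingested"  # "ingested" | "internal_engine"
    n_frames_averaged: int = 1

    def protein_keys(self) -> list[ResidueKey]:
        return sorted({k for k, _ in self.entries}, key=lambda k: (k.chain_id, k.resnum))

    def ring_indices(self) -> list[int]:
        return sorted({r for _, r in self.entries})

    def per_residue_totals(self) -> dict[ResidueKey, float]:
        """Total interaction energy per protein residue, summed over rings."""
        out: dict[ResidueKey, float] = {}
        for (key, _), e in self.entries.items():
            out[key] = out.get(key, 0.0) + e.vdw + e.ele_total
        return out

    def top_contributors(self, k: int = 10) -> list[tuple[ResidueKey, float]]:
        totals = self.per_residue_totals()
        return sorted(totals.items(), key=lambda kv: (kv[1], kv[0]))[:k]


_CANONICAL_COLS = [
    "protein_chain",
    "protein_resnum",
    "protein_resname",
    "ring_index",
    "vdw",
    "ele_vac",
    "ele_rf",
    "ele_total",
    "hbond_fraction",
]


def write_decomp_table(table: PairEnergyTable, path: str | Path) -> None:
    """Write the canonical tab-separated energy table (``#`` comment header)."""
    rows = []
    for (key, ring), e in sorted(
        table.entries.items(), key=lambda kv: (kv[0][0].chain_id, kv[0][0].resnum, kv[0][1])
    ):
        rows.append(
            {
                "protein_chain": key.chain_id,
                "protein_resnum": key.resnum,
                "protein_resname": key.resname,
                "ring_index": ring,
                "vdw": e.vdw,
                "ele_vac": e.ele_vac,
                "ele_rf": e.ele_rf,
                "ele_total": e.ele_total,
                "hbond_fraction": "" if e.hbond_fraction is None else e.hbond_fraction,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# provenance = {table.provenance}\n")
        fh.write(f"# n_frames_averaged = {table.n_frames_averaged}\n")
        fh.write("\t".join(_CANONICAL_COLS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    format(row[c], ".17g") if isinstance(row[c], float) else str(row[c])
                    for c in _CANONICAL_COLS
                )
                + "\n"
            )


def parse_decomp_table(
    path: str | Path,
    dialect: str = "canonical_tsv",
    annotation: GlycanAnnotation | None = None,
    glycan_resnames: Iterable[str] | None = None,
) -> PairEnergyTable:
    """Read a per-residue-pair energy decomposition table.

    ``canonical_tsv`` is this package's own format (see
    :func:`write_decomp_table`).  ``amber_csv`` is a header-driven reading of
    MMPBSA-style pairwise decomposition CSVs: the residue of the second column
    is matched to a glycan ring via ``annotation`` (residue number -> ring
    index) or, failing that, by order of first appearance; sidechain/backbone
    sub-rows, when a ``Location`` column is present, are summed into the
    residue total.  ``ele_total`` is always recomputed as ``ele_vac + ele_rf``.
    """
    if dialect == "canonical_tsv":
        return _parse_canonical_tsv(path)
    if dialect == "amber_csv":
        return _parse_amber_csv(path, annotation, glycan_resnames)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_canonical_tsv(path: str | Path) -> PairEnergyTable:
    provenance = "ingested"
    n_frames = 1
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("#").split("=", 1)
                k, v = k.strip(), v.strip()
                if k == "provenance":
                    provenance = v
                elif k == "n_frames_averaged":
                    n_frames = int(v)
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("protein_chain", "protein_resnum", "protein_resname", "ring_index",
                "vdw", "ele_vac", "ele_rf"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    entries: dict[tuple[ResidueKey, int], PairEnergy] = {}
    for _, row in df.iterrows():
        key = ResidueKey(
            chain_id=str(row["protein_chain"]),
            resnum=int(row["protein_resnum"]),
            resname=str(row["protein_resname"]),
            role="protein",
        )
        pair = (key, int(row["ring_index"]))
        if pair in entries:
            raise ValueError(f"{path}: duplicate pair row for {key.label()} / ring {pair[1]}")
        hb = row.get("hbond_fraction")
        hb = None if hb is None or (isinstance(hb, float) and np.isnan(hb)) else float(hb)
        entries[pair] = PairEnergy(
            vdw=float(row["vdw"]),
            ele_vac=float(row["ele_vac"]),
            ele_rf=float(row["ele_rf"]),
            hbond_fraction=hb,
        )
    return PairEnergyTable(entries=entries, provenance=provenance, n_frames_averaged=n_frames)


def _find_column(columns: Sequence[str], *needles: str) -> str | None:
    for col in columns:
        low = col.strip().lower()
        if any(n in low for n in needles):
            return col
    return None


def _parse_amber_csv(
    path: str | Path,
    annotation: GlycanAnnotation | None,
    glycan_resnames: Iterable[str] | None,
) -> PairEnergyTable:
    df = pd.read_csv(path)
    cols = list(df.columns)
    col_r1 = _find_column(cols, "resid 1", "residue 1", "resid1")
    col_r2 = _find_column(cols, "resid 2", "residue 2", "resid2")
    col_vdw = _find_column(cols, "van der waals", "vdw")
    col_ele = _find_column(cols, "electrostatic")
    col_rf = _find_column(cols, "polar solvation", "polar solv")
    missing = [
        label
        for label, col in [
            ("residue 1", col_r1),
            ("residue 2", col_r2),
            ("van der Waals", col_vdw),
            ("Electrostatic", col_ele),
            ("Polar Solvation", col_rf),
        ]
        if col is None
    ]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    col_loc = _find_column(cols, "location")
    glycan_resnames = set(glycan_resnames) if glycan_resnames else None
    ring_by_resnum = (
        {k.resnum: i for k, i in annotation.ring_of_residue().items()} if annotation else None
    )

    accum: dict[tuple[ResidueKey, int], list[float]] = {}
    seen_locations: dict[tuple[ResidueKey, int], set] = {}
    ring_order: dict[str, int] = {}
    for _, row in df.iterrows():
        rname1, rnum1 = _split_residue_id(str(row[col_r1]))
        rname2, rnum2 = _split_residue_id(str(row[col_r2]))
        key = ResidueKey(chain_id="A", resnum=rnum1, resname=rname1, role="protein")
        if ring_by_resnum is not None:
            if rnum2 not in ring_by_resnum:
                raise ValueError(f"{path}: residue {rname2} {rnum2} not in the glycan annotation")
            ring = ring_by_resnum[rnum2]
        else:
            if glycan_resnames is not None and rname2 not in glycan_resnames:
                raise ValueError(f"{path}: residue {rname2} {rnum2} is not a known glycan residue")
            ident = f"{rname2} {rnum2}"
            ring_order.setdefault(ident, len(ring_order) + 1)
            ring = ring_order[ident]
        pair = (key, ring)
        loc = str(row[col_loc]).strip() if col_loc else "Total"
        if loc in seen_locations.setdefault(pair, set()):
            raise ValueError(f"{path}: duplicate pair row for {key.label()} / ring {ring}")
        seen_locations[pair].add(loc)
        vals = accum.setdefault(pair, [0.0, 0.0, 0.0])
        vals[0] += float(row[col_vdw])
        vals[1] += float(row[col_ele])
        vals[2] += float(row[col_rf])

    entries = {
        pair: PairEnergy(vdw=v[0], ele_vac=v[1], ele_rf=v[2]) for pair, v in accum.items()
    }
    return PairEnergyTable(entries=entries, provenance="ingested")


def _split_residue_id(ident: str) -> tuple[str, int]:
    """Parse identifiers like ``LYS 118`` or ``LYS118`` into (name, number)."""
    ident = ident.strip()
    parts = ident.split()
    if len(parts) == 2 and parts[1].lstrip("-").isdigit():
        return parts[0], int(parts[1])
    head = ident.rstrip("0123456789")
    tail = ident[len(head):]
    if not tail:
        raise ValueError(f"cannot parse residue identifier {ident!r}")
    return head.strip(), int(tail)


# ---------------------------------------------------------------------------
# Force-field parameter sidecar and config files
# ---------------------------------------------------------------------------

def write_ff_params(ensemble: StructureEnsemble, born_radii: dict[int, float],
                    path: str | Path) -> None:
    """Write per-atom charges, LJ parameters and Born radii as TSV keyed by serial."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("serial\tpartial_charge\tlj_rmin_half\tlj_epsilon\tborn_radius\n")
        for a in ensemble.atoms:
            fh.write(
                f"{a.serial}\t{repr(float(a.partial_charge or 0.0))}\t"
                f"{repr(float(a.lj_rmin_half or 0.0))}\t"
                f"{repr(float(a.lj_epsilon or 0.0))}\t"
                f"{format(born_radii.get(a.serial, 0.0), '.17g')}\n"
            )


def read_ff_params(ensemble: StructureEnsemble, path: str | Path) -> dict[int, float]:
    """Attach charges/LJ parameters from a TSV onto the ensemble's atoms;
    returns the Born radii map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    by_serial = {int(r["serial"]): r for _, r in df.iterrows()}
    born: dict[int, float] = {}
    for a in ensemble.atoms:
        if a.serial not in by_serial:
            raise ValueError(f"{path}: no parameters for atom serial {a.serial}")
        row = by_serial[a.serial]
        a.partial_charge = float(row["partial_charge"])
        a.lj_rmin_half = float(row["lj_rmin_half"])
        a.lj_epsilon = float(row["lj_epsilon"])
        born[a.serial] = float(row["born_radius"])
    return born


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` config file ('#' comments, blank lines ok)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: malformed config line {line!r}")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_config(cfg: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in cfg.items():
            fh.write(f"{k} = {v}\n")
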