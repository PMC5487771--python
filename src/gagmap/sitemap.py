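"""Three-channel interaction site-maps.

A site-map is a (protein residue × glycan ring) matrix with one channel per
interaction type: H-bond occupancy, electrostatics and van der Waals.  Energy
channels store favorable magnitudes (−E clipped at zero) so all three
channels are non-negative and mutually comparable; signed energies remain
available upstream in the :class:`~gagmap.structio.PairEnergyTable`.

Maps from chains of different length are compared after per-ring
normalization with rings aligned on their 1-based index from the
non-reducing end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hbond import HBondOccupancyTable, residue_pair_occupancy
from .structio import GlycanAnnotation, PairEnergyTable, ResidueKey

__all__ = [
    "CHANNELS",
    "SiteMap",
    "CorrelationResult",
    "build_sitemap",
    "aggregate_sitemaps",
    "normalize_sitemap",
    "correlate_sitemaps",
    "difference_map",
    "write_sitemap",
    "read_sitemap",
]

CHANNELS = ("hbond", "ele", "vdw")


@dataclass
class SiteMap:
    """Protein-residue × glycan-ring interaction map with three channels."""

    protein_index: list[ResidueKey]
    ring_index: list[int]
    channels: dict[str, np.ndarray]
    normalization: str = "none"  # "none" | "per_ring" | "global"
    n_sources: int = 1
    clipped: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = (len(self.protein_index), len(self.ring_index))
        for name in CHANNELS:
            if name not in self.channels:
                raise ValueError(f"missing channel {name!r}")
            self.channels[name] = np.asarray(self.channels[name], dtype=float)
            if self.channels[name].shape != shape:
                raise ValueError(
                    f"channel {name!r} shape {self.channels[name].shape} != {shape}"
                )
        self._check_normalization()

    def _check_normalization(self) -> None:
        for name in CHANNELS:
            m = np.abs(self.channels[name])
            if self.normalization == "per_ring":
                sums = m.sum(axis=0)
                live = sums > 0
                if not np.allclose(sums[live], 1.0, atol=1e-9):
                    raise ValueError(f"per_ring channel {name!r}: columns do not sum to 1")
            elif self.normalization == "global":
                total = m.sum()
                if total > 0 and not np.isclose(total, 1.0, atol=1e-9):
                    raise ValueError(f"global channel {name!r}: grand sum != 1")

    def same_index(self, other: "SiteMap") -> bool:
        return self.protein_index == other.protein_index and self.ring_index == other.ring_index

    def cell_labels(self) -> list[tuple[ResidueKey, int]]:
        return [(k, r) for k in self.protein_index for r in self.ring_index]

    def top_cells(self, channel: str, k: int) -> list[tuple[ResidueKey, int]]:
        """The ``k`` largest cells of one channel, deterministic tie-break by
        (residue, ring)."""
        mat = self.channels[channel]
        cells = [
            (mat[i, j], self.protein_index[i], self.ring_index[j])
            for i in range(mat.shape[0])
            for j in range(mat.shape[1])
        ]
        cells.sort(key=lambda c: (-c[0], c[1], c[2]))
        return [(key, ring) for _, key, ring in cells[:k]]


def build_sitemap(
    occupancy: HBondOccupancyTable,
    energies: PairEnergyTable,
    annotation: GlycanAnnotation,
) -> SiteMap:
    """Assemble the three channels from an occupancy table and an energy table.

    H-bond cell: residue-pair occupancy (max over the pair's atom pairs).
    Energy cells: favorable magnitude ``max(0, −E)``; unfavorable (positive)
    energies are clipped to zero and counted in ``clipped``.
    """
    ring_of = annotation.ring_of_residue()
    for (_, ring) in energies.entries:
        if ring not in annotation.residue_of_ring():
            raise ValueError(f"energy table ring index {ring} not in the annotation")

    protein = sorted(
        {k for k, _ in energies.entries}
        | {
            key
            for pair in occupancy.entries
            for key, _ in pair
            if key.role == "protein"
        },
        key=lambda k: (k.chain_id, k.resnum),
    )
    rings = [r.ring_index for r in annotation.rings]
    p_pos = {k: i for i, k in enumerate(protein)}
    r_pos = {r: j for j, r in enumerate(rings)}
    shape = (len(protein), len(rings))

    hb = np.zeros(shape)
    for (a, b), frac in residue_pair_occupancy(occupancy).items():
        prot, gly = (a, b) if a.role == "protein" else (b, a)
        if prot.role != "protein" or gly.role != "glycan":
            continue
        if gly not in ring_of:
            raise ValueError(f"occupancy references glycan residue {gly.label()} "
                             "missing from the annotation")
        i, j = p_pos[prot], r_pos[ring_of[gly]]
        hb[i, j] = max(hb[i, j], frac)

    ele = np.zeros(shape)
    vdw = np.zeros(shape)
    clipped = {"ele": 0, "vdw": 0}
    for (key, ring), e in energies.entries.items():
        i, j = p_pos[key], r_pos[ring]
        if e.ele_total > 0:
            clipped["ele"] += 1
        else:
            ele[i, j] = -e.ele_total
        if e.vdw > 0:
            clipped["vdw"] += 1
        else:
            vdw[i, j] = -e.vdw

    return SiteMap(
        protein_index=protein,
        ring_index=rings,
        channels={"hbond": hb, "ele": ele, "vdw": vdw},
        normalization="none",
        n_sources=1,
        clipped=clipped,
    )


def normalize_sitemap(sitemap: SiteMap, mode: str) -> SiteMap:
    """Normalize each channel: ``per_ring`` divides every ring column by its
    absolute sum (all-zero columns unchanged, flagged); ``global`` divides the
    whole channel by its grand absolute sum."""
    if mode not in ("per_ring", "global"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    channels = {}
    flags = list(sitemap.flags)
    for name in CHANNELS:
        m = sitemap.channels[name].copy()
        if mode == "per_ring":
            sums = np.abs(m).sum(axis=0)
            zero = sums == 0
            if zero.any():
                flags.append(f"{name}: all-zero ring column(s) left unnormalized")
            sums[zero] = 1.0
            m = m / sums[None, :]
        else:
            total = np.abs(m).sum()
            if total == 0:
                flags.append(f"{name}: all-zero channel left unnormalized")
            else:
                m = m / total
        channels[name] = m
    return SiteMap(
        protein_index=sitemap.protein_index,
        ring_index=sitemap.ring_index,
        channels=channels,
        normalization=mode,
        n_sources=sitemap.n_sources,
        clipped=dict(sitemap.clipped),
        flags=flags,
    )


def aggregate_sitemaps(maps: list[SiteMap], weights: list[float] | None = None) -> SiteMap:
    """Per-channel weighted sum over maps sharing one index set, then global
    normalization.  Used to pool maps from many structures/poses of one
    derivative; ``n_sources`` accumulates."""
    if not maps:
        raise ValueError("no maps to aggregate")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_index(m):
            raise ValueError("site-maps have mismatching index sets")
    if weights is None:
        weights = [1.0] * len(maps)
    if len(weights) != len(maps):
        raise ValueError("weights length mismatch")
    channels = {
        name: sum(w * m.channels[name] for w, m in zip(weights, maps))
        for name in CHANNELS
    }
    clipped: dict[str, int] = {}
    for m in maps:
        for k, v in m.clipped.items():
            clipped[k] = clipped.get(k, 0) + v
    raw = SiteMap(
        protein_index=first.protein_index,
        ring_index=first.ring_index,
        channels=channels,
        normalization="none",
        n_sources=sum(m.n_sources for m in maps),
        clipped=clipped,
    )
    return normalize_sitemap(raw, "global")


@dataclass
class CorrelationResult:
    """Correlation between two maps' flattened cells on one channel.
    ``r`` is None when undefined (zero variance), with the reason recorded."""

    r: float | None
    p: float | None
    spearman_r: float | None
    channel: str
    n_cells: int
    reason: str | None = None


def correlate_sitemaps(a: SiteMap, b: SiteMap, channel: str) -> CorrelationResult:
    """Pearson correlation (Spearman reported alongside) over flattened cells."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if not a.same_index(b):
        raise ValueError("site-maps have mismatching index sets")
    x = a.channels[channel].ravel()
    y = b.channels[channel].ravel()
    if x.size < 3:
        return CorrelationResult(None, None, None, channel, x.size, "fewer than 3 cells")
    if np.var(x) == 0 or np.var(y) == 0:
        return CorrelationResult(None, None, None, channel, x.size,
                                 "zero variance in at least one map")
    pear = stats.pearsonr(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spear = stats.spearmanr(x, y)
    return CorrelationResult(
        r=float(pear.statistic),
        p=float(pear.pvalue),
        spearman_r=float(spear.statistic),
        channel=channel,
        n_cells=x.size,
    )


def difference_map(
    a: SiteMap, b: SiteMap, quantile: float = 0.95
) -> tuple[dict[str, np.ndarray], dict[str, list[tuple[ResidueKey, int, float]]]]:
    """Signed per-cell difference ``a − b`` per channel.

    Both maps must carry the same normalization mode.  The summary lists, per
    channel, cells with |Δ| at or above the given quantile of the non-zero
    |Δ| distribution (default: top 5%), largest first.
    """
    if not a.same_index(b):
        raise ValueError("site-maps have mismatching index sets")
    if a.normalization != b.normalization:
        raise ValueError(
            f"normalization mismatch: {a.normalization!r} vs {b.normalization!r}"
        )
    diffs = {name: a.channels[name] - b.channels[name] for name in CHANNELS}
    summary: dict[str, list[tuple[ResidueKey, int, float]]] = {}
    for name, d in diffs.items():
        mags = np.abs(d).ravel()
        nz = mags[mags > 0]
        if nz.size == 0:
            summary[name] = []
            continue
        thresh = float(np.quantile(nz, quantile))
        cells = [
            (a.protein_index[i], a.ring_index[j], float(d[i, j]))
            for i in range(d.shape[0])
            for j in range(d.shape[1])
            if abs(d[i, j]) >= thresh and d[i, j] != 0
        ]
        cells.sort(key=lambda c: (-abs(c[2]), c[0], c[1]))
        summary[name] = cells
    return diffs, summary


def plot_sitemap(sitemap: SiteMap, path=None):
    """Render the three channels as residue × ring heat maps.

    Returns the matplotlib figure; saves to ``path`` when given.  Rings run
    left (non-reducing) to right (reducing) on the x-axis.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_res = len(sitemap.protein_index)
    fig, axes = plt.subplots(
        1, 3, figsize=(3.2 * 3, max(2.5, 0.28 * n_res)), sharey=True
    )
    labels = [k.label() for k in sitemap.protein_index]
    for ax, name in zip(axes, CHANNELS):
        im = ax.imshow(sitemap.channels[name], aspect="auto", cmap="viridis")
        ax.set_title(name)
        ax.set_xticks(range(len(sitemap.ring_index)))
        ax.set_xticklabels(
            [f"{'NR' if r == sitemap.ring_index[0] else ''}{r}" for r in sitemap.ring_index]
        )
        ax.set_xlabel("sugar ring (NR→R)")
        fig.colorbar(im, ax=ax, shrink=0.8)
    axes[0].set_yticks(range(n_res))
    axes[0].set_yticklabels(labels, fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# TSV serialization (one row per cell per channel)
# ---------------------------------------------------------------------------

def write_sitemap(sitemap: SiteMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# normalization = {sitemap.normalization}\n")
        fh.write(f"# n_sources = {sitemap.n_sources}\n")
        for name, count in sorted(sitemap.clipped.items()):
            fh.write(f"# clipped_{name} = {count}\n")
        fh.write("protein_chain\tprotein_resnum\tprotein_resname\tring_index\tchannel\tvalue\n")
        for i, key in enumerate(sitemap.protein_index):
            for j, ring in enumerate(sitemap.ring_index):
                for name in CHANNELS:
                    fh.write(
                        f"{key.chain_id}\t{key.resnum}\t{key.resname}\t{ring}\t{name}\t"
                        f"{format(sitemap.channels[name][i, j], '.17g')}\n"
                    )


def read_sitemap(path) -> SiteMap:
    import pandas as pd

    normalization = "none"
    n_sources = 1
    clipped: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("#").split("=", 1)
                k, v = k.strip(), v.strip()
                if k == "normalization":
                    normalization = v
                elif k == "n_sources":
                    n_sources = int(v)
                elif k.startswith("clipped_"):
                    clipped[k[len("clipped_"):]] = int(v)
    df = pd.read_csv(path, sep="\t", comment="#")
    protein = sorted(
        {
            ResidueKey(str(c), int(n), str(rn), "protein")
            for c, n, rn in zip(
                df["protein_chain"], df["protein_resnum"], df["protein_resname"]
            )
        },
        key=lambda k: (k.chain_id, k.resnum),
    )
    rings = sorted(set(int(r) for r in df["ring_index"]))
    p_pos = {k: i for i, k in enumerate(protein)}
    r_pos = {r: j for j, r in enumerate(rings)}
    channels = {name: np.zeros((len(protein), len(rings))) for name in CHANNELS}
    for _, row in df.iterrows():
        key = ResidueKey(
            str(row["protein_chain"]), int(row["protein_resnum"]),
            str(row["protein_resname"]), "protein",
        )
        channels[str(row["channel"])][p_pos[key], r_pos[int(row["ring_index"])]] = float(
            row["value"]
        )
    return SiteMap(
        protein_index=protein,
        ring_index=rings,
        channels=channels,
        normalization=normalization,
        n_sources=n_sources,
        clipped=clipped,
    )
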