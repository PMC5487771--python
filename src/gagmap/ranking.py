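"""Ranking ligands from ensembles of binding free-energy values.

Binding free energies from multipose docking are noisy distributions, not
single numbers.  This module ranks ligands the way ensemble docking studies
do: by best (most negative) ΔG within each receptor-conformation grouping,
recording how often each ligand lands in each rank position across
groupings, testing pairwise differences with Welch's unequal-variance
t-test, and collapsing the rank-occurrence table into a consensus order by
mean occupied rank.

All decisions are invariant to adding a constant to every ΔG value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeltaGSamples",
    "RankTable",
    "PairTest",
    "rank_by_best",
    "rank_occurrence",
    "welch_ttest_matrix",
    "consensus_ranking",
    "read_deltaG_tsv",
    "write_rank_table",
]


@dataclass
class DeltaGSamples:
    """Per-ligand binding free-energy samples, kcal/mol (more negative =
    stronger binding), with an optional per-receptor-conformation grouping:
    ``groups[label]`` parallels ``values[label]`` with grouping ids."""

    values: dict[str, np.ndarray]
    groups: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("no ligands")
        for label, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.size == 0:
                raise ValueError(f"ligand {label!r} has no samples")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"ligand {label!r} has non-finite samples")
            self.values[label] = v
        if self.groups is not None:
            for label in self.values:
                if label not in self.groups:
                    raise ValueError(f"ligand {label!r} missing from grouping")
                if len(self.groups[label]) != len(self.values[label]):
                    raise ValueError(f"grouping length mismatch for ligand {label!r}")

    @property
    def ligands(self) -> list[str]:
        return sorted(self.values)

    def group_ids(self) -> list:
        if self.groups is None:
            raise ValueError("samples carry no grouping")
        ids: set = set()
        for g in self.groups.values():
            ids.update(np.asarray(g).tolist())
        return sorted(ids)

    def shifted(self, constant: float) -> "DeltaGSamples":
        return DeltaGSamples(
            values={k: v + constant for k, v in self.values.items()},
            groups=None if self.groups is None else {k: np.asarray(v) for k, v in self.groups.items()},
        )


@dataclass
class RankTable:
    """ligand × rank-position occurrence counts over groupings.

    ``counts[i, p]`` is how often ``ligands[i]`` scored at rank position
    ``p + 1``; every grouping contributes exactly one count per ligand, so
    each row sums to ``n_groupings``.
    """

    ligands: list[str]
    counts: np.ndarray
    n_groupings: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.ligands), len(self.ligands)):
            raise ValueError("counts must be square ligand × position")
        if not np.all(self.counts.sum(axis=1) == self.n_groupings):
            raise ValueError("each row must sum to the number of groupings")

    def mean_rank(self) -> dict[str, float]:
        positions = np.arange(1, len(self.ligands) + 1)
        return {
            lig: float((self.counts[i] * positions).sum() / self.n_groupings)
            for i, lig in enumerate(self.ligands)
        }


def rank_by_best(samples: DeltaGSamples) -> list[str]:
    """Order ligands by their single most favourable (minimum) ΔG, the
    classical best-pose ranking; ties break by label."""
    return sorted(samples.values, key=lambda lig: (float(samples.values[lig].min()), lig))


def rank_occurrence(samples: DeltaGSamples) -> RankTable:
    """Tally rank positions over groupings (best ΔG within each grouping).

    Every grouping must contain samples for every ligand; a missing ligand is
    a hard error naming it.
    """
    if samples.groups is None:
        raise ValueError("rank_occurrence requires grouped samples")
    ligands = samples.ligands
    pos = {lig: i for i, lig in enumerate(ligands)}
    gids = samples.group_ids()
    counts = np.zeros((len(ligands), len(ligands)), dtype=int)
    for g in gids:
        bests = {}
        for lig in ligands:
            mask = np.asarray(samples.groups[lig]) == g
            if not mask.any():
                raise ValueError(f"ligand {lig!r} has no samples in grouping {g!r}")
            bests[lig] = float(samples.values[lig][mask].min())
        ordered = sorted(ligands, key=lambda L: (bests[L], L))
        for rank, lig in enumerate(ordered):
            counts[pos[lig], rank] += 1
    return RankTable(ligands=ligands, counts=counts, n_groupings=len(gids))


@dataclass
class PairTest:
    ligand_a: str
    ligand_b: str
    t: float
    p: float
    significant: bool
    degenerate: bool = False  # zero variance in both samples


def welch_ttest_matrix(
    samples: DeltaGSamples,
    alpha: float = 0.05,
    holm: bool = False,
) -> list[PairTest]:
    """Two-sided Welch's t-test for every unordered ligand pair.

    ``significant`` is ``p < alpha`` on the raw p-values (matching reporting
    of raw p < 0.05 pairs); Holm step-down correction is available but off by
    default.  Pairs where both samples have zero variance are flagged
    degenerate: p = 1 when the means are equal, p = 0 otherwise.
    """
    ligands = samples.ligands
    for lig in ligands:
        if len(samples.values[lig]) < 2:
            raise ValueError(f"ligand {lig!r} needs at least 2 samples for a t-test")
    results: list[PairTest] = []
    for i, a in enumerate(ligands):
        for b in ligands[i + 1:]:
            xa, xb = samples.values[a], samples.values[b]
            if np.var(xa) == 0 and np.var(xb) == 0:
                if np.isclose(xa.mean(), xb.mean()):
                    results.append(PairTest(a, b, 0.0, 1.0, False, degenerate=True))
                else:
                    t = np.inf if xa.mean() > xb.mean() else -np.inf
                    results.append(PairTest(a, b, float(t), 0.0, True, degenerate=True))
                continue
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            results.append(PairTest(a, b, float(t), float(p), bool(p < alpha)))
    if holm:
        order = np.argsort([r.p for r in results])
        m = len(results)
        running_max = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * results[idx].p)
            running_max = max(running_max, adj)
            results[idx].p = running_max
            results[idx].significant = running_max < alpha
    return results


def consensus_ranking(table: RankTable) -> list[str]:
    """Order by mean occupied rank position (ascending); ties by rank-1
    count (descending), then label."""
    mean_rank = table.mean_rank()
    rank1 = {lig: int(table.counts[i, 0]) for i, lig in enumerate(table.ligands)}
    return sorted(table.ligands, key=lambda L: (mean_rank[L], -rank1[L], L))


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_deltaG_tsv(path) -> DeltaGSamples:
    """Read ligand/value(/group) rows from a tab-separated file."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("ligand", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    values = {
        str(lig): sub["value"].to_numpy(dtype=float)
        for lig, sub in df.groupby("ligand", sort=True)
    }
    groups = None
    if "group" in df.columns:
        groups = {
            str(lig): sub["group"].to_numpy()
            for lig, sub in df.groupby("ligand", sort=True)
        }
    return DeltaGSamples(values=values, groups=groups)


def write_deltaG_tsv(samples: DeltaGSamples, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        cols = "ligand\tvalue" + ("\tgroup" if samples.groups is not None else "")
        fh.write(cols + "\n")
        for lig in samples.ligands:
            vals = samples.values[lig]
            grp = samples.groups[lig] if samples.groups is not None else None
            for i, v in enumerate(vals):
                row = f"{lig}\t{repr(float(float(v)))}"
                if grp is not None:
                    row += f"\t{grp[i]}"
                fh.write(row + "\n")


def write_rank_table(table: RankTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_groupings = {table.n_groupings}\n")
        positions = "\t".join(f"rank_{p}" for p in range(1, len(table.ligands) + 1))
        fh.write(f"ligand\t{positions}\tmean_rank\n")
        mean_rank = table.mean_rank()
        for i, lig in enumerate(table.ligands):
            counts = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{lig}\t{counts}\t{mean_rank[lig]:.4f}\n")
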