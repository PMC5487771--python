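# Methods

This note documents the models, conventions and design choices behind
`gagmap`, in the order the pipeline runs.

## Data model and units

Ångström, kcal/mol, elementary charges and degrees throughout — the
conventions of the biomolecular force-field ecosystem the input numbers
come from. Source PDB residue numbering is preserved so protein residues
keep their literature labels (Lys 118 stays Lys 118); glycan rings
additionally carry 1-based indices counted from the non-reducing end, the
direction in which sulfation patterns are written. A structural ensemble is
a fixed topology plus an ordered stack of coordinate frames (one per PDB
MODEL); all frames must share the atom count and ordering of the first.

Glycan sulfation patterns are `-`-separated ring tokens
(`GlcNS6S-IdoA2S-…`): base `GlcN` or `IdoA`, an optional bare `S` directly
after `GlcN` for the N-sulfate, then positional codes (`2S`, `3S`, `6S`).
`GlcN` with an N-sulfate classifies as ring type `GlcNS`, `IdoA` with a
2-O-sulfate as `IdoA2S`; unknown bases map to `other`.

Frame subsampling takes `count` evenly spaced frames from the final
`tail_frames` window, endpoints included for `count ≥ 2`
(`rint(linspace)` over the window). Whether "evenly distributed" frames
should include window endpoints is a genuine convention choice; including
them is this package's reading and is pinned by tests.

## Hydrogen bonds

Geometric criterion (AMBER-style defaults): heavy-atom donor–acceptor
distance ≤ 3.0 Å **and** D–H···A angle ≥ 135° for at least one hydrogen
covalently bonded to the donor. Both cutoffs are configurable; the ≥/≤
conventions are fixed (at these tolerances the choice of strict vs
non-strict inequality is immaterial for real coordinates but is pinned for
reproducibility). Donors are N/O atoms carrying ≥ 1 bonded hydrogen;
acceptors are all N/O heavy atoms, sulfate and carboxylate oxygens
included; an atom may be both. Hydrogens are attached to their heavy atom
by covalent distance (< 1.2 Å) at parse time.

Occupancy is the fraction of frames in which a given donor-atom /
acceptor-atom pair has at least one qualifying geometry; several qualifying
hydrogens in one frame count once. Only inter-molecular (protein↔glycan)
pairs enter the tables by default. The residue-pair statistic used for
site-map cells is the **maximum** over that residue pair's atom pairs — a
sum would count one physical contact several times when it is visible
through multiple donor/acceptor atoms.

Structures without explicit hydrogens (typical crystal structures) fall
back to a distance-only criterion; every N/O atom is then a potential donor
and the output carries an explicit warning in its metadata.

## Interaction energies

Production per-residue-pair energies are expected to be **ingested** from
external MM-GBSA-style decompositions; the parser is header-driven (column
names, not positions), sums sidechain/backbone sub-rows into residue
totals when a location column is present, and always recomputes the
electrostatic total as vacuum + reaction field.

The internal engine is a deliberately simple pairwise model — not a
reimplementation of a GB solver. Born radii are inputs, never solved for,
and there is no nonpolar solvation term (the site-map channel split uses
only vdW + total electrostatics). Per atom pair at distance r:

- van der Waals: Lennard-Jones in the r_min/2 + ε convention with
  Lorentz–Berthelot combining, ε_ij((r_min/r)¹² − 2(r_min/r)⁶);
- vacuum electrostatics: k q₁q₂/(ε_in r), k = 332.0636 kcal·Å/(mol·e²);
- reaction field: −k(1/ε_in − 1/ε_solv) q₁q₂/f_GB with
  f_GB = sqrt(r² + R₁R₂ exp(−r²/(4R₁R₂))).

Defaults ε_in = 1, ε_solv = 78.5 (water). The engine exists so that the
downstream site-mapping mathematics can be exercised against an energy
source whose per-cell sums are *exactly* conservation-checkable: summing
all (residue, ring) cells component-wise reproduces the directly computed
whole-complex inter-molecular energy to floating-point precision (no
distance cutoff is applied, so nothing is lost). The reaction field
vanishes as ε_solv → ε_in, which the tests check at ε_solv = ε_in + 1e−9.
1–4 scaling conventions are irrelevant here because only inter-molecular
pairs are summed.

## Site-maps

Three channels on a (protein residue × ring index) grid: H-bond occupancy,
electrostatics, van der Waals. Energy channels store **favorable
magnitudes** max(0, −E); unfavorable (positive) cells are clipped to zero
and counted in the map's metadata. This makes the energy channels
non-negative and comparable to occupancies; the signed raw tables remain
available upstream.

Normalization: `per_ring` divides each ring column (per channel) by its
absolute sum — the convention that lets chains of different dp be compared
after aligning ring indices from the non-reducing end; all-zero columns are
left unchanged and flagged. `global` divides each channel by its grand
absolute sum. The exact denominator of per-ring normalization is a design
choice of this package (an absolute-sum convention), fixed here and
enforced as an invariant on every constructed map.

Aggregation over pose sets or structures is a per-channel weighted sum
followed by global normalization; it is scale-invariant and
permutation-invariant in the input order. Map comparison reports Pearson r
as the headline (Spearman alongside); zero-variance inputs yield an
explicit "undefined" result with a reason rather than NaN propagation.
Difference maps require both maps to carry the same normalization and
summarise cells above a |Δ| quantile (default top 5 %).

## Pose analysis

- RMSD over ordered atom pairs, optionally after least-squares (Kabsch)
  superposition.
- RMSatd pairs atoms **within each chemical element** by minimum total
  squared distance (Hungarian assignment, not greedy — greedy is
  order-dependent). Element is used as the atom type because force-field
  types are unavailable at parse time. Unequal element counts leave the
  surplus atoms unmatched and reported. RMSatd ≤ ordered RMSD whenever the
  index order is a valid same-type matching.
- Orientation: the ligand axis runs from the first (non-reducing) to the
  last ring heavy-atom centroid; angle θ to the reference axis classifies
  parallel (θ ≤ 45°), antiparallel (θ ≥ 135°) or perpendicular. The
  thresholds are symmetric tertiles around 90°, configurable; only the
  three labels are standard in the field, not the cut angles.
- Bound-pose filter: a pose is bound when **any** sugar heavy atom lies
  within the cutoff (default 10 Å) of the anchor point, e.g. the Cα of a
  marker binding-site residue; reading "a sugar residue within X Å" as a
  residue-to-point minimum over its atoms.

DBSCAN runs on a precomputed symmetric distance matrix (pose RMSD/RMSatd,
or loop RMSD). Conventions, fixed because implementations differ and
published (ε, minpoints) values only make sense under one convention:

- a point's ε-neighbourhood **includes the point itself**, so
  minpoints = 2 means "at least one other point within ε";
- border points join the first core cluster that reaches them in an
  ascending-index scan (deterministic);
- unreachable non-core points are noise (label −1).

Representatives are medoids (member minimizing summed in-cluster distance;
ties to the lowest index). Binding-loop clustering selects loop heavy atoms
by residue-number ranges, superposes each frame pair on those same atoms
before computing RMSD (so rigid-body motion of the whole complex cannot
split clusters — heavy atoms only, the choice here since hydrogens are
both noisy and often absent), and returns the medoids of the most
populated clusters.

## Ensemble ranking

`rank_by_best` orders ligands by their single most favourable ΔG (more
negative = rank 1). `rank_occurrence` applies that ranking within each
receptor-conformation grouping and tallies a ligand × rank-position count
table; `consensus_ranking` orders by mean occupied rank (ties: rank-1
count, then label). Pairwise comparisons use Welch's unequal-variance
two-sided t-test — there is no evidence of variance homogeneity across
docking-score distributions, so the pooled-variance test is not assumed.
Raw p < 0.05 decides significance by default; Holm step-down correction is
available but off, matching the common practice of reporting raw
significant pairs. Degenerate pairs (both samples constant) get p = 1 when
means are equal, p = 0 otherwise, and are flagged. All ranking and test
decisions are invariant to adding a constant to every ΔG.

Groupings are treated as **independent sample sets** (one per receptor
conformation / docking batch). This matters for the recovery guarantee: if
groupings were bootstrap resamples of one shared base sample, every
grouping would share the same sample minima and consensus ranking by
best-of-grouping would recover a planted order spaced 5 kcal/mol (SD 10,
n = 100) only ~⅓ of the time — a calibration simulation during development
showed exactly that — whereas with independent per-grouping draws the
recovery rate is ~100 %. The synthetic generator therefore draws each
grouping fresh, emulating "100 solutions per ligand per receptor
conformation".

## The synthetic test bed

The generators return their ground truth alongside the data; no test
re-infers truth from the data it checks. Defaults define the study
conditions and are not tuned per test.

**Toy complexes** (`gen_toy_complex_ensemble`): protein residues are
four-atom fragments (backbone C, amide-like N–H donor, charged side-chain
N) and glycan rings four-atom fragments (two ring carbons, hydroxyl-like
acceptor O, charged sulfate/carboxylate O) on a chain with 9 Å ring
spacing. Geometry over physical realism: the fragments exist to exercise
the detectors' definitions, not to fold. Planted H-bond pairs toggle the
donor group between 2.8 Å (in-window, D–H···A = 180°) and 3.6 Å
(out-of-window) from the acceptor — Bernoulli per frame by default
(matching a time-fraction statistic), an `exact` mode realising
round(p·n) frames deterministically, and a Markov-switching stress mode
with stationary occupancy p. Planted hot pairs place opposite charges
across the interface, with the side-chain charge calibrated against the
engine's own pair formula so the cell's electrostatic mean lands near the
requested value (−8 kcal/mol by default, over a unit-SD background); the
donor/acceptor contact atoms carry an LJ minimum at the 2.8 Å contact so
planted pairs are favorable in all three channels. Defaults: 10 protein
residues, fully sulfated dp6 pattern, 100 frames, five planted pairs with
occupancies 0.9–0.2, coordinate jitter SD 0.02 Å on non-planted atoms.
Atoms closer than 0.8 Å trigger a bounded regeneration, then a hard error.

**Pose sets** (`gen_pose_set`): bound clusters are distinct rigid
placements of the glycan template with the non-reducing ring pinned ~4 Å
from the anchor (so every clustered pose passes the bound filter), rotated
120°/n apart so clusters sit far apart in pose-RMSD space (the
`center_spread` parameter is a floor on that separation); membership blurs
with isotropic coordinate noise (SD 0.5 Å ⇒ within-cluster RMSD ≈ 1.2 Å,
well under the ε = 3 Å clustering scale). Unbound poses sit on distinct
radial shells beyond the cutoff, mutually separated so they label as
noise. Defaults: 100 poses, 3 clusters, 30 % unbound.

**Decomposition fixtures** (`gen_decomp_fixture`): table-level planting —
background cells −|N(0, noise_sd)| per energy channel and occupancies
U(0, 0.15); hot cells N(−8, noise_sd) and occupancies U(0.75, 0.95). The
vacuum/reaction-field split of the electrostatic total uses
vac = 1.6·total, rf = −0.6·total, mimicking partial solvent screening. The
fixture also returns a matching planted occupancy table so recovery checks
cover all three channels.

**ΔG samples** (`gen_deltaG_samples`): normal draws at planted means
(−60 … −40 kcal/mol spaced 5), SD 10, n = 100 per ligand (per grouping
when grouped).

What the toys do *not* emulate: conformational correlation between frames
(beyond the optional Markov mode), water-mediated bridges, realistic
charge distributions, anisotropic pose noise, or score–geometry coupling.
Passing tests therefore certify the *analysis mathematics* — detection,
aggregation, normalization, clustering, ranking — not the physics of any
force field or docking engine.

## Numerical choices and degenerate inputs

- All TSV writers emit shortest-round-trip floats; write→read reproduces
  tables beyond 1e−6 and PDB coordinates to the format's 1e−3 Å.
- Angle test uses a cosine comparison with a 1e−12 slack against the exact
  threshold.
- Deterministic tie-breaks everywhere: top-k bonds by (occupancy, donor
  resnum, acceptor resnum, atom names); top cells by (value, residue,
  ring); medoids and border points by lowest index; rank ties by label.
- Zero-variance correlations and t-tests return explicit flagged results
  instead of NaNs; all-zero normalization columns are left untouched and
  flagged.
- Every generator is fully deterministic under its integer seed (seeded
  `default_rng` sequences; no time-based state).

## Problem sizes

The test suite and the acceptance script run at desk scale by design: toy
complexes of ~64 atoms × 100 frames, 100-frame detector oracles on
~50-atom random frames, 200-point clustering comparisons across 20
parameter settings, 100-seed site-map recovery, and 200-replicate ranking
recovery with 100 groupings × 100 samples per ligand. These sizes make
every check exhaustive or statistically overwhelming while keeping the
whole suite under a minute of compute.

## Known limitations

- The internal energy engine is a stand-in for testing the analysis
  layer; its absolute energies are not comparable to MM-GBSA output.
- Multi-model PDB (and the canonical TSVs) are the only trajectory/table
  formats; binary trajectory formats are out of scope.
- Site-maps compare only maps sharing an index set; comparing different
  proteins requires upstream residue mapping.
- Whether published loop-clustering used heavy atoms only, or superposed
  globally rather than on the loop, is not standardised; this package's
  choices (heavy atoms, loop superposition) are documented above and
  configurable only by editing the selection.
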