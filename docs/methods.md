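# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `loopconf`, in the order the pipeline applies them.

## Coordinates, units and data model

Coordinates are stored in nanometres throughout; multi-model PDB I/O
(via biotite) converts Å↔nm at the boundary, because every analysis
threshold (0.2 nm cluster cut-off, 0.35 nm hydrogen-bond distance,
1.4 nm energy cut-off) is conventionally quoted in nm. A `Topology`
couples the atom table — names, author residue numbering, partial
charges (e), Lennard-Jones C6 (kJ mol⁻¹ nm⁶) and C12 (kJ mol⁻¹ nm¹²),
hydrogen-bond roles — with an explicit donor–hydrogen bond table; the
per-atom data arrive in a plain whitespace-delimited sidecar file rather
than a force-field topology, keeping the reader engine-neutral. Frames
carry a timestamp (ps) and an optional system label, which is how
multi-system ensembles remain attributable after timewise concatenation.

There is **no periodic-boundary handling**: all distances are plain
Euclidean. Every quantity computed here acts within ≤ 1.4 nm on a single
(synthetic, whole) molecule pair, where minimum-image corrections would
be inert; trajectories with broken molecules across a box boundary must
be made whole upstream. The loop and flanking residue ranges are
configuration, not constants — real receptors differ, so the selections
(`resid 7-14`, `name CA and resid 1-6 15-20` for the bundled synthetic
system) are always explicit.

## Superposition, RMSF, RMSD

Rigid-body fits use the Kabsch algorithm (SVD of the cross-covariance
with the determinant-sign correction), so reflections are never
returned; degenerate inputs (< 3 atoms, collinear fit group) are
refused. Fits are **unweighted** — the descriptors are defined on plain
coordinates and fitting is typically restricted to Cα anyway; no mass-
or B-factor weighting is offered.

RMSF fits every frame to a reference over the fit selection and measures
each atom's root-mean-square deviation from its *mean fitted position*.
The fit reference is configurable and defaults to the **first frame**;
passing `average_frame(...)` instead fits to the mean structure. The two
choices differ only when the ensemble mean drifts relative to frame one;
both are exposed rather than silently picking one. A single-frame
trajectory is refused (zero-variance degenerate) rather than returning
zeros.

Loop RMSD fits on the flanking Cα backbone and measures over **all loop
atoms** by default; any measure selection (e.g. backbone-only) can be
passed. The all-against-all matrix supports two routes:

- `fit_sel` given: every pair is superposed independently (batched SVD),
  then symmetrized — exact but O(n²) fits;
- `fit_sel=None`: frames are compared as-is. Fitting every frame once to
  the ensemble's first frame and then using this route is the pipeline
  default; when the fit group is rigid (as planted in the generator, and
  approximately true for a stable β-sheet scaffold) it agrees with the
  per-pair route while scaling to 10⁴-frame ensembles in seconds. The
  Gram-matrix formulation runs in a single n×n buffer, and the matrix
  symmetrization/validation are blocked so no full-matrix temporary is
  allocated (a 15,000-frame ensemble peaks near 2.5 GB).

## Clustering (Daura / GROMOS)

Greedy neighbour counting on the RMSD matrix: among unassigned frames,
the one with the most unassigned neighbours at distance ≤ cut-off —
**counting itself** — becomes a centre; the cluster is removed; repeat.
Ties in the neighbour count break to the lowest frame index, and output
clusters are numbered by descending size (ties by earliest centre
index), so "cluster 1" is always the most populated conformation. These
two conventions make the algorithm fully deterministic; both are checked
against an independently coded step-by-step simulation of the rules in
the tests.

The default cut-off is 0.2 nm. Composition fractions are normalized
**per system** (members with a label divided by that system's total
frames), so statements like "the apo system spends 82% of its time in
cluster 2" read directly off the table. The cut-off sweep reports
cluster counts across cut-offs (non-increasing in the cut-off), and the
incremental diagnostic reclusters growing trajectory prefixes; its count
curve typically levels off once sampling stops discovering new
conformations, but monotonicity is *not* an algorithmic guarantee and is
reported as observed, never asserted.

## Non-metric MDS and meta-clusters

The distance submatrix over the top-K cluster centres (default K = 25;
frames in clusters beyond the top K are reported in an explicit
"unassigned" channel rather than dropped) is embedded in 2D by
minimizing Kruskal stress-1,

    stress = sqrt( Σ (d_ij − d̂_ij)² / Σ d_ij² ),

alternating isotonic (monotone) regression of the configuration
distances on the dissimilarity rank order with Guttman-transform
configuration updates. Numerical choices:

- **Ties** in the dissimilarities follow the primary approach: tied
  input values may receive distinct disparities.
- **Disparity normalization**: after each isotonic fit the disparities
  are rescaled to the distances' total square sum. This pins the free
  overall scale; without it the normalized stress can drift upward even
  as the raw stress decreases.
- **Monotone safeguard**: an update that would increase stress-1 is
  rejected and terminates the run, so the reported stress sequence is
  non-increasing by construction. Convergence tolerance 1e-6 on the
  stress decrease, max 500 iterations.
- **Initialization**: restart 0 starts from the classical-scaling
  (PCoA) configuration; three further restarts are random from the seed
  and replace it only on a strict stress improvement beyond the
  tolerance. With small, heavily tied centre sets (exactly the regime
  here) purely random starts routinely converge to degenerate
  rank-preserving distortions — near-zero stress, but inter/intra
  distance ratios unrelated to the input — which breaks any
  distance-threshold grouping downstream. Anchoring one restart at the
  metric solution keeps near-embeddable inputs undistorted while leaving
  the non-metric criterion in charge.
- **Output scale**: stress-1 is scale-invariant, so the final
  configuration is rescaled to the least-squares match between embedded
  distances and input dissimilarities. Embedded distances thus carry the
  input units (nm for RMSD input), making the meta-cluster threshold
  interpretable.

Meta-clusters replace the manual "circled by hand" grouping of nearby
centres with deterministic single-linkage connected components at a
user-set threshold (bundled default 0.45 nm, between the planted
intra-group ≈ 0.27 nm and inter-group ≥ 0.74 nm centre distances); the
threshold is recorded in the run manifest. Per-system meta-cluster
residence fractions sum to 1 including the unassigned remainder.

## Hydrogen bonds and non-bonded energies

A hydrogen bond requires a flagged donor with a covalently bound
hydrogen in one group and a flagged acceptor in the other (both
directions are searched), donor–acceptor distance ≤ 0.35 nm, and an
angular criterion. The default convention is **acceptor–donor–hydrogen ≤
30°** (the hydrogen lies within a 30° cone about the donor→acceptor
axis, measured at the donor); the near-linearity convention
donor–hydrogen–acceptor ≥ 150° is available as `angle_convention="DHA"`.
The 30° magnitude only makes sense with the vertex at the donor — with
the vertex at the hydrogen, 30° would describe a folded, non-bonding
geometry — so the donor-vertex form is the default, and the convention
in force is logged with the run. The distance criterion is
donor–acceptor, not hydrogen–acceptor.

Energies are plain truncated pair sums between two disjoint groups:
E_Coul = Σ f·q_i·q_j/r_ij with f = 138.935458 kJ mol⁻¹ nm e⁻², and
E_LJ = Σ C12_ij/r_ij¹² − C6_ij/r_ij⁶ with geometric-mean combination of
the per-atom parameters, cut-off 1.4 nm, no switching function and no
long-range correction — short-range terms only, by design. Histograms
use half-open bins [k·w, (k+1)·w) (an edge value belongs to the higher
bin) with bundled widths of 100 and 10 kJ/mol, and always conserve the
frame count.

## The synthetic generator

`make_loop_system` builds a hairpin: two six-residue flanking strands
(N/CA/O per residue) bridged by an eight-residue loop (N/CA/O plus an
amide hydrogen; loop N atoms are donors, all O atoms acceptors). Loop
conformations come from rotating the loop arc (radius 0.7 nm) about the
axis through its anchor points — a one-parameter pseudo-dihedral
deformation giving inter-state Cα RMSD ≈ 2·0.71·r·sin(Δφ/2), so state
separations are dialled directly in degrees. Per frame, a state is drawn
(independently from stationary occupancies, or from a Markov chain when
time structure is wanted, e.g. for the convergence diagnostic), loop
atoms get isotropic Gaussian noise (default σ = 0.02 nm per coordinate,
comfortably below half the 0.2 nm cut-off), scaffold atoms smaller noise
(σ = 0.005 nm), and optionally the whole frame undergoes a small random
rigid motion (≤ 3°, ≤ 0.05 nm) to exercise the fitting stage. State,
noise and motion draws come from independent seeded streams, so toggling
the rigid motion leaves the noise realization unchanged — which is how
the fit-invariance property is tested. True state labels are returned
for recovery scoring.

The bundled study plan plants six conformations in three well-separated
groups (pairwise centre RMSD ≈ 0.27 nm within a group, ≥ 0.74 nm
between) and three systems drawing from them: an apo-like system 80% in
its own group / 20% in the shared one, a ligand that spends 70% shared /
30% in a unique group, and a ligand locked 100% into the shared group.

What the generator does **not** emulate: force-field energetics,
solvent, correlated or diffusive dynamics, gradual conformational
transitions, scaffold deformation coupled to loop state. Passing tests
therefore demonstrate that the *analysis chain* recovers planted
structure under realistic noise and sampling — not that any particular
real receptor behaves this way. Two demo-specific artefacts are worth
naming: the loop–scaffold energy series is dominated by repulsive
contacts at the covalent seam between the groups (real studies measure
receptor–ligand interfaces between separate molecules, which is also why
no 1-2/1-3/1-4 exclusions are implemented), and the loop–scaffold
hydrogen-bond histogram peaks at zero because the planted conformations
keep the loop donors away from the scaffold — the detector's positive
path is exercised by a dedicated fixture with a planted on/off schedule.

## Problem sizes and determinism

Bundled analysis runs use 400–600 frames per system; the recovery tests
run at 4,000–15,000 frames total (binomial sampling error at these sizes
is well inside the ±0.03 recovery tolerance used); the acceptance script
uses 2,000 frames per system. Every random draw — generator, MDS
restarts, brute-force rotation grids — derives from an explicit seed,
and two pipeline runs from one configuration and seed produce
byte-identical outputs (checked file-by-file in the tests; the manifest
records parameters, seeds and SHA-256 checksums of every output).

## Known limitations

- No trajectory formats beyond multi-model PDB (+ sidecar); no
  GRO/XTC/TRR readers.
- No periodic boundaries, no minimum-image distances.
- Per-pair-fit RMSD matrices are O(n²) superpositions and intended for
  n ≲ 2,000; larger ensembles use the fit-once route, which assumes the
  fit group is rigid.
- Single-linkage meta-clustering needs a user-chosen threshold; there is
  no automatic meta-cluster count selection.
- The energy kernel implements fixed point charges and geometric-mean LJ
  combination only; no PME/reaction field, no polarization.
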