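# Methods

## Model and scope

The package compares two MD trajectories of a bead-per-residue protein
chain by the symmetrized Kullback–Leibler divergence (KLD) between each
residue's positional distribution, after rigid-body alignment to a
common reference. It assumes residue correspondence by index (no
sequence alignment), unwrapped coordinates (no periodic-boundary
handling), and that each residue is represented by one backbone bead.
All internal coordinates are nm; user-facing RMSD and distances are
reported in Å to match structural-biology convention, and PDB I/O
converts Å↔nm at the boundary.

## Alignment

Every frame is superposed on the first snapshot of a designated
reference trajectory by weighted Kabsch superposition (proper rotations
only; reflections rejected by the usual sign correction on the smallest
singular direction; point sets with fewer than 3 points or an
effectively collinear geometry are rejected). Pairwise alignment before
divergence profiling is iterative:

1. align both trajectories with uniform weights;
2. pool the per-selected-bead positional variance over both aligned
   trajectories;
3. set w_i ∝ 1/(variance_i + ε) with ε = 1e-4 nm², rescaled to max 1;
4. realign, stopping when the mean geodesic angle between successive
   per-frame rotations drops below `tol` (default 1e-3 rad) or after
   `max_iter` (default 10) iterations.

Down-weighting mobile residues is the purpose of iterating: a loop in
genuine motion should not drag the superposition of the rigid core.
Non-convergence is reported by flag and warning, not as an error. On
rigid-body-only pairs the loop converges by the second iteration with
uniform weights.

## Discretization and the divergence estimator

Per residue, both trajectories' backbone-bead positions are binned on a
shared axis-aligned 3D grid covering their joint bounding box. The grid
origin sits 1.5 bins below the observed minimum so extreme points are
strictly interior to bins (no floating-point edge ties), with at least
one empty padding bin per side. Before normalization every bin receives
an additive pseudocount (default 0.5), which keeps both directed
divergences finite and treats the two trajectories symmetrically. The
symmetrized value is the arithmetic mean of the two directions,
½[KLD(P,Q) + KLD(Q,P)], in nats (a bits option rescales by 1/ln 2).
Snapshots are paired by index after truncation to the shorter
trajectory; only distributional content matters, so pairing affects
nothing but window bookkeeping.

**Bin width.** The default is 0.1 nm for full-trajectory profiles: with
2000 snapshots and ~0.1 nm fluctuation scales, each residue's histogram
is adequately populated. Windowed (time-resolved) estimates are a
different regime: a 50-snapshot window over a 0.1 nm-binned cloud of
0.1 nm width spreads ~50 samples over several hundred occupied bins, and
the resulting small-sample bias of the plug-in KLD rises to a large
fraction of any real signal. The standard histogram-density rule applies
— keep the occupied bin count well below the sample count — so windowed
analyses in the examples and validation use 0.2 nm bins, at which the
null (identical-distribution) windowed divergence stays near 20% of a
0.5 nm-switch plateau instead of ~65%. Both parameters are exposed on
`BinningSpec`; absolute KLD values always depend on the discretization
and are comparable only within one configuration (the normalization
constant of windowed maps is recorded on the map for this reason).

**Estimator floor.** For two identical distributions the plug-in
divergence is positive at finite n and decreases as n grows; the test
suite checks this consistency property, and the acceptance script
reports the 99th-percentile floor under the default study conditions.

## Moving windows

Window *w* (1-based) covers snapshots max(1, w−W+1) … min(w, N) for
w = 1 … N+W−1: windows grow from a single snapshot to width W, slide,
and shrink from the left once the trajectory end is reached. The window
axis is reported by right-edge snapshot. With W ≥ N the full-width
window reproduces the whole-trajectory profile exactly (same grids, same
counts). Maps from several comparisons are normalized jointly by their
single global maximum, so 1.0 marks the largest difference over the
whole comparison set and 0.0 no difference; per-map normalization is
available behind a flag.

## Geometry observables

*RMSD* is computed against a reference frame with no re-superposition —
region RMSD deliberately inherits the global alignment, so a region's
displacement relative to the aligned core is visible. *COM distances*
default to uniform bead masses (per-bead masses are a config hook).
*SASA* is Shrake–Rupley with a deterministic generalized-spiral point
set (default 960 points per bead): for each target bead the accessible
fraction of points on the sphere of radius r_i + probe, not buried in
any other inflated bead, scales the analytic sphere area. Context beads
occlude without contributing area. Default bead radius and probe are
both 0.26 nm, the regular Martini bead radius. Quadrature error at 960
points is well under 1% against the analytic sphere and under 2% against
Monte-Carlo surface sampling for overlapping pairs.

## Synthetic data

The generator emulates the statistical structure the analysis assumes
and nothing more: per-residue independent isotropic Gaussian
fluctuations (default σ = 0.1 nm) about an ideal-helix reference chain
(rise 0.15 nm, radius 0.23 nm, 100°/residue — geometry is
seed-independent; the seed drives only dynamics), wrapped in independent
rigid-body random walks (defaults: 0.002 rad and 0.01 nm per-frame
steps) so alignment is genuinely exercised. Default pair size is 100
residues × 2000 snapshots, which the full pipeline processes in seconds.

Planted events: `mean_shift` displaces a residue block's mean by a given
magnitude along a random unit vector; `two_state_switch` applies the
displacement from a given snapshot onward; `flip_pair` splits its
residue range into two halves and displaces them in opposite directions
by the magnitude along their connecting axis from the switch snapshot
onward — a perfect positional exchange when the magnitude equals the
centroid separation, and the analog of two side chains swapping places.
Planted anchor distances for the flip are computable in closed form from
the reference geometry (`flip_pair_planted_distances`), since rigid
drift preserves internal distances. One RNG stream is seeded once with a
fixed draw order (baseline noise A, baseline noise B, walk A, walk B,
event directions last), so adding an event perturbs no other draws.
Overlapping events are rejected.

What this generator does **not** model: bonds, excluded volume,
correlated residue motion, or any force field. Passing tests therefore
demonstrate that the estimator and pipeline behave correctly when their
distributional assumptions hold exactly — not that real coarse-grained
trajectories satisfy those assumptions. In real data, correlated motion
makes per-residue divergences correlated along the chain, and absolute
KLD magnitudes are not transferable across discretizations.

The gate system places a target bead inside a shell of occluders at
deterministic sphere directions whose radius interpolates linearly
between an open and a closed value; with 48 occluders at 0.26 nm radius
the closed shell (0.4 nm) fully covers the target's probe-inflated
surface, so the SASA series runs monotonically from the free-sphere
value to ~0.

## Numerical choices and degenerate inputs

Empty selections raise rather than return silently. Histogram geometry
mismatches between compared distributions are errors. All-zero windowed
maps are returned unchanged from normalization with a warning. Alignment
of under-determined point sets raises a degeneracy error carrying the
frame context. Unequal frame counts in windowed comparison truncate to
the shorter trajectory with a warning. Pipeline failures remove partial
outputs; pipeline TSVs are written with fixed formatting so identical
plans reproduce byte-identical files, each carrying a config hash.

## Validation problem sizes

The validation suite runs the full study conditions (100 residues, 2000
snapshots) for the 20-seed recovery and change-point experiments, and
smaller chains (20–60 residues, 200–800 snapshots) for unit-level
properties, keeping the whole suite under a minute of single-core time.

## Known limitations

Residue correspondence is positional (index-based); no support for
insertions/deletions between compared systems. The divergence carries no
significance test — peaks are ranked, not tested. SASA uses a single
radius table per run; per-frame radii are unsupported. The TSV fixture
format stores 1e-6 nm precision and is intended for tests and small
exchanges, not production trajectories.
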