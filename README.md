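# trajdiverge

Per-residue divergence analysis for pairs of molecular-dynamics
trajectories of coarse-grained (bead-per-residue) proteins.

## The problem

Long coarse-grained MD simulations — e.g. of a cryptochrome
photoreceptor cycling through the redox states of its flavin cofactor —
produce pairs of trajectories that must be compared *structurally*: which
residues move differently between two simulations, when does a loop gate
open or close, how does the solvent exposure of a buried cofactor evolve,
and how are cofactor–residue distances distributed? Frame-by-frame RMSD
alone cannot separate "mobile but identically distributed" from
"genuinely different conformation". This package implements the
distribution-level comparison used for that purpose, for structural
bioinformaticians analysing trajectory ensembles.

## The statistic

For two trajectories *Q* and *P*, aligned to a common reference, the
positions of residue *i*'s backbone bead are discretized into a 3D
histogram on a shared grid. The Kullback–Leibler divergence

&nbsp;&nbsp;&nbsp;&nbsp;KLD(*P*<sub>i</sub>, *Q*<sub>i</sub>) = Σ<sub>k</sub> *q*<sub>k</sub> ln(*q*<sub>k</sub> / *p*<sub>k</sub>)

is symmetrized as the arithmetic mean of both directions and reported per
residue (in nats). Because the statistic compares *distributions*, two
simulations with equally high but similar residue motion diverge little;
only distributional differences register. A moving-window variant
(windows grow to a maximum of *W* = 50 snapshots, slide, then shrink at
the trajectory end, so window *w* covers snapshots max(1, *w*−*W*+1) …
min(*w*, *N*)) resolves the divergence in time; maps from several
comparisons are normalized jointly so that 1.0 marks the largest
difference observed over the whole comparison set.

Around the core statistic the package provides:

* **Iterative pairwise alignment** — weighted Kabsch superposition onto a
  reference snapshot, iterated with inverse-variance reweighting so
  genuinely mobile residues do not drag the fit.
* **RMSD series** (Å) for arbitrary selections, including region RMSD
  without re-alignment.
* **Shrake–Rupley SASA** with a deterministic spiral quadrature and a
  0.26 nm probe (one regular Martini bead).
* **Center-of-mass distance distributions** between bead groups (e.g. a
  five-bead flavin cofactor and individual tryptophan residues), with
  min/max summaries, histograms and mode detection.
* **A synthetic-data generator** producing trajectory pairs with shared
  baseline fluctuations, rigid-body drift, and planted conformational
  events (mean shift, two-state switch, positional flip) plus a closing
  "gate" system — every pipeline stage is testable with known ground
  truth and no external data.

Standard formats (GRO, PDB, multi-model PDB, XTC/DCD) are read and
written via MDAnalysis; a plain-text TSV fixture format is provided so
the test suite needs no binary codecs.

## Worked example

`examples/01_divergence_profile.py` plants a 0.5 nm mean shift on
residues 40–60 of a 100-residue chain (2000 snapshots, 0.1 nm baseline
fluctuation, rigid-body drift), aligns both trajectories, and profiles
the divergence:

```
alignment: 4 iterations, converged=True
planted residues : 40-60 (mean shift 0.5 nm)
top-21 by KLD    : 40-60 (contiguous=True)
max divergence   : 2.678 nats at residue 40
background median: 0.139 nats
```

The 21 planted residues occupy exactly the top 21 profile ranks, an
order of magnitude above the sampling floor that finite snapshot counts
impose on identical distributions. The other examples demonstrate
change-point localization with the windowed map, the SASA gate-closing
signature, distance-distribution bimodality from a positional flip, and
the full multi-comparison pipeline with its ranked region report
(regions such as an EEE linear-motif segment at residues 440–460, a
surface patch at 80–90, and a C-terminal tail from residue 480 are
built-in defaults; the phosphate-binding loop span is user-supplied).

A thin CLI mirrors the library (`trajdiverge simulate | align | compare |
window | rmsd | sasa | dist | report`); see `trajdiverge --help`.

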