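"""Per-residue divergence profile between two trajectories.

Generates a synthetic pair in which residues 40-60 are mean-shifted by
0.5 nm in trajectory B, aligns both trajectories to A's first snapshot,
and computes the symmetrized Kullback-Leibler divergence per residue.
High values mark residues whose positional distributions differ between
the two simulations; the planted region should dominate the profile.
"""

import numpy as np

from trajdiverge import (
    Event,
    SyntheticConfig,
    divergence_profile,
    generate_pair,
    iterative_align,
    resolve_selection,
)

config = SyntheticConfig(
    n_residues=100,
    n_frames=2000,
    baseline_sigma=0.1,
    events=(Event("mean_shift", (40, 60), 0.5),),
    seed=1,
)
traj_a, traj_b, truth = generate_pair(config)

sel = resolve_selection(traj_a, "backbone")
res_a, res_b = iterative_align(traj_a, traj_b, traj_a, sel)
print(
    f"alignment: {res_a.n_iterations} iterations, converged={res_a.converged}"
)

profile = divergence_profile(res_a.trajectory, res_b.trajectory, sel)
top = sorted(int(r) for r in profile.top_residues(21))
print(f"planted residues : 40-60 (mean shift {truth[0].magnitude} nm)")
print(f"top-21 by KLD    : {top[0]}-{top[-1]}"
      f" (contiguous={top == list(range(top[0], top[-1] + 1))})")
print(f"max divergence   : {profile.values.max():.3f} nats "
      f"at residue {int(profile.residue_indices[np.argmax(profile.values)])}")
print(f"background median: {np.median(profile.values):.3f} nats")
# The planted region should carry divergences an order of magnitude above
# the background floor set by finite sampling of identical distributions.
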