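"""Time-resolved divergence: locating a conformational switch.

Trajectory B's residues 40-60 jump to a 0.5 nm-shifted state at snapshot
1000 (of 2000). The moving-window divergence (windows grow to 50
snapshots, slide, then shrink at the trajectory end) localizes the
switch: windows before it show only the sampling floor, windows after it
plateau, and the half-plateau crossing falls within one window width of
the true switch.

Windowed estimates use 0.2 nm bins: a 50-snapshot window must populate
the per-residue histogram, so the occupied bin count has to stay well
below the window size.
"""

import numpy as np

from trajdiverge import (
    BinningSpec,
    Event,
    SyntheticConfig,
    generate_pair,
    iterative_align,
    normalize_maps,
    resolve_selection,
    windowed_divergence,
)

SWITCH = 1000
config = SyntheticConfig(
    events=(Event("two_state_switch", (40, 60), 0.5, switch_frame=SWITCH),),
    seed=1,
)
traj_a, traj_b, _ = generate_pair(config)

sel = resolve_selection(traj_a, "backbone")
res_a, res_b = iterative_align(traj_a, traj_b, traj_a, sel)

planted = resolve_selection(traj_a, "backbone and resid 40-60")
wmap = windowed_divergence(
    res_a.trajectory, res_b.trajectory, planted,
    BinningSpec(bin_width=0.2), max_window=50,
)
wmap = normalize_maps([wmap])[0]

series = wmap.values.mean(axis=1)  # mean over the planted residues
full = (wmap.window_stops - wmap.window_starts + 1) == 50
plateau = series[full & (wmap.window_starts > SWITCH + 200)
                 & (wmap.window_stops <= 1900)].mean()
first = int(np.argmax(series > 0.5 * plateau))
edge = int(wmap.window_stops[first])

print(f"windows computed      : {wmap.n_windows} (max width {wmap.max_window})")
print(f"normalization constant: {wmap.normalization:.4f} nats -> map max 1.0")
print(f"post-switch plateau   : {plateau:.3f} (normalized units)")
print(f"half-plateau crossing : window ending at snapshot {edge}")
print(f"planted switch        : snapshot {SWITCH + 1}"
      f" (localization error {abs(edge - SWITCH - 1)} snapshots)")
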