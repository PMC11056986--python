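"""Solvent accessibility of a buried cofactor while a gate closes.

A target bead (the cofactor analog) sits inside a shell of occluder
beads whose radius contracts linearly over the trajectory — the
geometry of a loop gate closing over a binding pocket. Shrake-Rupley
SASA with a 0.26 nm probe (one regular Martini bead) drops monotonically
from the free-sphere value to near zero at full enclosure.
"""

import numpy as np

from trajdiverge import (
    GateConfig,
    generate_gate_system,
    resolve_selection,
    sasa_series,
)

config = GateConfig(n_frames=30, n_occluders=48, r_start=1.6, r_end=0.4)
traj = generate_gate_system(config)
target = resolve_selection(traj, "name TGT")
occluders = resolve_selection(traj, "name OCC")

series = sasa_series(traj, target, occluders)

free_sphere = 4 * np.pi * (0.26 + 0.26) ** 2
print(f"isolated-bead SASA  : {free_sphere:.4f} nm^2 (analytic)")
print(f"open-state SASA     : {series[0]:.4f} nm^2 (shell at {config.r_start} nm)")
print(f"closed-state SASA   : {series[-1]:.4f} nm^2 (shell at {config.r_end} nm)")
print(f"monotone closing    : {bool((np.diff(series) <= 1e-9).all())}")
print(f"occlusion fraction  : {1 - series[-1] / series[0]:.1%}")
for f in range(0, config.n_frames, 6):
    bar = "#" * int(40 * series[f] / series[0])
    print(f"  frame {f:3d}  {series[f]:7.4f} nm^2  {bar}")
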