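"""The full comparison workflow in one plan.

Two synthetic trajectories are compared to a shared reference: one
carries a 0.5 nm mean shift on a "loop" region, the other is
event-free. The plan aligns each comparison to the reference, computes
profiles, windowed maps (normalized jointly, so 1.0 marks the largest
difference over the whole comparison set), per-region RMSD, and a
ranked region report — the quantitative summary a practitioner would
read first.
"""

import tempfile
from pathlib import Path

from trajdiverge import (
    BinningSpec,
    ComparisonPlan,
    Event,
    RegionSet,
    SyntheticConfig,
    TrajectorySource,
    generate_pair,
    run_comparison,
)

ref_cfg = SyntheticConfig(n_residues=60, n_frames=800, seed=21)
traj_ref, traj_shifted, _ = generate_pair(
    SyntheticConfig(
        n_residues=60, n_frames=800, seed=21,
        events=(Event("mean_shift", (25, 32), 0.5),),
    )
)
_, traj_quiet, _ = generate_pair(ref_cfg)

out_dir = Path(tempfile.mkdtemp(prefix="trajdiverge_"))
plan = ComparisonPlan(
    reference=TrajectorySource("reference", trajectory=traj_ref),
    comparisons=[
        TrajectorySource("shifted_loop", trajectory=traj_shifted),
        TrajectorySource("no_event", trajectory=traj_quiet),
    ],
    regions=RegionSet({"LOOP": [(25, 32)], "HEAD": [(1, 10)], "TAIL": [(50, 60)]}),
    binning=BinningSpec(bin_width=0.2),
    max_window=50,
    out_dir=str(out_dir),
    seed=21,
)
result = run_comparison(plan)

print(result.report.table.to_string(index=False))
print(f"\njoint normalization constant: {result.normalization:.4f} nats")
for outcome in result.outcomes:
    print(
        f"{outcome.label:13s} window-map max {outcome.window_map.values.max():.3f}"
        f"  degenerate={outcome.degenerate}"
    )
print(f"\nTSV artifacts written to {out_dir}:")
for p in sorted(result.written_files):
    print(f"  {p.name}")
# The LOOP region ranks 1 in the event-bearing comparison, and the joint
# scaling puts the global maximum (1.0) in that comparison's map.
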