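"""End-to-end comparison workflow.

A :class:`ComparisonPlan` names one reference trajectory and a set of
trajectories to compare against it. Running the plan performs, per
comparison: iterative pairwise alignment to the reference's first frame,
the full-trajectory divergence profile, the moving-window divergence map,
whole-backbone and per-region RMSD; then normalizes all windowed maps
jointly by their single global maximum (so 1.0 is the largest difference
observed over the whole comparison set) and aggregates divergences over
the named regions into a ranked report.

All tabular outputs are TSV with ``#``-prefixed metadata headers carrying
the plan's config hash so reruns are byte-identical and attributable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .alignment import AlignmentResult, iterative_align
from .divergence import (
    BinningSpec,
    DivergenceProfile,
    WindowedDivergenceMap,
    divergence_profile,
    normalize_maps,
    windowed_divergence,
)
from .errors import ConfigurationError
from .geometry import RmsdSeries, rmsd_series
from .model import RegionSet, Trajectory
from .selection import resolve_selection

logger = logging.getLogger(__name__)

#: Divergence below which a comparison is flagged as degenerate (self-like).
DEGENERATE_KLD = 1e-9


@dataclass
class TrajectorySource:
    """A labelled trajectory, either in memory or on disk."""

    label: str
    trajectory: Trajectory | None = None
    structure_path: str | None = None
    trajectory_path: str | None = None
    format: str | None = None

    def load(self) -> Trajectory:
        if self.trajectory is not None:
            traj = self.trajectory
        elif self.structure_path and self.trajectory_path:
            structure = tio.read_structure(self.structure_path)
            traj = tio.read_trajectory(
                structure, self.trajectory_path, self.format
            )
        elif self.trajectory_path:
            traj = tio.read_tsv_fixture(self.trajectory_path)
        else:
            raise ConfigurationError(
                f"source {self.label!r} has neither a trajectory nor paths"
            )
        traj.label = self.label
        return traj


@dataclass
class ComparisonPlan:
    reference: TrajectorySource
    comparisons: list[TrajectorySource]
    selection: str = "backbone"
    regions: RegionSet = field(default_factory=lambda: RegionSet({}))
    binning: BinningSpec = field(default_factory=BinningSpec)
    max_window: int = 50
    align_max_iter: int = 10
    align_tol: float = 1e-3
    joint_normalization: bool = True
    out_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = [self.reference.label] + [c.label for c in self.comparisons]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"labels must be unique, got {labels}")
        if not self.comparisons:
            raise ConfigurationError("plan needs at least one comparison")

    def config_hash(self) -> str:
        payload = repr(
            (
                self.reference.label,
                [c.label for c in self.comparisons],
                self.selection,
                self.regions.regions,
                (self.binning.bin_width, self.binning.pseudocount, self.binning.units),
                self.max_window,
                self.align_max_iter,
                self.align_tol,
                self.joint_normalization,
                self.seed,
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ComparisonOutcome:
    """Everything computed for one (reference vs X) comparison."""

    label: str
    profile: DivergenceProfile
    window_map: WindowedDivergenceMap
    rmsd_backbone: RmsdSeries
    rmsd_regions: dict[str, RmsdSeries]
    alignment: tuple[AlignmentResult, AlignmentResult]
    degenerate: bool


@dataclass
class RegionReport:
    """Per (comparison, region) divergence/RMSD aggregates with ranks."""

    table: pd.DataFrame  # comparison, region, mean_kld, max_kld, mean_rmsd_A, rank

    def rank_of(self, comparison: str, region: str) -> int:
        row = self.table[
            (self.table.comparison == comparison) & (self.table.region == region)
        ]
        return int(row["rank"].iloc[0])


@dataclass
class ComparisonResult:
    plan: ComparisonPlan
    outcomes: list[ComparisonOutcome]
    report: RegionReport
    normalization: float | None
    written_files: list[Path] = field(default_factory=list)


def _region_rows(
    plan: ComparisonPlan, outcome: ComparisonOutcome
) -> list[dict]:
    rows = []
    for name in plan.regions.names():
        resids = plan.regions.residues(name)
        mask = np.isin(outcome.profile.residue_indices, resids)
        if not mask.any():
            raise ConfigurationError(
                f"region {name!r} selects no profiled residues"
            )
        vals = outcome.profile.values[mask]
        rmsd = outcome.rmsd_regions[name]
        rows.append(
            {
                "comparison": outcome.label,
                "region": name,
                "mean_kld": float(vals.mean()),
                "max_kld": float(vals.max()),
                "mean_rmsd_A": float(rmsd.values.mean()),
            }
        )
    # rank regions within this comparison by mean divergence, 1 = largest
    order = np.argsort([-r["mean_kld"] for r in rows], kind="stable")
    for rank, i in enumerate(order, start=1):
        rows[i]["rank"] = rank
    return rows


def _write_tsv(
    path: Path, meta: dict[str, object], header: list[str], rows
) -> None:
    with path.open("w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{v:.10g}" if isinstance(v, float) else str(v) for v in row
                )
                + "\n"
            )


def run_comparison(plan: ComparisonPlan) -> ComparisonResult:
    """Execute the full comparison workflow; see the module docstring.

    Any stage error aborts with the stage and label in the message and
    removes partially written outputs.
    """
    written: list[Path] = []
    out_dir = Path(plan.out_dir) if plan.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(plan, out_dir, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run(
    plan: ComparisonPlan, out_dir: Path | None, written: list[Path]
) -> ComparisonResult:
    meta_base = {
        "config_hash": plan.config_hash(),
        "reference": plan.reference.label,
        "selection": plan.selection,
        "seed": plan.seed,
    }

    def stage(name: str, label: str):
        logger.info("stage %s [%s]", name, label)

    ref = plan.reference.load()
    sel_ref = resolve_selection(ref, plan.selection)

    outcomes: list[ComparisonOutcome] = []
    raw_maps: list[WindowedDivergenceMap] = []
    for source in plan.comparisons:
        label = source.label
        try:
            traj = source.load()
            stage("align", label)
            sel = resolve_selection(traj, plan.selection)
            resA, resB = iterative_align(
                ref, traj, ref, sel_ref,
                max_iter=plan.align_max_iter, tol=plan.align_tol,
            )
            logger.info(
                "alignment [%s]: %d iterations, converged=%s",
                label, resA.n_iterations, resA.converged,
            )
            alignedRef, aligned = resA.trajectory, resB.trajectory

            stage("profile", label)
            profile = divergence_profile(alignedRef, aligned, sel_ref, plan.binning)
            stage("window", label)
            wmap = windowed_divergence(
                alignedRef, aligned, sel_ref, plan.binning, plan.max_window
            )
            stage("rmsd", label)
            ref0 = alignedRef.frame(0)
            rmsd_bb = rmsd_series(aligned, ref0, sel)
            rmsd_regions = {
                name: rmsd_series(
                    aligned, ref0,
                    resolve_selection(aligned, plan.regions.selection_spec(name)),
                )
                for name in plan.regions.names()
            }
            degenerate = float(profile.values.max()) < DEGENERATE_KLD
            if degenerate:
                logger.warning(
                    "comparison [%s] is degenerate (max KLD < %g)",
                    label, DEGENERATE_KLD,
                )
            outcomes.append(
                ComparisonOutcome(
                    label, profile, wmap, rmsd_bb, rmsd_regions,
                    (resA, resB), degenerate,
                )
            )
            raw_maps.append(wmap)
        except Exception as exc:
            exc.args = (f"[comparison {label!r}] {exc}",)
            raise

    normalization: float | None = None
    if plan.joint_normalization:
        normed = normalize_maps(raw_maps)
        normalization = normed[0].normalization
        for outcome, nm in zip(outcomes, normed):
            outcome.window_map = nm
    else:
        for outcome in outcomes:
            one = normalize_maps([outcome.window_map])[0]
            outcome.window_map = one

    rows: list[dict] = []
    for outcome in outcomes:
        rows.extend(_region_rows(plan, outcome))
    table = pd.DataFrame(rows)
    report = RegionReport(table)

    if out_dir is not None:
        for outcome in outcomes:
            meta = dict(meta_base, comparison=outcome.label)
            p = out_dir / f"profile_{outcome.label}.tsv"
            _write_tsv(
                p, meta, ["residue", "kld_nats"],
                (
                    (int(r), float(v))
                    for r, v in zip(
                        outcome.profile.residue_indices, outcome.profile.values
                    )
                ),
            )
            written.append(p)
            wm = outcome.window_map
            p = out_dir / f"window_{outcome.label}.tsv"
            wmeta = dict(meta, normalization=wm.normalization, max_window=wm.max_window)
            _write_tsv(
                p, wmeta, ["window_right_edge", "residue", "value"],
                (
                    (int(wm.window_stops[wi]), int(res), float(wm.values[wi, rj]))
                    for wi in range(wm.n_windows)
                    for rj, res in enumerate(wm.residue_indices)
                ),
            )
            written.append(p)
            p = out_dir / f"rmsd_backbone_{outcome.label}.tsv"
            _write_tsv(
                p, meta, ["frame", "rmsd_A"],
                ((f, float(v)) for f, v in enumerate(outcome.rmsd_backbone.values)),
            )
            written.append(p)
            for name, series in outcome.rmsd_regions.items():
                p = out_dir / f"rmsd_{name}_{outcome.label}.tsv"
                _write_tsv(
                    p, dict(meta, region=name), ["frame", "rmsd_A"],
                    ((f, float(v)) for f, v in enumerate(series.values)),
                )
                written.append(p)
        p = out_dir / "region_report.tsv"
        _write_tsv(
            p, dict(meta_base, normalization=normalization),
            ["comparison", "region", "mean_kld", "max_kld", "mean_rmsd_A", "rank"],
            (
                (
                    r["comparison"], r["region"], float(r["mean_kld"]),
                    float(r["max_kld"]), float(r["mean_rmsd_A"]), int(r["rank"]),
                )
                for r in rows
            ),
        )
        written.append(p)

    return ComparisonResult(plan, outcomes, report, normalization, written)
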