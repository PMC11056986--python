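"""Per-residue symmetrized Kullback-Leibler divergence between trajectories.

For each residue, the positions of its backbone bead over each aligned
trajectory are discretized into a 3D histogram on a common grid; the
directed KLD between the two normalized histograms,

    KLD(P, Q) = sum_k q_k ln(q_k / p_k),

is symmetrized as the arithmetic mean of both directions. A moving-window
variant resolves the divergence in time: windows grow from the start of
the trajectories up to a maximum size ``W``, slide, and shrink again at
the end, so window ``w`` covers snapshots max(1, w-W+1) .. min(w, N).

Discretization: per residue, an axis-aligned joint bounding box over both
trajectories' positions for that residue, padded by one bin on every side;
an additive pseudocount per bin keeps every divergence finite. The
pseudocount also sets the floor/ceiling behaviour of the estimator: the
profile of two identical distributions tends to 0 as the snapshot count
grows at fixed pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    ConfigurationError,
    EmptyWindowError,
    GeometryError,
    ShapeError,
)
from .model import Selection, Trajectory

logger = logging.getLogger(__name__)

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class BinningSpec:
    """Histogram discretization parameters.

    bin_width : nm, edge length of the cubic bins (default 0.1 nm, one
    Martini bead diameter scale).
    pseudocount : additive count per bin before normalization (> 0).
    units : "nats" (natural log) or "bits".
    """

    bin_width: float = 0.1
    pseudocount: float = 0.5
    units: str = "nats"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be > 0")
        if self.units not in ("nats", "bits"):
            raise ConfigurationError("units must be 'nats' or 'bits'")

    @property
    def log_scale(self) -> float:
        return 1.0 if self.units == "nats" else 1.0 / _LN2


@dataclass(frozen=True)
class BinGeometry:
    """Origin, bin width and per-axis bin counts of a residue's grid."""

    origin: tuple[float, float, float]
    bin_width: float
    shape: tuple[int, int, int]

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "BinGeometry", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.bin_width - other.bin_width) <= atol
            and all(
                abs(a - b) <= atol for a, b in zip(self.origin, other.origin)
            )
        )


@dataclass
class ResidueDistribution:
    """Discretized positional distribution of one residue over a frame set."""

    residue_index: int
    counts: np.ndarray  # flattened over the 3D grid, sums to n
    n: int
    geometry: BinGeometry
    pseudocount: float

    @property
    def probabilities(self) -> np.ndarray:
        """Pseudocount-smoothed probabilities (sum to 1)."""
        k = self.geometry.n_bins
        return (self.counts + self.pseudocount) / (self.n + k * self.pseudocount)


@dataclass
class DivergenceProfile:
    """Symmetrized KLD per residue between two trajectories."""

    residue_indices: np.ndarray  # 1-based
    values: np.ndarray  # >= 0, in `units`
    labels: tuple[str, str]
    spec: BinningSpec

    def top_residues(self, k: int) -> np.ndarray:
        order = np.argsort(self.values)[::-1]
        return self.residue_indices[order[:k]]


@dataclass
class WindowedDivergenceMap:
    """Window x residue matrix of symmetrized KLD.

    Window bounds are 1-based inclusive snapshot indices; the reported
    window axis is the right-edge snapshot of each window. ``normalization``
    holds the global constant after :func:`normalize_maps` (the raw global
    maximum that was mapped to 1.0), else None.
    """

    values: np.ndarray  # (n_windows, n_residues)
    window_starts: np.ndarray
    window_stops: np.ndarray
    residue_indices: np.ndarray
    max_window: int
    labels: tuple[str, str]
    spec: BinningSpec
    normalization: float | None = None

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


# -- histogram machinery -----------------------------------------------------


def joint_geometry(
    posA: np.ndarray, posB: np.ndarray, bin_width: float
) -> BinGeometry:
    """Joint axis-aligned bounding box over both clouds, padded by one bin.

    The origin sits 1.5 bins below the observed minimum so the extreme
    points are strictly interior to their bins (no FP edge ties); each
    side keeps at least one empty padding bin.
    """
    lo = np.minimum(posA.min(axis=0), posB.min(axis=0))
    hi = np.maximum(posA.max(axis=0), posB.max(axis=0))
    origin = lo - 1.5 * bin_width
    shape = np.floor((hi - origin) / bin_width).astype(int) + 2
    return BinGeometry(tuple(origin), float(bin_width), tuple(int(s) for s in shape))


def _flat_bin_indices(pos: np.ndarray, geom: BinGeometry) -> np.ndarray:
    idx = np.floor((pos - np.asarray(geom.origin)) / geom.bin_width).astype(int)
    idx = np.clip(idx, 0, np.asarray(geom.shape) - 1)  # guard FP edge cases
    return np.ravel_multi_index(idx.T, geom.shape)


def _backbone_bead_of(traj: Trajectory, residue: int) -> int:
    candidates = [
        i
        for i, b in enumerate(traj.beads)
        if b.residue_index == residue and b.bead_name == "BB"
    ]
    if not candidates:
        candidates = [
            i for i, b in enumerate(traj.beads) if b.residue_index == residue
        ]
    if len(candidates) != 1:
        raise ShapeError(
            f"residue {residue} resolves to {len(candidates)} beads; "
            "expected a unique backbone bead"
        )
    return candidates[0]


def build_distribution(
    traj: Trajectory,
    residue: int,
    frames: slice | None,
    spec: BinningSpec,
    joint_box: BinGeometry,
) -> ResidueDistribution:
    """Histogram one residue's backbone-bead positions over a frame range.

    ``joint_box`` must be the shared geometry computed from *both*
    trajectories being compared (see :func:`joint_geometry`).
    """
    bead = _backbone_bead_of(traj, residue)
    pos = traj.coords[frames if frames is not None else slice(None), bead, :]
    if pos.shape[0] == 0:
        raise EmptyWindowError(
            f"frame range selects no frames for residue {residue}"
        )
    flat = _flat_bin_indices(pos, joint_box)
    counts = np.bincount(flat, minlength=joint_box.n_bins).astype(float)
    return ResidueDistribution(
        residue_index=residue,
        counts=counts,
        n=pos.shape[0],
        geometry=joint_box,
        pseudocount=spec.pseudocount,
    )


# -- divergences -------------------------------------------------------------


def _check_geometry(P: ResidueDistribution, Q: ResidueDistribution) -> None:
    if not P.geometry.matches(Q.geometry):
        raise GeometryError(
            f"bin geometries differ: {P.geometry} vs {Q.geometry}"
        )


def kld(P: ResidueDistribution, Q: ResidueDistribution, units: str = "nats") -> float:
    """Directed divergence of Q from P: sum_k q_k ln(q_k / p_k)."""
    _check_geometry(P, Q)
    p = P.probabilities
    q = Q.probabilities
    value = float(np.sum(q * np.log(q / p)))
    return value / _LN2 if units == "bits" else value


def symmetrized_kld(
    P: ResidueDistribution, Q: ResidueDistribution, units: str = "nats"
) -> float:
    """Arithmetic mean of the two directed divergences; symmetric, >= 0."""
    return 0.5 * (kld(P, Q, units) + kld(Q, P, units))


def _sym_kld_from_counts(
    cA: np.ndarray, cB: np.ndarray, nA: np.ndarray, nB: np.ndarray,
    k: int, pseudocount: float,
) -> np.ndarray:
    """Vectorized symmetrized KLD for stacks of count vectors (nats).

    cA, cB: (..., k) counts; nA, nB: (...) totals.
    """
    p = (cA + pseudocount) / (np.asarray(nA)[..., None] + k * pseudocount)
    q = (cB + pseudocount) / (np.asarray(nB)[..., None] + k * pseudocount)
    log_ratio = np.log(q) - np.log(p)
    return 0.5 * np.sum((q - p) * log_ratio, axis=-1)


def divergence_profile(
    trajA: Trajectory,
    trajB: Trajectory,
    sel: Selection,
    spec: BinningSpec = BinningSpec(),
) -> DivergenceProfile:
    """Symmetrized KLD per selected residue over the full frame sets.

    Both trajectories must already be aligned to the common reference.
    """
    idx = sel.as_array()
    residsA = trajA.bead_residue_indices()[idx]
    if trajB.n_beads != trajA.n_beads:
        raise ShapeError(
            f"trajectories have {trajA.n_beads} vs {trajB.n_beads} beads"
        )
    values = np.empty(len(idx))
    for j, bead in enumerate(idx):
        posA = trajA.coords[:, bead, :]
        posB = trajB.coords[:, bead, :]
        geom = joint_geometry(posA, posB, spec.bin_width)
        cA = np.bincount(_flat_bin_indices(posA, geom), minlength=geom.n_bins)
        cB = np.bincount(_flat_bin_indices(posB, geom), minlength=geom.n_bins)
        values[j] = _sym_kld_from_counts(
            cA.astype(float), cB.astype(float),
            posA.shape[0], posB.shape[0],
            geom.n_bins, spec.pseudocount,
        )
    return DivergenceProfile(
        residue_indices=residsA,
        values=values * spec.log_scale,
        labels=(trajA.label, trajB.label),
        spec=spec,
    )


def window_bounds(n_frames: int, max_window: int) -> tuple[np.ndarray, np.ndarray]:
    """1-based inclusive (start, stop) snapshot bounds of every window.

    Window w (w = 1 .. N+W-1) covers snapshots max(1, w-W+1) .. min(w, N):
    growing from a single snapshot, sliding at full width W, then shrinking
    from the left once the trajectory end is reached.
    """
    if max_window < 2:
        raise ConfigurationError(f"max_window must be >= 2, got {max_window}")
    w = np.arange(1, n_frames + max_window)
    starts = np.maximum(1, w - max_window + 1)
    stops = np.minimum(w, n_frames)
    return starts, stops


def windowed_divergence(
    trajA: Trajectory,
    trajB: Trajectory,
    sel: Selection,
    spec: BinningSpec = BinningSpec(),
    max_window: int = 50,
) -> WindowedDivergenceMap:
    """Moving-window symmetrized KLD per residue.

    Frame counts are truncated to the shorter trajectory (with a warning)
    so snapshot/window indices stay aligned. The bin geometry per residue
    is fixed from the full (truncated) trajectories, so windows share grids.
    """
    n = min(trajA.n_frames, trajB.n_frames)
    if trajA.n_frames != trajB.n_frames:
        logger.warning(
            "frame counts differ (%d vs %d); truncating to %d",
            trajA.n_frames, trajB.n_frames, n,
        )
    starts, stops = window_bounds(n, max_window)
    n_windows = len(starts)
    lengths = stops - starts + 1
    idx = sel.as_array()
    resids = trajA.bead_residue_indices()[idx]
    values = np.empty((n_windows, len(idx)))

    for j, bead in enumerate(idx):
        posA = trajA.coords[:n, bead, :]
        posB = trajB.coords[:n, bead, :]
        geom = joint_geometry(posA, posB, spec.bin_width)
        k = geom.n_bins
        flatA = _flat_bin_indices(posA, geom)
        flatB = _flat_bin_indices(posB, geom)
        # cumulative counts: cum[t, b] = count of bin b among snapshots 1..t
        cumA = np.zeros((n + 1, k), dtype=np.int32)
        cumB = np.zeros((n + 1, k), dtype=np.int32)
        cumA[np.arange(1, n + 1), flatA] = 1
        cumB[np.arange(1, n + 1), flatB] = 1
        np.cumsum(cumA, axis=0, out=cumA)
        np.cumsum(cumB, axis=0, out=cumB)
        # chunk windows to bound the (windows x bins) temporary
        chunk = max(1, int(4_000_000 // max(k, 1)))
        for lo in range(0, n_windows, chunk):
            hi = min(lo + chunk, n_windows)
            cA = (cumA[stops[lo:hi]] - cumA[starts[lo:hi] - 1]).astype(float)
            cB = (cumB[stops[lo:hi]] - cumB[starts[lo:hi] - 1]).astype(float)
            values[lo:hi, j] = _sym_kld_from_counts(
                cA, cB, lengths[lo:hi], lengths[lo:hi], k, spec.pseudocount
            )
    return WindowedDivergenceMap(
        values=values * spec.log_scale,
        window_starts=starts,
        window_stops=stops,
        residue_indices=resids,
        max_window=max_window,
        labels=(trajA.label, trajB.label),
        spec=spec,
    )


def normalize_maps(
    maps: list[WindowedDivergenceMap],
) -> list[WindowedDivergenceMap]:
    """Scale all maps by the single global maximum across all of them.

    After scaling the largest entry over all maps is exactly 1.0 ("1.0
    corresponds to the largest overall difference; 0.0 no difference").
    All-zero input is returned unchanged with a warning.
    """
    if not maps:
        raise ConfigurationError("normalize_maps needs at least one map")
    gmax = max(float(m.values.max()) for m in maps)
    if gmax <= 0:
        logger.warning("all windowed maps are zero; normalization skipped")
        return maps
    return [
        replace(m, values=m.values / gmax, normalization=gmax) for m in maps
    ]
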