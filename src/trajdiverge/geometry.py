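"""Geometric observables: RMSD series, COM distances, coarse-grained SASA.

User-facing distances and RMSD are reported in Angstrom (matching the
conventions of structural-biology figures); everything internal is nm.

SASA follows Shrake-Rupley with a deterministic generalized-spiral point
set on every inflated bead sphere; the default probe of 0.26 nm is the
radius of a regular Martini coarse-grained bead, so probe and bead radii
live on the same scale as the bead model itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, EmptySelectionError
from .model import Frame, Selection, Trajectory

_A_PER_NM = 10.0

#: Radius (nm) of a regular Martini bead; default bead and probe radius.
MARTINI_BEAD_RADIUS = 0.26


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Angstrom) of a selection against a reference frame."""

    values: np.ndarray
    selection_spec: str
    reference_label: str = ""

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class DistanceSeries:
    """Per-frame COM-COM distance (Angstrom) between two bead groups."""

    values: np.ndarray
    label_a: str = ""
    label_b: str = ""

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())

    def histogram(self, bin_width: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """Counts and bin edges (Angstrom) of the distance distribution."""
        lo = np.floor(self.min / bin_width) * bin_width
        hi = np.ceil(self.max / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        counts, edges = np.histogram(self.values, bins=edges)
        return counts, edges

    def modes(self, bin_width: float = 0.5, min_separation: float = 1.0) -> np.ndarray:
        """Centers (Angstrom) of local maxima of the histogram, highest first."""
        counts, edges = self.histogram(bin_width)
        centers = 0.5 * (edges[:-1] + edges[1:])
        picked: list[float] = []
        for i in np.argsort(counts)[::-1]:
            if counts[i] == 0:
                break
            c = float(centers[i])
            if all(abs(c - p) >= min_separation for p in picked):
                picked.append(c)
        return np.array(picked)


@dataclass
class SasaResult:
    """Total solvent-accessible surface area (nm^2) of a target group."""

    total: float
    per_bead: np.ndarray  # nm^2 per target bead
    probe_radius: float
    n_points: int


def rmsd_series(
    traj: Trajectory, ref_frame: Frame, sel: Selection
) -> RmsdSeries:
    """RMSD_t = sqrt(mean over selection of |x_t - x_ref|^2), in Angstrom.

    No superposition is performed here: the trajectory is expected to be
    aligned already on whatever global selection the protocol prescribes
    (region RMSD is computed without re-alignment on the region).
    """
    idx = sel.as_array()
    if len(idx) == 0:
        raise EmptySelectionError("RMSD selection is empty")
    diff = traj.coords[:, idx, :] - ref_frame.coordinates[idx]
    rmsd_nm = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
    return RmsdSeries(rmsd_nm * _A_PER_NM, sel.spec)


def com(
    frame: Frame, group: Selection, masses: np.ndarray | None = None
) -> np.ndarray:
    """Mass-weighted mean position (nm) of a bead group; uniform by default."""
    idx = group.as_array()
    if len(idx) == 0:
        raise EmptySelectionError("COM group is empty")
    pos = frame.coordinates[idx]
    if masses is None:
        return pos.mean(axis=0)
    m = np.asarray(masses, dtype=float)
    if m.shape == (frame.coordinates.shape[0],):
        m = m[idx]
    if m.shape != (len(idx),):
        raise ConfigurationError(
            f"masses must match the group ({len(idx)} beads), got {m.shape}"
        )
    total = m.sum()
    if total <= 0:
        raise ConfigurationError("total mass of COM group must be positive")
    return (m[:, None] * pos).sum(axis=0) / total


def distance_series(
    traj: Trajectory,
    groupA: Selection,
    groupB: Selection,
    masses: np.ndarray | None = None,
) -> DistanceSeries:
    """Per-frame Euclidean COM-COM distance (Angstrom) between two groups."""
    idxA = groupA.as_array()
    idxB = groupB.as_array()
    if len(idxA) == 0 or len(idxB) == 0:
        raise EmptySelectionError("distance groups must be non-empty")

    def _group_com(idx: np.ndarray) -> np.ndarray:
        pos = traj.coords[:, idx, :]
        if masses is None:
            return pos.mean(axis=1)
        m = np.asarray(masses, dtype=float)
        if m.shape == (traj.n_beads,):
            m = m[idx]
        total = m.sum()
        if total <= 0:
            raise ConfigurationError("total mass must be positive")
        return np.einsum("j,fjk->fk", m, pos) / total

    comA = _group_com(idxA)
    comB = _group_com(idxB)
    d_nm = np.linalg.norm(comA - comB, axis=1)
    return DistanceSeries(d_nm * _A_PER_NM, groupA.spec, groupB.spec)


# -- SASA --------------------------------------------------------------------


def sphere_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden-angle) unit sphere points."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def resolve_radii(
    traj: Trajectory,
    table: dict[str, float] | None = None,
    default: float | None = MARTINI_BEAD_RADIUS,
) -> np.ndarray:
    """Per-bead radii (nm): name table overrides bead radii, then default.

    Raises a configuration error naming the first bead whose radius
    cannot be resolved.
    """
    radii = np.empty(traj.n_beads)
    for i, b in enumerate(traj.beads):
        if table is not None and b.bead_name in table:
            radii[i] = table[b.bead_name]
        elif b.radius is not None:
            radii[i] = b.radius
        elif default is not None:
            radii[i] = default
        else:
            raise ConfigurationError(
                f"no radius for bead {b.bead_name!r} (residue {b.residue_index})"
            )
    return radii


def sasa(
    frame: Frame,
    radii: np.ndarray,
    target: Selection,
    context: Selection | None = None,
    probe: float = MARTINI_BEAD_RADIUS,
    n_points: int = 960,
) -> SasaResult:
    """Shrake-Rupley SASA (nm^2) of the target beads in one frame.

    For each target bead, a deterministic point set is placed on the
    sphere of radius r_i + probe; the accessible fraction (points not
    buried inside any other inflated bead) times 4 pi (r_i + probe)^2 is
    the bead's contribution. Context beads occlude but contribute no area.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.shape != (frame.coordinates.shape[0],):
        raise ConfigurationError(
            f"radii must have one entry per bead; got {radii.shape} for "
            f"{frame.coordinates.shape[0]} beads"
        )
    t_idx = target.as_array()
    if len(t_idx) == 0:
        raise EmptySelectionError("SASA target is empty")
    c_idx = context.as_array() if context is not None else np.array([], dtype=int)
    occluder_pool = np.unique(np.concatenate([t_idx, c_idx]))
    unit = sphere_points(n_points)

    per_bead = np.empty(len(t_idx))
    pos = frame.coordinates
    for k, i in enumerate(t_idx):
        ri = radii[i] + probe
        others = occluder_pool[occluder_pool != i]
        if len(others) > 0:
            d_centers = np.linalg.norm(pos[others] - pos[i], axis=1)
            near = others[d_centers < ri + radii[others] + probe]
        else:
            near = others
        area = 4.0 * np.pi * ri * ri
        if len(near) == 0:
            per_bead[k] = area
            continue
        pts = pos[i] + ri * unit  # (n_points, 3)
        d2 = np.sum(
            (pts[:, None, :] - pos[near][None, :, :]) ** 2, axis=2
        )
        buried = (d2 < (radii[near] + probe) ** 2).any(axis=1)
        per_bead[k] = area * (1.0 - buried.mean())
    return SasaResult(
        total=float(per_bead.sum()),
        per_bead=per_bead,
        probe_radius=probe,
        n_points=n_points,
    )


def sasa_series(
    traj: Trajectory,
    target: Selection,
    context: Selection | None = None,
    radii_table: dict[str, float] | None = None,
    probe: float = MARTINI_BEAD_RADIUS,
    n_points: int = 960,
) -> np.ndarray:
    """Per-frame total SASA (nm^2) of the target group over a trajectory."""
    radii = resolve_radii(traj, radii_table)
    return np.array(
        [
            sasa(traj.frame(f), radii, target, context, probe, n_points).total
            for f in range(traj.n_frames)
        ]
    )
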