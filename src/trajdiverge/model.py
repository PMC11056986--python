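"""Trajectory data model for bead-per-residue (coarse-grained) chains.

Units: all internal coordinates are nanometres (the Martini convention);
file readers convert at the boundary (PDB is stored in Angstrom on disk).
Residue numbering is 1-based everywhere user-facing; bead indices into
the coordinate array are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import ShapeError


@dataclass(frozen=True)
class Bead:
    """One coarse-grained interaction site.

    Parameters
    ----------
    bead_name
        Site name, e.g. ``"BB"`` (backbone), ``"SC2"``, ``"FLA1"``.
    residue_index
        1-based residue number the bead belongs to.
    residue_name
        Three-letter residue name (``"TRP"``, ``"FAD"``, ...).
    radius
        Optional van der Waals-type radius in nm, used by SASA.
    """

    bead_name: str
    residue_index: int
    residue_name: str = "UNK"
    radius: float | None = None

    def __post_init__(self) -> None:
        if not self.bead_name:
            raise ValueError("bead_name must be non-empty")
        if self.residue_index < 1:
            raise ValueError(
                f"residue_index must be >= 1, got {self.residue_index}"
            )


@dataclass
class Frame:
    """A single snapshot: one 3D point per bead, in nm."""

    coordinates: np.ndarray  # (n_beads, 3)
    time: float | None = None  # simulation time in microseconds

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ShapeError(
                f"frame coordinates must be (n_beads, 3), got "
                f"{self.coordinates.shape}"
            )
        if not np.isfinite(self.coordinates).all():
            raise ValueError("frame contains non-finite coordinates")


class Trajectory:
    """An ordered list of beads plus a (n_frames, n_beads, 3) coordinate block.

    The coordinate block is the primary storage; :class:`Frame` objects are
    views constructed on demand.
    """

    def __init__(
        self,
        beads: Sequence[Bead],
        coords: np.ndarray,
        label: str = "",
        times: np.ndarray | None = None,
    ) -> None:
        self.beads: list[Bead] = list(beads)
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None, :, :]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ShapeError(
                f"coords must be (n_frames, n_beads, 3), got {coords.shape}"
            )
        if coords.shape[0] < 1:
            raise ShapeError("a trajectory needs at least one frame")
        if coords.shape[1] != len(self.beads):
            raise ShapeError(
                f"coordinate block has {coords.shape[1]} beads but "
                f"{len(self.beads)} bead records were given"
            )
        if not np.isfinite(coords).all():
            raise ValueError("trajectory contains non-finite coordinates")
        self.coords = coords
        self.label = label
        if times is not None:
            times = np.asarray(times, dtype=float)
            if times.shape != (coords.shape[0],):
                raise ShapeError("times must have one entry per frame")
        self.times = times

    # -- basic introspection -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_indices(self) -> np.ndarray:
        """Sorted unique 1-based residue numbers present in the chain."""
        return np.unique([b.residue_index for b in self.beads])

    @property
    def n_residues(self) -> int:
        return len(self.residue_indices)

    def frame(self, i: int) -> Frame:
        t = None if self.times is None else float(self.times[i])
        return Frame(self.coords[i], time=t)

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    # -- derived views -------------------------------------------------------

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Trajectory":
        """New trajectory sharing this one's beads with replacement coordinates."""
        return Trajectory(
            self.beads,
            coords,
            label=self.label if label is None else label,
            times=self.times if coords.shape[0] == self.n_frames else None,
        )

    def bead_names(self) -> np.ndarray:
        return np.array([b.bead_name for b in self.beads])

    def bead_residue_indices(self) -> np.ndarray:
        return np.array([b.residue_index for b in self.beads], dtype=int)

    def bead_residue_names(self) -> np.ndarray:
        return np.array([b.residue_name for b in self.beads])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = f" label={self.label!r}" if self.label else ""
        return (
            f"<Trajectory {self.n_frames} frames x {self.n_beads} beads"
            f" ({self.n_residues} residues){lab}>"
        )


@dataclass(frozen=True)
class Selection:
    """A resolved bead selection: strictly increasing 0-based indices."""

    indices: tuple[int, ...]
    spec: str = ""

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


@dataclass
class RegionSet:
    """Named residue regions (1-based inclusive ranges) driving reporting.

    Default regions follow the cryptochrome-4 taxonomy: the EEE linear-motif
    region (residues 440-460), the surface patch opposite the tryptophan
    tetrad (OPP, 80-90) and the C-terminal tail (CT, residue 480 to the end).
    The phosphate-binding loop (PBL) has no default span and must be supplied
    by the user.
    """

    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ranges in self.regions.items():
            if not ranges:
                raise ValueError(f"region {name!r} has no ranges")
            for lo, hi in ranges:
                if lo < 1 or hi < lo:
                    raise ValueError(
                        f"region {name!r} has invalid range {lo}-{hi}"
                    )

    @classmethod
    def default(
        cls, last_residue: int, pbl: tuple[int, int] | None = None
    ) -> "RegionSet":
        regions: dict[str, list[tuple[int, int]]] = {}
        if pbl is not None:
            regions["PBL"] = [tuple(pbl)]
        regions["OPP"] = [(80, 90)]
        regions["EEE"] = [(440, 460)]
        regions["CT"] = [(480, last_residue)]
        return cls(regions)

    def selection_spec(self, name: str) -> str:
        """Backbone selection text covering the named region."""
        ranges = self.regions[name]
        parts = " ".join(
            f"{lo}" if lo == hi else f"{lo}-{hi}" for lo, hi in ranges
        )
        return f"backbone and resid {parts}"

    def residues(self, name: str) -> np.ndarray:
        """All 1-based residue numbers in the named region."""
        out: list[int] = []
        for lo, hi in self.regions[name]:
            out.extend(range(lo, hi + 1))
        return np.unique(out)

    def names(self) -> list[str]:
        return list(self.regions)
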