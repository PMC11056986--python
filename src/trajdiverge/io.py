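"""Readers and writers for structure/trajectory formats.

GRO, PDB (single and multi-model) and the XTC/DCD binary classes are
handled through MDAnalysis; the plain-text TSV fixture format defined
here is the package's own and needs no binary codec.

Unit convention: everything in memory is nm. MDAnalysis reports
positions in Angstrom, so values are divided by 10 on the way in and
multiplied by 10 on the way out.

TSV fixture format (whitespace separated, ``#`` metadata header)::

    # trajdiverge-tsv v1
    # label=<label>
    # beads=<name>:<resid>:<resname>[:<radius_nm>] ...
    # columns: frame bead x y z   (indices 0-based; coordinates in nm)
    0 0 1.234567 0.000000 -0.500000
    ...
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ParseError, ShapeError
from .model import Bead, Trajectory

_A_PER_NM = 10.0

STRUCTURE_FORMATS = ("gro", "pdb")
TRAJECTORY_FORMATS = ("xtc", "dcd", "pdb", "tsv")


def _infer_format(path: str | Path, allowed: tuple[str, ...]) -> str:
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in allowed:
        return suffix
    raise ConfigurationError(
        f"cannot infer format of {path!r}; expected one of {allowed}"
    )


def _mda_universe(path: str | Path, fmt: str):
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path), format=fmt)
    except Exception as exc:  # MDAnalysis raises a zoo of types
        raise ParseError(f"failed to parse {path!r} as {fmt}: {exc}") from exc


def _beads_from_universe(u) -> list[Bead]:
    names = getattr(u.atoms, "names", None)
    resids = u.atoms.resids
    resnames = getattr(u.atoms, "resnames", None)
    beads = []
    for i in range(len(u.atoms)):
        beads.append(
            Bead(
                bead_name=str(names[i]) if names is not None else f"X{i}",
                residue_index=int(resids[i]),
                residue_name=str(resnames[i]) if resnames is not None else "UNK",
            )
        )
    return beads


def read_structure(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a GRO or PDB file into a single-frame trajectory (nm).

    Bead order is preserved from the file; PDB coordinates (Angstrom on
    disk) are converted to nm.
    """
    fmt = (format or _infer_format(path, STRUCTURE_FORMATS)).lower()
    if fmt not in STRUCTURE_FORMATS:
        raise ConfigurationError(
            f"unknown structure format {fmt!r}; expected one of {STRUCTURE_FORMATS}"
        )
    u = _mda_universe(path, fmt)
    coords = np.asarray(u.atoms.positions, dtype=float) / _A_PER_NM
    return Trajectory(_beads_from_universe(u), coords[None], label=Path(path).stem)


def read_trajectory(
    structure: Trajectory, path: str | Path, format: str | None = None
) -> Trajectory:
    """Read frames from a trajectory file onto a structure's beads.

    The returned trajectory carries the structure's bead metadata and
    exactly the frames stored in the file, in file order.

    Raises
    ------
    ShapeError
        If the file's bead count differs from the structure's.
    """
    fmt = (format or _infer_format(path, TRAJECTORY_FORMATS)).lower()
    if fmt == "tsv":
        fixture = read_tsv_fixture(path)
        if fixture.n_beads != structure.n_beads:
            raise ShapeError(
                f"fixture has {fixture.n_beads} beads but structure has "
                f"{structure.n_beads}"
            )
        return Trajectory(structure.beads, fixture.coords, label=fixture.label)
    if fmt == "pdb":
        u = _mda_universe(path, "pdb")
        n = len(u.atoms)
        if n != structure.n_beads:
            raise ShapeError(
                f"trajectory file has {n} beads but structure has "
                f"{structure.n_beads}"
            )
        frames = [u.atoms.positions / _A_PER_NM for _ in u.trajectory]
        return Trajectory(structure.beads, np.stack(frames), label=Path(path).stem)
    if fmt in ("xtc", "dcd"):
        if fmt == "xtc":
            from MDAnalysis.coordinates.XTC import XTCReader as Reader
        else:
            from MDAnalysis.coordinates.DCD import DCDReader as Reader
        try:
            reader = Reader(str(path))
        except Exception as exc:
            raise ParseError(f"failed to open {path!r} as {fmt}: {exc}") from exc
        with reader:
            if reader.n_atoms != structure.n_beads:
                raise ShapeError(
                    f"trajectory file has {reader.n_atoms} beads but structure "
                    f"has {structure.n_beads}"
                )
            frames = [np.array(ts.positions, dtype=float) / _A_PER_NM for ts in reader]
        return Trajectory(structure.beads, np.stack(frames), label=Path(path).stem)
    raise ConfigurationError(
        f"unknown trajectory format {fmt!r}; expected one of {TRAJECTORY_FORMATS}"
    )


# -- TSV fixture format ------------------------------------------------------


def write_tsv_fixture(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the plain-text fixture format (nm, 1e-6 precision)."""
    path = Path(path)
    bead_field = " ".join(
        f"{b.bead_name}:{b.residue_index}:{b.residue_name}"
        + (f":{b.radius:g}" if b.radius is not None else "")
        for b in traj.beads
    )
    with path.open("w") as fh:
        fh.write("# trajdiverge-tsv v1\n")
        fh.write(f"# label={traj.label}\n")
        fh.write(f"# beads={bead_field}\n")
        fh.write("# columns: frame bead x y z\n")
        for f in range(traj.n_frames):
            for b in range(traj.n_beads):
                x, y, z = traj.coords[f, b]
                fh.write(f"{f} {b} {x:.6f} {y:.6f} {z:.6f}\n")


def _parse_bead_token(tok: str, lineno: int) -> Bead:
    parts = tok.split(":")
    if len(parts) not in (3, 4):
        raise ParseError(f"line {lineno}: bad bead token {tok!r}")
    radius = float(parts[3]) if len(parts) == 4 else None
    return Bead(parts[0], int(parts[1]), parts[2], radius=radius)


def read_tsv_fixture(path: str | Path) -> Trajectory:
    """Read the fixture format written by :func:`write_tsv_fixture`."""
    path = Path(path)
    label = path.stem
    beads: list[Bead] | None = None
    rows: list[tuple[int, int, float, float, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("label="):
                    label = body[len("label="):]
                elif body.startswith("beads="):
                    beads = [
                        _parse_bead_token(tok, lineno)
                        for tok in body[len("beads="):].split()
                    ]
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ParseError(
                    f"line {lineno}: expected 5 fields (frame bead x y z), "
                    f"got {len(fields)}"
                )
            try:
                rows.append(
                    (int(fields[0]), int(fields[1]), float(fields[2]),
                     float(fields[3]), float(fields[4]))
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    if beads is None:
        raise ParseError(f"{path}: missing '# beads=' metadata line")
    if not rows:
        raise ParseError(f"{path}: no coordinate rows")
    n_beads = len(beads)
    n_frames = max(r[0] for r in rows) + 1
    if len(rows) != n_frames * n_beads:
        raise ParseError(
            f"{path}: expected {n_frames * n_beads} rows for {n_frames} frames "
            f"x {n_beads} beads, found {len(rows)}"
        )
    coords = np.full((n_frames, n_beads, 3), np.nan)
    for f, b, x, y, z in rows:
        if not (0 <= b < n_beads):
            raise ParseError(f"{path}: bead index {b} out of range")
        coords[f, b] = (x, y, z)
    if np.isnan(coords).any():
        raise ParseError(f"{path}: missing (frame, bead) rows")
    return Trajectory(beads, coords, label=label)


# -- writers via MDAnalysis --------------------------------------------------


def _universe_from(traj: Trajectory):
    import MDAnalysis as mda

    resids_per_bead = traj.bead_residue_indices()
    uniq, atom_resindex = np.unique(resids_per_bead, return_inverse=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=traj.n_beads,
            n_residues=len(uniq),
            atom_resindex=atom_resindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", list(traj.bead_names()))
        u.add_TopologyAttr("resids", [int(r) for r in uniq])
        resnames = []
        seen = {}
        for b in traj.beads:
            if b.residue_index not in seen:
                seen[b.residue_index] = b.residue_name
        u.add_TopologyAttr("resnames", [seen[int(r)] for r in uniq])
    return u


def write_structure(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write one frame as GRO or PDB (inferred from the suffix)."""
    fmt = _infer_format(path, STRUCTURE_FORMATS)
    u = _universe_from(traj)
    u.atoms.positions = traj.coords[frame] * _A_PER_NM
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    # silence unused-variable linters; fmt kept for symmetry with readers
    del fmt


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    """Write all frames as multi-model PDB, XTC, DCD, or the TSV fixture."""
    fmt = (format or _infer_format(path, TRAJECTORY_FORMATS)).lower()
    if fmt == "tsv":
        write_tsv_fixture(traj, path)
        return
    import MDAnalysis as mda

    u = _universe_from(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_beads, multiframe=True) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f] * _A_PER_NM
                w.write(u.atoms)
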