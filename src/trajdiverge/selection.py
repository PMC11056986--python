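"""A small selection grammar over beads.

Clauses are joined by ``and`` and each clause is one of::

    all
    backbone                 # beads named BB
    name N1 N2 ...
    resname R1 R2 ...
    resid 440-460 470 480-490

Residue numbers are 1-based inclusive. Resolution is deterministic,
idempotent, and independent of clause order (clauses intersect).
"""

from __future__ import annotations

import numpy as np

from .errors import EmptySelectionError, SelectionError
from .model import Selection, Trajectory

BACKBONE_BEAD_NAME = "BB"


def _parse_resid_tokens(tokens: list[str], clause: str) -> list[tuple[int, int]]:
    if not tokens:
        raise SelectionError(f"'resid' clause needs at least one range: {clause!r}")
    ranges: list[tuple[int, int]] = []
    for tok in tokens:
        try:
            if "-" in tok[1:]:  # allow plain integers; no negative resids
                lo_s, hi_s = tok.split("-", 1)
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(tok)
        except ValueError as exc:
            raise SelectionError(
                f"bad residue token {tok!r} in clause {clause!r}"
            ) from exc
        if lo < 1 or hi < lo:
            raise SelectionError(f"invalid residue range {tok!r}")
        ranges.append((lo, hi))
    return ranges


def _clause_mask(traj: Trajectory, clause: str) -> np.ndarray:
    tokens = clause.split()
    if not tokens:
        raise SelectionError("empty clause")
    head, rest = tokens[0].lower(), tokens[1:]
    if head == "all":
        if rest:
            raise SelectionError(f"'all' takes no arguments: {clause!r}")
        return np.ones(traj.n_beads, dtype=bool)
    if head == "backbone":
        if rest:
            raise SelectionError(f"'backbone' takes no arguments: {clause!r}")
        return traj.bead_names() == BACKBONE_BEAD_NAME
    if head == "name":
        if not rest:
            raise SelectionError(f"'name' needs at least one bead name: {clause!r}")
        return np.isin(traj.bead_names(), rest)
    if head == "resname":
        if not rest:
            raise SelectionError(f"'resname' needs at least one name: {clause!r}")
        return np.isin(traj.bead_residue_names(), rest)
    if head == "resid":
        resids = traj.bead_residue_indices()
        mask = np.zeros(traj.n_beads, dtype=bool)
        for lo, hi in _parse_resid_tokens(rest, clause):
            mask |= (resids >= lo) & (resids <= hi)
        return mask
    raise SelectionError(f"unknown selection keyword {head!r} in {clause!r}")


def resolve_selection(traj: Trajectory, spec: str) -> Selection:
    """Resolve selection text to a strictly increasing 0-based index list.

    Raises
    ------
    SelectionError
        If the text does not parse.
    EmptySelectionError
        If the selection matches no beads (never returned silently).
    """
    if not spec or not spec.strip():
        raise SelectionError("selection text is empty")
    mask = np.ones(traj.n_beads, dtype=bool)
    for clause in spec.split(" and "):
        mask &= _clause_mask(traj, clause.strip())
    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise EmptySelectionError(
            f"selection {spec!r} matches no beads in trajectory "
            f"{traj.label or '<unnamed>'}"
        )
    return Selection(tuple(int(i) for i in indices), spec=spec)
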