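"""Rigid-body superposition (Kabsch) and iterative pairwise alignment.

Divergence profiling compares per-residue positional distributions, so
both trajectories must first be expressed in a common frame. Plain
least-squares superposition weights every residue equally, letting a
genuinely mobile loop drag the fit; the iterative scheme therefore
re-weights residues by the inverse of their positional variance and
realigns until the rotations stop changing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError
from .model import Frame, Selection, Trajectory

logger = logging.getLogger(__name__)

#: Variance regularization (nm^2) in the inverse-variance weights.
VARIANCE_EPSILON = 1e-4


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation, mapping mobile onto reference."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,) nm

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation matrix is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) coordinate array."""
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


@dataclass
class AlignmentResult:
    """Outcome of :func:`iterative_align` for one trajectory."""

    trajectory: Trajectory
    weights: np.ndarray  # final per-selected-bead weights in [0, 1]
    weights_history: list[np.ndarray] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Weighted least-squares superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation + translation minimizing the weighted sum
    of squared deviations. Reflections are rejected via the usual sign
    correction on the smallest singular direction.

    Raises
    ------
    DegenerateInputError
        For fewer than 3 points or an (effectively) collinear point set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise DegenerateInputError(
            f"point sets must both be (n, 3); got {mobile.shape} vs "
            f"{reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateInputError(f"need >= 3 points, got {n}")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,) or (weights < 0).any():
        raise ValueError("weights must be a nonnegative vector, one per point")
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("weights must sum to a positive value")
    w = weights / wsum

    mob_mean = w @ mobile
    ref_mean = w @ reference
    mob_c = mobile - mob_mean
    ref_c = reference - ref_mean

    # collinearity check on the weighted mobile cloud
    s_mob = np.linalg.svd(mob_c * np.sqrt(w)[:, None], compute_uv=False)
    if s_mob[1] < 1e-10 * max(s_mob[0], 1e-30):
        raise DegenerateInputError("mobile point set is collinear/degenerate")

    H = (w[:, None] * mob_c).T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_mean - R @ mob_mean
    return RigidTransform(R, t)


def _batch_kabsch(
    mobiles: np.ndarray,  # (F, n, 3)
    reference: np.ndarray,  # (n, 3)
    weights: np.ndarray,  # (n,)
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Kabsch over a stack of frames. Returns (R (F,3,3), t (F,3))."""
    w = weights / weights.sum()
    mob_mean = np.einsum("j,fjk->fk", w, mobiles)
    ref_mean = w @ reference
    mob_c = mobiles - mob_mean[:, None, :]
    ref_c = reference - ref_mean
    H = np.einsum("j,fjk,jl->fkl", w, mob_c, ref_c)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fkl,fml->fkm", Vt.transpose(0, 2, 1), U))
    D = np.repeat(np.eye(3)[None], len(mobiles), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("fkl,fkm,fnm->fln", Vt, D, U)
    t = ref_mean - np.einsum("fkl,fl->fk", R, mob_mean)
    return R, t


def align_to_reference(
    traj: Trajectory,
    ref_frame: Frame,
    sel: Selection,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Superpose every frame on ``ref_frame`` over the selection.

    Non-selected beads are carried along by the same rigid transform.
    """
    R, t = _align_transforms(traj, ref_frame, sel, weights)
    coords = np.einsum("fkl,fjl->fjk", R, traj.coords) + t[:, None, :]
    return traj.with_coords(coords)


def _align_transforms(
    traj: Trajectory,
    ref_frame: Frame,
    sel: Selection,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    idx = sel.as_array()
    if weights is None:
        weights = np.ones(len(idx))
    if len(idx) < 3:
        raise DegenerateInputError(
            f"alignment selection has {len(idx)} beads; need >= 3"
        )
    return _batch_kabsch(traj.coords[:, idx, :], ref_frame.coordinates[idx], weights)


def _rotation_angles(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    """Geodesic angle (radians) between two stacks of rotations."""
    rel_trace = np.einsum("fkl,fkl->f", Ra, Rb)
    return np.arccos(np.clip((rel_trace - 1.0) / 2.0, -1.0, 1.0))


def iterative_align(
    trajA: Trajectory,
    trajB: Trajectory,
    ref: Trajectory,
    sel: Selection,
    max_iter: int = 10,
    tol: float = 1e-3,
    epsilon: float = VARIANCE_EPSILON,
) -> tuple[AlignmentResult, AlignmentResult]:
    """Iteratively align a trajectory pair to ``ref``'s first frame.

    Loop: (1) align both trajectories with the current weights (uniform at
    first); (2) pool the per-selected-bead positional variance over both
    aligned trajectories; (3) set w_i proportional to 1/(variance_i + epsilon),
    scaled to max 1; (4) realign. Stops when the mean change in per-frame
    rotation between successive iterations falls below ``tol`` radians, or
    after ``max_iter`` iterations (then ``converged`` is False and a warning
    is logged — non-convergence is not an error).
    """
    if trajA.n_residues != trajB.n_residues:
        raise ValueError(
            f"trajectories have {trajA.n_residues} vs {trajB.n_residues} residues"
        )
    ref_frame = ref.frame(0)
    idx = sel.as_array()
    n_sel = len(idx)
    w = np.ones(n_sel)
    history: list[np.ndarray] = []
    prev_R: tuple[np.ndarray, np.ndarray] | None = None
    converged = False
    n_iter = 0

    RA = tA = RB = tB = None
    for it in range(1, max_iter + 1):
        n_iter = it
        history.append(w.copy())
        RA, tA = _align_transforms(trajA, ref_frame, sel, w)
        RB, tB = _align_transforms(trajB, ref_frame, sel, w)
        if prev_R is not None:
            delta = 0.5 * (
                _rotation_angles(RA, prev_R[0]).mean()
                + _rotation_angles(RB, prev_R[1]).mean()
            )
            if delta < tol:
                converged = True
                break
        prev_R = (RA, RB)
        if it == max_iter:
            break
        # pooled per-bead positional variance over both aligned trajectories
        selA = np.einsum("fkl,fjl->fjk", RA, trajA.coords[:, idx, :]) + tA[:, None, :]
        selB = np.einsum("fkl,fjl->fjk", RB, trajB.coords[:, idx, :]) + tB[:, None, :]
        pooled = np.concatenate([selA, selB], axis=0)
        var = pooled.var(axis=0).sum(axis=1)  # total 3D variance, nm^2
        w = 1.0 / (var + epsilon)
        w = w / w.max()

    if not converged and max_iter > 1:
        logger.warning(
            "iterative alignment did not converge in %d iterations", max_iter
        )

    coordsA = np.einsum("fkl,fjl->fjk", RA, trajA.coords) + tA[:, None, :]
    coordsB = np.einsum("fkl,fjl->fjk", RB, trajB.coords) + tB[:, None, :]
    resA = AlignmentResult(
        trajA.with_coords(coordsA), history[-1], history, n_iter, converged
    )
    resB = AlignmentResult(
        trajB.with_coords(coordsB), history[-1].copy(), list(history), n_iter, converged
    )
    return resA, resB
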