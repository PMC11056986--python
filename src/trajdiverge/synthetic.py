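"""Synthetic trajectory pairs with planted conformational differences.

The generator produces the statistical structure the divergence analysis
assumes: a bead-per-residue chain fluctuating isotropically about a fixed
reference geometry, wrapped in a rigid-body random walk (so alignment is
actually exercised), with optional planted events —

* ``mean_shift``   — a contiguous residue block whose mean position is
  displaced in one trajectory (a persistently shifted loop);
* ``two_state_switch`` — a block that jumps to a displaced mean at a given
  snapshot (an open/closed gate transition);
* ``flip_pair``    — two halves of a block exchange positions along their
  connecting axis at a given snapshot (the analog of two side chains
  swapping places, which makes anchored distance distributions bimodal).

Fluctuations are independent isotropic Gaussians per residue, the
simplest model under which per-residue positional distributions — the
objects the KLD machinery compares — are exactly well defined. No bonds,
excluded volume or force field: physically realistic dynamics are
deliberately out of scope.

Draw order from the single seeded stream is fixed (baseline noise A,
baseline noise B, rigid walk A, rigid walk B, then event directions), so
adding an event never perturbs the baseline or drift draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .model import Bead, Trajectory

#: Ideal-helix backbone geometry (nm, degrees) for the reference chain.
HELIX_RISE = 0.15
HELIX_RADIUS = 0.23
HELIX_TWIST_DEG = 100.0

EVENT_KINDS = ("mean_shift", "two_state_switch", "flip_pair")


@dataclass(frozen=True)
class Event:
    """A planted conformational difference.

    residues : 1-based inclusive range (lo, hi).
    magnitude : displacement in nm.
    switch_frame : 0-based snapshot at which switch/flip events fire.
    state_b_only : if False, mean_shift is applied to both trajectories.
    """

    kind: str
    residues: tuple[int, int]
    magnitude: float
    switch_frame: int | None = None
    state_b_only: bool = True

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigurationError(
                f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}"
            )
        lo, hi = self.residues
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"invalid event residue range {self.residues}")
        if self.magnitude <= 0:
            raise ConfigurationError("event magnitude must be > 0")
        if self.kind in ("two_state_switch", "flip_pair") and self.switch_frame is None:
            raise ConfigurationError(f"{self.kind} events need switch_frame")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic trajectory pair.

    Defaults: 100 residues, 2000 snapshots, baseline sigma 0.1 nm — a
    pair the full pipeline processes in seconds.
    """

    n_residues: int = 100
    n_frames: int = 2000
    baseline_sigma: float = 0.1
    drift_rotation: float = 0.002  # radians/frame random-walk step scale
    drift_translation: float = 0.01  # nm/frame random-walk step scale
    events: tuple[Event, ...] = ()
    seed: int = 0
    shared_noise: bool = False  # reuse A's internal noise draws for B

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ConfigurationError("n_residues must be >= 10")
        if self.n_frames < 10:
            raise ConfigurationError("n_frames must be >= 10")
        if self.baseline_sigma <= 0:
            raise ConfigurationError("baseline_sigma must be > 0")
        occupied: set[int] = set()
        for ev in self.events:
            lo, hi = ev.residues
            if hi > self.n_residues:
                raise ConfigurationError(
                    f"event residues {ev.residues} exceed chain of "
                    f"{self.n_residues}"
                )
            span = set(range(lo, hi + 1))
            if occupied & span:
                raise ConfigurationError(
                    f"events overlap on residues {sorted(occupied & span)}"
                )
            occupied |= span
            if ev.switch_frame is not None and not (
                0 <= ev.switch_frame < self.n_frames
            ):
                raise ConfigurationError(
                    f"switch_frame {ev.switch_frame} outside 0..{self.n_frames - 1}"
                )


def generate_reference_chain(n_residues: int, seed: int = 0) -> Trajectory:
    """Bead-per-residue backbone on an ideal helix (single frame).

    The helix (rise 0.15 nm, radius 0.23 nm, 100 deg/residue) only gives
    residue ranges a meaningful spatial layout; its geometry is
    seed-independent — the seed is reserved for dynamics.
    """
    if n_residues < 10:
        raise ConfigurationError("n_residues must be >= 10")
    i = np.arange(n_residues)
    theta = np.deg2rad(HELIX_TWIST_DEG) * i
    coords = np.column_stack(
        [
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * i,
        ]
    )
    beads = [Bead("BB", int(r) + 1, "GLY") for r in i]
    return Trajectory(beads, coords[None], label=f"ref_chain_s{seed}")


def _random_walk_transforms(
    rng: np.random.Generator, n_frames: int, rot_step: float, trans_step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Compounding rigid-body random walk: (R (F,3,3), t (F,3))."""
    R = np.empty((n_frames, 3, 3))
    t = np.empty((n_frames, 3))
    cur_R = np.eye(3)
    cur_t = np.zeros(3)
    axes = rng.normal(size=(n_frames, 3))
    angles = rng.normal(scale=rot_step, size=n_frames)
    steps = rng.normal(scale=trans_step, size=(n_frames, 3))
    for f in range(n_frames):
        axis = axes[f]
        norm = np.linalg.norm(axis)
        if norm > 0 and rot_step > 0:
            axis = axis / norm
            a = angles[f]
            K = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            dR = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
            cur_R = dR @ cur_R
        cur_t = cur_t + steps[f]
        R[f] = cur_R
        t[f] = cur_t
    return R, t


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_pair(
    config: SyntheticConfig,
) -> tuple[Trajectory, Trajectory, list[Event]]:
    """Generate trajectories A (baseline) and B (baseline + events).

    Both share the reference geometry and baseline fluctuation statistics
    but ride independent rigid-body random walks. The planted events are
    returned as ground truth for recovery experiments.
    """
    rng = np.random.default_rng(config.seed)
    ref = generate_reference_chain(config.n_residues, config.seed)
    base = ref.coords[0]  # (N, 3)
    F, N = config.n_frames, config.n_residues

    noiseA = rng.normal(scale=config.baseline_sigma, size=(F, N, 3))
    if config.shared_noise:
        noiseB = noiseA
    else:
        noiseB = rng.normal(scale=config.baseline_sigma, size=(F, N, 3))
    RA, tA = _random_walk_transforms(
        rng, F, config.drift_rotation, config.drift_translation
    )
    RB, tB = _random_walk_transforms(
        rng, F, config.drift_rotation, config.drift_translation
    )

    offsetsA = np.zeros((F, N, 3))
    offsetsB = np.zeros((F, N, 3))
    for ev in config.events:
        lo, hi = ev.residues
        rsl = slice(lo - 1, hi)  # residues are 1-based
        if ev.kind == "mean_shift":
            u = _unit_vector(rng) * ev.magnitude
            offsetsB[:, rsl, :] += u
            if not ev.state_b_only:
                offsetsA[:, rsl, :] += u
        elif ev.kind == "two_state_switch":
            u = _unit_vector(rng) * ev.magnitude
            offsetsB[ev.switch_frame:, rsl, :] += u
        elif ev.kind == "flip_pair":
            mid = (lo + hi + 1) // 2
            g1 = slice(lo - 1, mid - 1)
            g2 = slice(mid - 1, hi)
            c1 = base[g1].mean(axis=0)
            c2 = base[g2].mean(axis=0)
            axis = c2 - c1
            sep = np.linalg.norm(axis)
            if sep == 0:
                axis = _unit_vector(rng)
            else:
                axis = axis / sep
            offsetsB[ev.switch_frame:, g1, :] += ev.magnitude * axis
            offsetsB[ev.switch_frame:, g2, :] -= ev.magnitude * axis

    internalA = base + noiseA + offsetsA
    internalB = base + noiseB + offsetsB
    coordsA = np.einsum("fkl,fjl->fjk", RA, internalA) + tA[:, None, :]
    coordsB = np.einsum("fkl,fjl->fjk", RB, internalB) + tB[:, None, :]
    labelA = f"synthA_s{config.seed}"
    labelB = f"synthB_s{config.seed}"
    trajA = Trajectory(ref.beads, coordsA, label=labelA)
    trajB = Trajectory(ref.beads, coordsB, label=labelB)
    return trajA, trajB, list(config.events)


def flip_pair_planted_distances(
    config: SyntheticConfig, event: Event, anchor_residues: tuple[int, int]
) -> tuple[float, float]:
    """Planted before/after COM distances (nm) from an anchor block to the
    first half of a flip_pair event's residues — ground truth for
    bimodality checks (rigid drift does not change internal distances)."""
    base = generate_reference_chain(config.n_residues, config.seed).coords[0]
    lo, hi = event.residues
    mid = (lo + hi + 1) // 2
    c1 = base[lo - 1:mid - 1].mean(axis=0)
    c2 = base[mid - 1:hi].mean(axis=0)
    axis = c2 - c1
    axis = axis / np.linalg.norm(axis)
    a_lo, a_hi = anchor_residues
    anchor = base[a_lo - 1:a_hi].mean(axis=0)
    before = float(np.linalg.norm(anchor - c1))
    after = float(np.linalg.norm(anchor - (c1 + event.magnitude * axis)))
    return before, after


@dataclass(frozen=True)
class GateConfig:
    """A target bead enclosed by a contracting (or expanding) occluder shell.

    Occluders sit at deterministic sphere directions around the target;
    their radial distance moves linearly from ``r_start`` to ``r_end`` nm
    over the frames, emulating a loop gate closing over a cofactor.
    """

    n_frames: int = 60
    n_occluders: int = 48
    r_start: float = 1.6
    r_end: float = 0.4
    bead_radius: float = 0.26
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_occluders < 4:
            raise ConfigurationError("need >= 1 frame and >= 4 occluders")
        if min(self.r_start, self.r_end) <= 0:
            raise ConfigurationError("shell radii must be positive")


def generate_gate_system(config: GateConfig) -> Trajectory:
    """Trajectory of a target bead (residue 1, ``TGT``) plus an occluder
    shell (``OCC`` beads) whose radius interpolates r_start -> r_end."""
    from .geometry import sphere_points

    directions = sphere_points(config.n_occluders)
    radii_t = np.linspace(config.r_start, config.r_end, config.n_frames)
    coords = np.zeros((config.n_frames, config.n_occluders + 1, 3))
    for f in range(config.n_frames):
        coords[f, 1:, :] = radii_t[f] * directions
    beads = [Bead("TGT", 1, "FAD", radius=config.bead_radius)]
    beads += [
        Bead("OCC", i + 2, "GLY", radius=config.bead_radius)
        for i in range(config.n_occluders)
    ]
    return Trajectory(beads, coords, label=f"gate_s{config.seed}")
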