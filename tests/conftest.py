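import numpy as np
import pytest

from trajdiverge import Bead, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_chain(n_residues: int, n_frames: int = 1, spacing: float = 0.4,
               label: str = "chain") -> Trajectory:
    """Straight bead-per-residue chain along x, optionally replicated frames."""
    beads = [Bead("BB", i + 1, "GLY") for i in range(n_residues)]
    base = np.zeros((n_residues, 3))
    base[:, 0] = spacing * np.arange(n_residues)
    coords = np.repeat(base[None], n_frames, axis=0)
    return Trajectory(beads, coords, label=label)


@pytest.fixture
def chain10():
    return make_chain(10)
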