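"""Counter-based randomness.

All stochastic decisions in a run are drawn from Philox streams keyed by
``(master seed, step index, purpose)`` and indexed by voxel.  A decision made
at a given voxel on a given step therefore does not depend on how many draws
other parts of the model consumed, which keeps trajectories bitwise
reproducible and makes perturbation experiments (dose sweeps, regime
comparisons) share their random decisions until the perturbation itself
changes the dynamics.
"""

from __future__ import annotations

import numpy as np

# purpose tags
DIVISION = 1
BRANCH = 2
TIP = 3

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


def purpose_generator(seed: int, step: int, purpose: int) -> np.random.Generator:
    """A Philox generator dedicated to one (seed, step, purpose) triple."""
    if seed < 0 or step < 0 or purpose < 0:
        raise ValueError("seed, step and purpose must be non-negative")
    key = np.array([seed, step * 16 + purpose], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


def uniform_grid(seed: int, step: int, purpose: int, shape) -> np.ndarray:
    """Voxel-indexed uniforms in [0, 1) for one step and purpose."""
    gen = purpose_generator(seed, step, purpose)
    n = int(np.prod(shape))
    return gen.random(n).reshape(shape)
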