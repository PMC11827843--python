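"""Counter-based seed derivation.

One master seed drives every stochastic stage.  Child streams are derived
with :class:`numpy.random.SeedSequence` spawn keys, so each (stage, index)
pair gets an independent stream regardless of execution order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spawn_seed", "keyed_rng"]


def spawn_seed(master: int, *key: int) -> int:
    """Derive a child integer seed (< 2**31) from a master seed and a key path."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def keyed_rng(master: int, *key: int) -> np.random.Generator:
    """A Generator seeded by (master, key path) via the same splitting rule."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
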