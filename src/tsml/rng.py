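"""Named, reproducible random substreams.

Every source of randomness in the package (data generation, parameter
initialization, shuffling, frame sampling, splitting) draws from a
substream addressed by a root seed plus a tuple of names, e.g.
``substream(seed, "init", "spatial", "student1")``.  Substreams are
independent of each other and of call order, so any component can be
re-run in isolation and reproduce its draws exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _key(words: tuple[str | int, ...]) -> list[int]:
    out = []
    for w in words:
        if isinstance(w, (int, np.integer)):
            out.append(int(w) & 0x7FFFFFFF)
        else:
            out.append(zlib.crc32(str(w).encode("utf-8")) & 0x7FFFFFFF)
    return out


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator for the substream addressed by ``names``."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *_key(names)])


def spawn_seed(seed: int, *names: str | int) -> int:
    """Derive a scalar child seed (< 2**31) for APIs that take one."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
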