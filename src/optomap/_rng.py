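"""Deterministic, splittable random streams.

A single experiment seed is fanned out into independent substreams keyed by
(domain, index...) so that, e.g., adding cells to a scene never reshuffles the
draws of existing cells, and fluorescence noise is independent of ephys noise.
"""

from __future__ import annotations

import numpy as np

# Domain codes for substream keys. Stable across releases: changing a code
# changes every simulation generated under it.
SCENE = 0
CELL = 1
SPIKES = 2
OFFTARGET = 3
GCAMP = 4
EPHYS = 5
SPONT = 6
USER = 7


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``key`` under ``seed``.

    The same (seed, key) always yields the same stream; distinct keys yield
    statistically independent streams (numpy SeedSequence spawn keys).
    """
    if not (0 <= int(seed) < 2**63):
        raise ValueError(f"seed must be a non-negative 63-bit integer, got {seed}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
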