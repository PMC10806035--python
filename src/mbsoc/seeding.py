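"""Deterministic per-purpose random streams.

Every stochastic component draws from its own substream derived from
(master seed, purpose label, instance index), so adding an experiment never
perturbs the draws of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np


def spawn_rng(master_seed: int, purpose: str, index: int = 0) -> np.random.Generator:
    """Generator for one purpose-labelled substream of ``master_seed``."""
    key = zlib.crc32(purpose.encode("utf8"))
    seq = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key, int(index)))
    return np.random.default_rng(seq)
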