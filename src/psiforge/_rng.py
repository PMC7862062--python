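"""Seed-stream derivation.

One master seed; each generator/operation draws from a child stream derived
from a fixed textual label, so adding or re-ordering one simulation never
perturbs the random stream of another.
"""

import zlib

import numpy as np


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for ``label`` derived deterministically from ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))
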