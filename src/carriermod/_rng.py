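"""Named, independent random streams.

Every stochastic component (founder genotypes, event ages, censoring,
ascertainment, dosage noise, ...) draws from its own generator so that one
component can be varied while the others are held fixed under the same seed.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a reproducible generator keyed by (seed, name).

    The stream key is derived from a CRC32 of the name, so streams are
    stable across runs and independent of the order in which they are
    requested.
    """
    seed = int(seed)
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))
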