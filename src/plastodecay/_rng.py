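"""Per-operation random streams.

Every stochastic operation draws from a generator derived from
``(seed, operation_name)`` so that adding new operations never perturbs
the streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, op_name: str) -> np.random.Generator:
    """Return a deterministic generator for (seed, op_name)."""
    tag = zlib.crc32(op_name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
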