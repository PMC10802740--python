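"""Deterministic substream derivation.

All randomness in the package flows from one integer pipeline seed.  Each
module/purpose derives its own independent generator from (seed, label...)
so stages can be regenerated in isolation without perturbing one another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator keyed by the pipeline seed and a label path.

    The label path is hashed with CRC-32 into a second entropy word, so
    identical (seed, labels) always produce the same stream and distinct
    labels produce independent streams.
    """
    key = zlib.crc32("/".join(str(l) for l in labels).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def subseed(seed: int, *labels: object) -> int:
    """A plain integer seed (< 2**31) derived like :func:`substream`."""
    key = zlib.crc32("/".join(str(l) for l in labels).encode("utf-8"))
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]).generate_state(1)[0] & 0x7FFFFFFF)
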