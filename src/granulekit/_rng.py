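"""Seed-derivation helpers.

One root seed per run; every component derives its own independent child
stream deterministically from (seed, label...), so stages can be re-run in
isolation and still reproduce bit-identically.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng"]


def child_rng(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator keyed by the root seed and a component label chain.

    The label is hashed with CRC-32 so the mapping is stable across runs and
    platforms; distinct labels give statistically independent streams.
    """
    key = [int(seed)] + [zlib.crc32(str(lab).encode("utf8")) for lab in labels]
    return np.random.default_rng(key)
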