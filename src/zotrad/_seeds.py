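"""Deterministic seed derivation.

Every stochastic stage of the pipeline draws its seed from a master seed
through :func:`derive_seed`, a fixed integer hash built on
``numpy.random.SeedSequence``.  Deriving per-item seeds (rather than
sharing RNG state) makes each item reproducible independently of the
order in which items are generated.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_from"]


def _tag_to_int(tag: int | str) -> int:
    if isinstance(tag, str):
        return zlib.crc32(tag.encode("utf-8"))
    return int(tag)


def derive_seed(master_seed: int, *tags: int | str) -> int:
    """Hash ``(master_seed, *tags)`` into a seed in ``[0, 2**31)``.

    String tags are folded through CRC-32 so stage names ("split",
    "ga", ...) and integer indices can be mixed freely.  The mapping is
    fixed across runs and platforms.
    """
    entropy = [int(master_seed) & 0xFFFFFFFF] + [_tag_to_int(t) for t in tags]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


def rng_from(master_seed: int, *tags: int | str) -> np.random.Generator:
    """A ``numpy`` Generator seeded via :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *tags))
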