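"""Deterministic sub-seed derivation.

All randomness in the package flows from a single master seed.  Child
generators are derived with :class:`numpy.random.SeedSequence` spawn keys,
where each key is a stable integer hash of a string path such as
``("plate", "A01")``.  Because every consumer owns its own named stream,
adding wells, genes or replicates never perturbs draws made elsewhere.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _key(part: str | int) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part)
    # crc32 is stable across platforms and python versions
    return zlib.crc32(str(part).encode("utf-8"))


def child_rng(master_seed: int, *path: str | int) -> np.random.Generator:
    """Return a generator for the stream named by ``path``.

    The same ``(master_seed, path)`` pair always yields an identical
    stream; distinct paths yield statistically independent streams.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(_key(p) for p in path))
    return np.random.default_rng(ss)


def child_seed(master_seed: int, *path: str | int) -> int:
    """A plain integer sub-seed (< 2**31) for APIs that want one."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=tuple(_key(p) for p in path))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
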