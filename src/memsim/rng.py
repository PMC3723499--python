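"""Seed management.

A single master seed deterministically spawns named child streams so that
changing how one component consumes randomness never perturbs another
(per-realization, per-stage, per-replay streams are all independent).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng", "spawn_rngs"]


def _key(name: str | int) -> int:
    if isinstance(name, int):
        if name < 0:
            raise ValueError("integer stream names must be non-negative")
        return name
    return zlib.crc32(name.encode("utf-8"))


def child_seed_sequence(master_seed: int, *names: str | int) -> np.random.SeedSequence:
    """Named child of the master seed.

    The spawn key is derived from CRC32 hashes of the names, so the mapping
    (master_seed, names) -> stream is stable across runs and platforms.
    """
    return np.random.SeedSequence(master_seed, spawn_key=tuple(_key(n) for n in names))


def child_rng(master_seed: int, *names: str | int) -> np.random.Generator:
    """A Generator for the named child stream."""
    return np.random.default_rng(child_seed_sequence(master_seed, *names))


def spawn_rngs(master_seed: int, name: str, n: int) -> list[np.random.Generator]:
    """``n`` independent generators, one per realization/worker."""
    return [child_rng(master_seed, name, i) for i in range(n)]
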