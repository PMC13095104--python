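"""Named, hierarchical random streams.

One master seed reproduces a whole experiment; every component (network
wiring, cortical spike trains, per-trial background noise, per-trial initial
conditions, ...) draws from its own named sub-stream so it can be regenerated
in isolation without replaying anything else.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_rng"]


def _name_key(name: str) -> int:
    # stable across processes and platforms, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def substream(master_seed: int, name: str, *indices: int) -> np.random.SeedSequence:
    """Seed sequence for the sub-stream ``name`` (optionally indexed, e.g. per trial)."""
    if master_seed < 0:
        raise ValueError("master_seed must be non-negative")
    return np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=(_name_key(name), *[int(i) for i in indices]),
    )


def spawn_rng(master_seed: int, name: str, *indices: int) -> np.random.Generator:
    """Generator seeded from :func:`substream`."""
    return np.random.default_rng(substream(master_seed, name, *indices))
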