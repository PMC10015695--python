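"""Named random sub-streams.

All randomness in the package flows from a single integer root seed.
Independent stages (panel simulation, read generation, thinning, each
(fraction, method) cell of a benchmark sweep, ...) draw from sub-streams
keyed by stable string tags, so adding a stage never perturbs another
stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *tags) -> np.random.Generator:
    """Return a Generator for the sub-stream named by ``tags`` under ``seed``.

    Tags are hashed with CRC32 into the SeedSequence spawn key, so streams
    are reproducible across processes and platforms.
    """
    key = tuple(zlib.crc32(str(t).encode("utf8")) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
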