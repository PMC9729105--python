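"""Named random substreams derived from a single master seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Streams for distinct names are statistically independent and
    bit-reproducible across processes (the name is hashed with CRC32,
    which is platform-stable, unlike Python's ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
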