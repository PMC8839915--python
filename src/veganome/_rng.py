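"""Named random substreams derived from a single run seed."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: str) -> np.random.Generator:
    """Generator for a named substream of the master seed.

    Keys the stream by a CRC32 of the name path so that every stage of
    the pipeline draws from an independent, reproducible stream and
    adding a stage never perturbs the draws of another.
    """
    tag = zlib.crc32("/".join(names).encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))
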