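"""Named random substreams.

Every stochastic stage of the pipeline derives its generator from a single
integer seed plus a short stage name, so stages can be re-run independently
without perturbing each other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage `name` derived from the master `seed`.

    The stage name is hashed with CRC-32, which is stable across platforms
    and Python versions (unlike the builtin ``hash``).
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
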