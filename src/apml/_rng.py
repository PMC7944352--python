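"""Seed handling: one top-level seed, named substreams per generator.

Every dataset/experiment generator draws from ``substream(seed, name)`` so
that partial reruns (e.g. regenerating only the test split) stay aligned
with the manifest.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> np.random.SeedSequence:
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named child stream of a top-level integer seed."""
    return np.random.default_rng(substream_seed(seed, name))
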