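"""Domain-separated random streams.

Every stochastic component (Mock generation, Control balancing, bootstrap
resampling, fixture synthesis) derives its generator from the single user
seed plus a component-specific stream key.  This keeps a run a pure
function of the seed while guaranteeing that two components given the same
seed never consume the same underlying random stream — otherwise, e.g., a
Mock repertoire generated with the seed that also synthesised the proteome
would tile the proteome's own residue draws and self-match everywhere.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """A generator for ``stream`` that is independent across stream names
    and deterministic in (seed, stream)."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    )
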