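"""Seed handling: every public function accepts an int seed or a Generator."""

from __future__ import annotations

import numpy as np


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator to a Generator.

    Any object exposing the Generator draw methods is passed through,
    so deterministic stand-ins can drive the samplers in tests.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if hasattr(seed, "random") and hasattr(seed, "standard_normal"):
        return seed
    return np.random.default_rng(seed)
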