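"""Counter-based seed derivation.

A single global seed fans out to per-stage / per-animal / per-frequency
substreams via :class:`numpy.random.SeedSequence` spawn keys, so enlarging a
cohort never reshuffles the randomness of earlier animals.
"""

from __future__ import annotations

import numpy as np

# Stable stage indices used as the first spawn-key component.
STAGE_PHANTOM = 0
STAGE_WAVES = 1
STAGE_CONTRAST = 2
STAGE_COHORT = 3


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``key``.

    ``seed`` is the user-facing global seed; ``key`` is an arbitrary tuple of
    non-negative integers (stage, animal index, timepoint index, ...).
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
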