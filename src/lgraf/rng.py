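"""Seed management.

A single master seed fans out into independent named substreams, one per
pipeline stage, so that changing the draws of one stage (e.g. trying a
different crop scheme) does not perturb the random sequences of the others.
"""

from __future__ import annotations

import numpy as np

#: Fixed stage identifiers; order is part of the reproducibility contract.
STAGE_IDS = {
    "roads": 0,
    "settlement": 1,
    "inaccessible": 2,
    "fields": 3,
    "crops": 4,
    "fixtures": 5,
}


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Return the dedicated random generator for one pipeline stage."""
    if stage not in STAGE_IDS:
        raise KeyError(f"unknown rng stage {stage!r}")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, STAGE_IDS[stage]]))


def as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed, Generator or None into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
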