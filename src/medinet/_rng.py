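"""Deterministic seed-stream management.

Every stochastic stage of the pipeline draws from its own generator, derived
from a single master seed plus a fixed stage code.  No stage touches numpy's
global state, so pipelines are reproducible end to end and stages can be
re-run in isolation.
"""

from __future__ import annotations

import numpy as np

# Fixed stage codes; appending new stages must not renumber existing ones.
STAGES = {
    "items_ms": 11,
    "items_hc": 12,
    "demographics_ms": 21,
    "demographics_hc": 22,
    "lifestyle_ms": 31,
    "lifestyle_hc": 32,
    "outcomes": 41,
    "edge_test": 51,
    "reshuffle": 61,
    "power_sim": 71,
}


def stage_rng(master_seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Return the generator for ``stage`` under ``master_seed``.

    ``extra`` integers (e.g. a replicate index) extend the entropy tuple so
    substreams never collide.
    """
    if stage not in STAGES:
        raise KeyError(f"unknown rng stage {stage!r}; known: {sorted(STAGES)}")
    entropy = [int(master_seed) & 0x7FFFFFFF, STAGES[stage], *[int(e) for e in extra]]
    return np.random.default_rng(np.random.SeedSequence(entropy))
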