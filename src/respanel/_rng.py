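"""Named random substreams derived from one integer seed.

Each simulation stage (expression draw, Ct noise, clinical covariates,
search restarts) pulls its own generator, keyed by a fixed purpose code,
so adding or re-running one stage never perturbs another stage's draws.
"""

from __future__ import annotations

import numpy as np

# Fixed purpose codes; order is part of the reproducibility contract.
_PURPOSES = {
    "expression": 0,
    "ct_noise": 1,
    "covariates": 2,
    "search": 3,
}


def substream(seed: int, purpose: str, *indices: int) -> np.random.Generator:
    """Return a Generator for (seed, purpose, *indices).

    ``indices`` distinguishes parallel uses within one purpose, e.g.
    (selection-model code, restart number) for search restarts.
    """
    if purpose not in _PURPOSES:
        raise ValueError(f"unknown substream purpose: {purpose!r}")
    key = (int(seed), _PURPOSES[purpose], *[int(i) for i in indices])
    return np.random.default_rng(np.random.SeedSequence(key))
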