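"""Shared helpers: seed-stream management and small validators."""

from __future__ import annotations

import numpy as np

#: canonical order in which pipeline stages draw their sub-streams
STAGE_NAMES = ("simulate", "de", "subnet", "regulon", "overlap")


def stage_rngs(master_seed: int) -> dict[str, np.random.Generator]:
    """Derive one independent generator per pipeline stage from a master seed.

    Uses ``numpy.random.SeedSequence.spawn`` so streams are statistically
    independent and stable across runs with the same master seed.
    """
    ss = np.random.SeedSequence(int(master_seed))
    children = ss.spawn(len(STAGE_NAMES))
    return {name: np.random.default_rng(child) for name, child in zip(STAGE_NAMES, children)}


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def check_proportion(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def check_positive(value, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")
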