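"""Within-participant trial list of the chase-detection study.

Every participant completes three blocks, one per cue condition, in an order
counterbalanced across participants (cycling through all six permutations of
baseline/social/nonsocial). Each block opens with 6 practice trials (one
chase-present and one chase-absent per subtlety) followed by 75 test trials:
for each of the three subtleties, 20 chase-present and 5 chase-absent trials
in a seeded random order.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .stimulus import CONDITIONS

__all__ = ["SUBTLETIES", "N_PRESENT_PER_CELL", "N_ABSENT_PER_CELL", "build_design"]

#: Chasing subtleties used in the study (deg).
SUBTLETIES = (15.0, 45.0, 75.0)
N_PRESENT_PER_CELL = 20
N_ABSENT_PER_CELL = 5

_PERMUTATIONS = tuple(itertools.permutations(CONDITIONS))

_COLUMNS = [
    "participant_id", "block_index", "condition", "subtlety",
    "chase_present", "is_practice", "trial_index", "seed",
]


def build_design(
    n_participants: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build the full trial table for ``n_participants``.

    Returns a DataFrame with one row per trial (243 per participant: 3
    blocks × (6 practice + 75 test)), columns ``participant_id``,
    ``block_index``, ``condition``, ``subtlety``, ``chase_present``,
    ``is_practice``, ``trial_index`` and a unique per-trial ``seed`` for
    trajectory generation. Condition orders cycle through all six block
    permutations in participant order; trial order within a block is a
    seeded shuffle (practice trials always precede test trials).
    """
    if n_participants < 1:
        raise InvalidParameterError("n_participants must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    rows: list[tuple] = []
    for p in range(n_participants):
        order = _PERMUTATIONS[p % len(_PERMUTATIONS)]
        for b, condition in enumerate(order):
            practice = [(s, pres) for s in SUBTLETIES for pres in (True, False)]
            test = [
                (s, pres)
                for s in SUBTLETIES
                for pres, n in ((True, N_PRESENT_PER_CELL), (False, N_ABSENT_PER_CELL))
                for _ in range(n)
            ]
            rng.shuffle(practice)
            rng.shuffle(test)
            for i, (s, pres) in enumerate(practice + test):
                rows.append((p, b, condition, s, pres, i < len(practice), i))

    table = pd.DataFrame(rows, columns=_COLUMNS[:-1])
    table["seed"] = _unique_seeds(len(table), rng)
    return table


def _unique_seeds(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n distinct seeds below 2^31."""
    seeds = rng.integers(0, 2**31, size=n)
    while len(np.unique(seeds)) < n:  # pragma: no cover - astronomically rare
        _, idx = np.unique(seeds, return_index=True)
        dup = np.setdiff1d(np.arange(n), idx)
        seeds[dup] = rng.integers(0, 2**31, size=len(dup))
    return seeds
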