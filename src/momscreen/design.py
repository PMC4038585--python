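"""Random assignment of subjects to training / test / validation sets.

Assignment is stratified by outcome group with a 40/30/30 design.  The
rounding convention — round-half-up on the training and test fractions, with
the validation set as remainder — is the one that reproduces the printed
per-group counts of the study design: 500 controls -> 200/150/150,
68 EO-PE -> 27/20/21, 99 LO-PE -> 40/30/29.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SplitAssignment", "split_sizes", "assign_splits", "SETS"]

SETS = ("train", "test", "validation")


@dataclass
class SplitAssignment:
    """Mapping subject_id -> {train, test, validation}, plus per-group counts."""

    assignment: pd.Series  # index subject_id, values in SETS
    group_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def subjects_in(self, which: str) -> pd.Index:
        if which not in SETS:
            raise ValueError(f"unknown set {which!r}")
        return self.assignment.index[self.assignment == which]

    def to_frame(self) -> pd.DataFrame:
        return self.assignment.rename("set").rename_axis("subject_id").reset_index()


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_sizes(n: int, fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
                ) -> tuple[int, int, int]:
    """Per-set sizes for a group of ``n``: round-half-up train and test,
    validation as remainder."""
    if n < 3:
        raise ValueError("need at least 3 subjects per group to split")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("split fractions must sum to 1")
    n_train = _round_half_up(fractions[0] * n)
    n_test = _round_half_up(fractions[1] * n)
    n_val = n - n_train - n_test
    if min(n_train, n_test, n_val) < 1:
        raise ValueError(f"group of {n} yields an empty split: "
                         f"({n_train}, {n_test}, {n_val})")
    return n_train, n_test, n_val


def assign_splits(subjects: pd.DataFrame,
                  fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
                  seed: int = 0) -> SplitAssignment:
    """Seeded random split within each outcome group.

    Within a group, a random permutation of its subjects is cut at the
    :func:`split_sizes` boundaries.  Identical ``(subjects, fractions, seed)``
    give an identical assignment.
    """
    if "group" not in subjects.columns or "subject_id" not in subjects.columns:
        raise ValueError("subject table needs subject_id and group columns")
    rng = np.random.default_rng(seed)
    labels = pd.Series(index=pd.Index(subjects["subject_id"], name="subject_id"),
                       dtype=object)
    counts: dict[str, tuple[int, int, int]] = {}
    for group, ids in subjects.groupby("group", sort=True)["subject_id"]:
        sizes = split_sizes(len(ids), fractions)
        counts[group] = sizes
        perm = rng.permutation(ids.to_numpy())
        bounds = np.cumsum(sizes[:2])
        for which, chunk in zip(SETS, np.split(perm, bounds)):
            labels.loc[chunk] = which
    return SplitAssignment(labels, counts)
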