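"""Block-design event tables and the dichoptic EEG condition grid.

The fMRI experiment presents a flickering checkerboard to the amblyopic eye
(AE), the fellow eye (FE), or both eyes (binocular) in 18-s blocks separated
by 12-s fixation blocks.  A run with 3 blocks per condition therefore lasts
9*18 + 10*12 = 282 s.  The EEG experiment crosses 2 spatial frequencies x
3 ocularities x 2 tag-frequency assignments = 12 conditions.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

CONDITIONS = ("AE", "FE", "binocular")
FIXATION = "fixation"

#: The two flicker tag frequencies (Hz).  One is delivered to each eye;
#: the assignment is counterbalanced across conditions.
TAG_FREQUENCIES = (7.2, 8.0)


def make_block_design(
    n_per_condition: int,
    block_s: float = 18.0,
    fix_s: float = 12.0,
    seed: int = 0,
    constraint: str = "balanced_triplets",
) -> pd.DataFrame:
    """Build a fixation-leading block design event table.

    The run alternates fixation and stimulus blocks,
    ``fix, stim, fix, stim, ..., fix``, with ``3 * n_per_condition``
    stimulus blocks (``n_per_condition`` per condition) and one more
    fixation block than stimulus blocks.  Condition order is
    pseudo-randomized per ``seed``.

    Parameters
    ----------
    n_per_condition :
        Number of stimulus blocks per condition (>= 1).
    block_s, fix_s :
        Stimulus and fixation block durations in seconds (> 0).
    seed :
        Seed for the condition-order randomization.
    constraint :
        ``"balanced_triplets"`` shuffles each consecutive triplet of
        stimulus blocks as a permutation of the three conditions, so every
        condition appears once per triplet (counterbalanced within run);
        ``"shuffle"`` applies a single unconstrained permutation.

    Returns
    -------
    pandas.DataFrame
        Columns ``onset`` (s), ``duration`` (s), ``trial_type``.
    """
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    if block_s <= 0 or fix_s <= 0:
        raise ValueError("block and fixation durations must be positive")
    if constraint not in ("balanced_triplets", "shuffle"):
        raise ValueError(f"unknown constraint {constraint!r}")

    rng = np.random.default_rng(seed)
    if constraint == "balanced_triplets":
        order: list[str] = []
        for _ in range(n_per_condition):
            order.extend(rng.permutation(CONDITIONS))
    else:
        order = list(rng.permutation(list(CONDITIONS) * n_per_condition))

    rows = []
    t = 0.0
    for cond in order:
        rows.append((t, fix_s, FIXATION))
        t += fix_s
        rows.append((t, block_s, cond))
        t += block_s
    rows.append((t, fix_s, FIXATION))
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


def design_duration(events: pd.DataFrame) -> float:
    """Total run length in seconds (sum of block durations)."""
    return float(events["duration"].sum())


def enumerate_conditions() -> list[tuple[str, str, str]]:
    """Enumerate the 12 EEG stimulus conditions in a stable order.

    Full crossing of spatial frequency {low, high} x ocularity
    {AE, FE, binocular} x tag-frequency assignment.  The assignment
    ``"f1=AE"`` tags the amblyopic (or non-dominant) eye at 7.2 Hz and the
    fellow eye at 8 Hz; ``"f1=FE"`` is the reverse.

    Returns
    -------
    list of (sf, ocularity, tf_assignment) tuples, length 12.
    """
    sfs = ("low", "high")
    ocularities = CONDITIONS
    assignments = ("f1=AE", "f1=FE")
    return list(itertools.product(sfs, ocularities, assignments))


def tag_frequency_map(assignment: str) -> dict[str, float]:
    """Map eye -> tag frequency (Hz) for a tag-frequency assignment."""
    f1, f2 = TAG_FREQUENCIES
    if assignment == "f1=AE":
        return {"AE": f1, "FE": f2}
    if assignment == "f1=FE":
        return {"AE": f2, "FE": f1}
    raise ValueError(f"unknown assignment {assignment!r}")
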