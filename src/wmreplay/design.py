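"""Enumeration of the experimental design.

The task is a combined delay-match-to-sample / Sternberg paradigm: each
trial presents an ordered sequence of three stimuli (one from each of three
visual categories, each shown from one of three perspectives), followed by a
5000 ms retention period and two memory probes (a same/different detail
probe and a 1/2/3 order probe).

The full design crosses the 6 category orders with the 3 perspectives of
each sequence position: 6 x 3 x 3 x 3 = 162 unique trials, split into 6 runs
of 27 trials.  Probe position is balanced over 1..3 and the correct
detail-probe answer is "same" on exactly half the trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CATEGORIES, PERSPECTIVES, ValidationError

N_TRIALS = 162
N_RUNS = 6
TRIALS_PER_RUN = 27


@dataclass
class TrialDesign:
    """One trial's configuration and (once simulated or observed) behavior.

    ``sequence`` is the ordered triplet of ``(category, perspective)`` pairs;
    the categories are always a permutation of F, B, C.  The detail probe
    shows ``probe_item``: on "same" trials it is exactly the stimulus at
    ``probe_position``, on "different" trials the same category from another
    perspective.
    """

    trial_id: int
    run_id: int
    sequence: tuple[tuple[str, str], ...]
    probe_position: int
    probe_same: bool
    probe_item: tuple[str, str]
    detail_response: bool | None = None
    detail_rt: float | None = None
    order_response: int | None = None
    order_rt: float | None = None
    pm_position: int | None = None  # simulation ground truth, 1-based

    def __post_init__(self) -> None:
        cats = tuple(c for c, _ in self.sequence)
        if sorted(cats) != sorted(CATEGORIES):
            raise ValidationError(f"sequence categories {cats} not a permutation")
        if self.probe_position not in (1, 2, 3):
            raise ValidationError("probe_position must be 1, 2 or 3")
        if self.probe_item[0] != self.sequence[self.probe_position - 1][0]:
            raise ValidationError("probe category != category at probe position")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.sequence)

    @property
    def probe_category(self) -> str:
        return self.probe_item[0]

    def position_of(self, category: str) -> int:
        """1-based sequence position of ``category``."""
        return self.categories.index(category) + 1

    @property
    def pm_category(self) -> str | None:
        if self.pm_position is None:
            return None
        return self.categories[self.pm_position - 1]


def enumerate_design(seed: int) -> list[TrialDesign]:
    """Enumerate all 162 unique trial configurations, randomly ordered.

    Every combination of a category order (6) and a perspective for each of
    the three positions (3^3) occurs exactly once.  Trial order is shuffled
    by ``seed`` and partitioned into 6 runs of 27.  Probe positions are
    balanced (54 trials each) and the detail probe answer is "same" on
    exactly 81 trials.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for order in itertools.permutations(CATEGORIES):
        for persps in itertools.product(PERSPECTIVES, repeat=3):
            configs.append(tuple(zip(order, persps)))
    assert len(configs) == N_TRIALS

    # Balanced probe assignment: position cycles 1,2,3; probe_same balanced
    # within each position (54 per position -> 27 same / 27 different).
    probe_positions = np.array([1, 2, 3] * (N_TRIALS // 3))
    probe_same = np.array(([True, False] * N_TRIALS)[:N_TRIALS])
    rng.shuffle(probe_positions)
    # pair same/different evenly within positions
    probe_same = np.empty(N_TRIALS, dtype=bool)
    for pos in (1, 2, 3):
        idx = np.flatnonzero(probe_positions == pos)
        half = len(idx) // 2
        flags = np.array([True] * half + [False] * (len(idx) - half))
        rng.shuffle(flags)
        probe_same[idx] = flags

    order_idx = rng.permutation(N_TRIALS)
    trials: list[TrialDesign] = []
    for tid, cfg_i in enumerate(order_idx):
        seq = configs[cfg_i]
        pos = int(probe_positions[tid])
        same = bool(probe_same[tid])
        cat, persp = seq[pos - 1]
        if same:
            probe_item = (cat, persp)
        else:
            others = [p for p in PERSPECTIVES if p != persp]
            probe_item = (cat, others[int(rng.integers(len(others)))])
        trials.append(
            TrialDesign(
                trial_id=tid,
                run_id=tid // TRIALS_PER_RUN + 1,
                sequence=seq,
                probe_position=pos,
                probe_same=same,
                probe_item=probe_item,
            )
        )
    return trials


def design_to_frame(design: list[TrialDesign]) -> pd.DataFrame:
    """Flatten a design (with any filled responses) to one row per trial."""
    rows = []
    for t in design:
        row: dict = {"trial_id": t.trial_id, "run_id": t.run_id}
        for i, (cat, persp) in enumerate(t.sequence, start=1):
            row[f"seq_cat_{i}"] = cat
            row[f"seq_persp_{i}"] = persp
        row.update(
            probe_position=t.probe_position,
            probe_same=t.probe_same,
            probe_category=t.probe_item[0],
            probe_perspective=t.probe_item[1],
            detail_response=t.detail_response,
            detail_rt=t.detail_rt,
            order_response=t.order_response,
            order_rt=t.order_rt,
            pm_position=t.pm_position,
        )
        rows.append(row)
    return pd.DataFrame(rows)
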