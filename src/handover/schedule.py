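"""Experimental design: conditions and the blocked trial schedule.

One dyad session consists of 4 blocks of 30 trials (120 trials). Object size
(small/big grasp surfaces) is blocked; object weight (400/700/1000 g) is
pseudo-randomized within each block so that every weight appears exactly 10
times per block. The two participants swap giver/receiver roles after block 2,
and the size block order is counterbalanced across dyads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Size",
    "Weight",
    "WEIGHT_KG",
    "SURFACE_M",
    "TrialCondition",
    "ExperimentSchedule",
    "make_schedule",
]


class Size(str, Enum):
    SMALL = "small"
    BIG = "big"


class Weight(str, Enum):
    LIGHT = "light"
    MEDIUM = "medium"
    HEAVY = "heavy"


#: Object mass per weight condition, kg.
WEIGHT_KG: dict[Weight, float] = {
    Weight.LIGHT: 0.400,
    Weight.MEDIUM: 0.700,
    Weight.HEAVY: 1.000,
}

#: Grasp-surface edge length per size condition, m.
SURFACE_M: dict[Size, float] = {
    Size.SMALL: 0.05,
    Size.BIG: 0.08,
}

N_BLOCKS = 4
TRIALS_PER_BLOCK = 30
REPS_PER_WEIGHT_PER_BLOCK = 10


@dataclass(frozen=True)
class TrialCondition:
    """Metadata identifying one handover trial and its object condition."""

    dyad_id: str
    block: int
    trial_in_block: int
    giver_id: str
    receiver_id: str
    size: Size
    weight: Weight

    def __post_init__(self) -> None:
        if not 1 <= self.block <= N_BLOCKS:
            raise ValueError(f"block must be in 1..{N_BLOCKS}, got {self.block}")
        if not 1 <= self.trial_in_block <= TRIALS_PER_BLOCK:
            raise ValueError(
                f"trial_in_block must be in 1..{TRIALS_PER_BLOCK}, "
                f"got {self.trial_in_block}"
            )
        if self.giver_id == self.receiver_id:
            raise ValueError("giver_id and receiver_id must differ")
        # Normalize plain strings to the enums.
        object.__setattr__(self, "size", Size(self.size))
        object.__setattr__(self, "weight", Weight(self.weight))

    @property
    def mass_kg(self) -> float:
        return WEIGHT_KG[self.weight]

    @property
    def surface_m(self) -> float:
        return SURFACE_M[self.size]


@dataclass(frozen=True)
class ExperimentSchedule:
    """The ordered list of 120 trial conditions for one dyad session.

    Validates the design invariants on construction: 4 blocks x 30 trials,
    each weight exactly 10x per block, size constant within a block, and a
    role swap after block 2.
    """

    dyad_id: str
    trials: tuple[TrialCondition, ...]

    def __post_init__(self) -> None:
        if len(self.trials) != N_BLOCKS * TRIALS_PER_BLOCK:
            raise ValueError(
                f"schedule must contain {N_BLOCKS * TRIALS_PER_BLOCK} trials, "
                f"got {len(self.trials)}"
            )
        for b in range(1, N_BLOCKS + 1):
            block = [t for t in self.trials if t.block == b]
            if len(block) != TRIALS_PER_BLOCK:
                raise ValueError(f"block {b} has {len(block)} trials")
            if len({t.size for t in block}) != 1:
                raise ValueError(f"object size varies within block {b}")
            for w in Weight:
                n = sum(t.weight == w for t in block)
                if n != REPS_PER_WEIGHT_PER_BLOCK:
                    raise ValueError(
                        f"block {b}: weight {w.value} appears {n}x, "
                        f"expected {REPS_PER_WEIGHT_PER_BLOCK}"
                    )
            givers = {t.giver_id for t in block}
            if len(givers) != 1:
                raise ValueError(f"giver varies within block {b}")
        first_half_giver = self.trials[0].giver_id
        second_half_giver = self.trials[-1].giver_id
        if first_half_giver == second_half_giver:
            raise ValueError("roles must swap after block 2")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]


def participant_ids(dyad_id: str) -> tuple[str, str]:
    """The two participant identifiers of a dyad."""
    return f"{dyad_id}-a", f"{dyad_id}-b"


def make_schedule(
    dyad_id: str, counterbalance_flag: bool, seed: int
) -> ExperimentSchedule:
    """Build the 120-trial schedule for one dyad session.

    Parameters
    ----------
    dyad_id:
        Identifier of the dyad; participant ids are derived as
        ``{dyad_id}-a`` and ``{dyad_id}-b``.
    counterbalance_flag:
        False -> size order small, big, small, big; True -> big first.
        Alternating the flag across dyads counterbalances the size order.
    seed:
        Seeds the pseudo-random weight permutation of each block.
    """
    p_a, p_b = participant_ids(dyad_id)
    if counterbalance_flag:
        block_sizes = [Size.BIG, Size.SMALL, Size.BIG, Size.SMALL]
    else:
        block_sizes = [Size.SMALL, Size.BIG, Size.SMALL, Size.BIG]

    trials: list[TrialCondition] = []
    for b in range(1, N_BLOCKS + 1):
        giver, receiver = (p_a, p_b) if b <= 2 else (p_b, p_a)
        pool = [w for w in Weight for _ in range(REPS_PER_WEIGHT_PER_BLOCK)]
        rng = np.random.default_rng(np.random.SeedSequence((seed, b)))
        weights = [pool[j] for j in rng.permutation(len(pool))]
        for i, w in enumerate(weights, start=1):
            trials.append(
                TrialCondition(
                    dyad_id=dyad_id,
                    block=b,
                    trial_in_block=i,
                    giver_id=giver,
                    receiver_id=receiver,
                    size=block_sizes[b - 1],
                    weight=Weight(w),
                )
            )
    return ExperimentSchedule(dyad_id=dyad_id, trials=tuple(trials))
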