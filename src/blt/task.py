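"""Trial-schedule generation and contingency-space coding for the Breathing
Learning Task (BLT).

The BLT is a probabilistic cue-outcome associative learning task: on each
trial one of two visual cues is shown and an inspiratory breathing resistance
is either delivered (``resistance = 1``) or not (``resistance = 0``).  One cue
predicts resistance with probability ``p_high`` (0.8 by default) and the other
with ``1 - p_high``; the cue-to-probability pairing reverses a number of times
during the session.  Because the two cue contingencies are coupled, every
trial can be recoded onto a single "contingency space" axis ``o``:

    o = 1  iff  (cue 1 was followed by resistance) or (cue 2 by no resistance)

so that a single prediction trajectory suffices for modelling.  The stimulus
valence ``s`` (1 = resistance, the aversive stimulus) is kept alongside ``o``
for the dual-learning-rate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialSchedule",
    "build_schedule",
    "to_contingency_outcome",
    "to_contingency_prediction",
    "DEFAULT_BLOCK_LENGTHS",
]

#: Default reversal-block partition: 30 trials at the initial pairing, then
#: four reversals at 12-13 trial intervals, 80 trials in total.
DEFAULT_BLOCK_LENGTHS: tuple[int, ...] = (30, 13, 12, 13, 12)


class ScheduleError(ValueError):
    """Raised when a schedule specification is internally inconsistent."""


@dataclass(frozen=True)
class TrialSchedule:
    """A realised BLT trial sequence.

    Attributes
    ----------
    n_trials : int
        Session length (80 in the standard task).
    cue : ndarray of int
        Per-trial cue label in {1, 2}.
    resistance : ndarray of int
        Per-trial stimulus in {0, 1}; 1 means resistance delivered.
    block_id : ndarray of int
        0-based reversal-block index per trial.
    o : ndarray of int
        Contingency-space outcome per trial.
    s : ndarray of int
        Stimulus valence per trial (equal to ``resistance``).
    p_high : float
        Dominant cue-outcome contingency.
    block_lengths : tuple of int
        Trials per reversal block; sums to ``n_trials``.
    realization : str
        ``"exact_proportion"`` or ``"bernoulli"``.
    seed : int
        Seed used to realise the sequence.
    """

    n_trials: int
    cue: np.ndarray
    resistance: np.ndarray
    block_id: np.ndarray
    o: np.ndarray
    s: np.ndarray
    p_high: float
    block_lengths: tuple[int, ...]
    realization: str = "exact_proportion"
    seed: int = 0
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if sum(self.block_lengths) != self.n_trials:
            raise ScheduleError(
                f"block_lengths {self.block_lengths} sum to "
                f"{sum(self.block_lengths)}, expected n_trials={self.n_trials}"
            )
        expected_o = to_contingency_outcome(self.cue, self.resistance)
        if not np.array_equal(expected_o, self.o):
            raise ScheduleError("o is inconsistent with (cue, resistance)")
        if not np.array_equal(self.s, self.resistance):
            raise ScheduleError("s must equal resistance")

    @property
    def n_blocks(self) -> int:
        return len(self.block_lengths)

    @property
    def n_reversals(self) -> int:
        return len(self.block_lengths) - 1

    def to_frame(self) -> pd.DataFrame:
        """Schedule as a tidy table (1-based trial index, as in task files)."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "cue": self.cue,
                "resistance": self.resistance,
                "block_id": self.block_id,
                "o": self.o,
                "s": self.s,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        p_high: float = 0.8,
        realization: str = "unknown",
        seed: int = -1,
    ) -> "TrialSchedule":
        cue = frame["cue"].to_numpy(dtype=int)
        resistance = frame["resistance"].to_numpy(dtype=int)
        block_id = frame["block_id"].to_numpy(dtype=int)
        block_lengths = tuple(
            int(np.sum(block_id == b)) for b in range(int(block_id.max()) + 1)
        )
        return cls(
            n_trials=len(frame),
            cue=cue,
            resistance=resistance,
            block_id=block_id,
            o=to_contingency_outcome(cue, resistance),
            s=resistance.copy(),
            p_high=p_high,
            block_lengths=block_lengths,
            realization=realization,
            seed=seed,
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TrialSchedule":
        return cls.from_frame(pd.read_csv(path), **kwargs)


def to_contingency_outcome(cue, resistance):
    """Map a (cue, resistance) event onto the contingency-space axis.

    Returns 1 iff cue 1 was paired with resistance or cue 2 with no
    resistance; the reversed pairings return 0.  Accepts scalars or arrays.
    """
    cue = np.asarray(cue)
    resistance = np.asarray(resistance)
    if not np.isin(cue, (1, 2)).all():
        raise ValueError(f"cue labels must be 1 or 2, got {np.unique(cue)}")
    if not np.isin(resistance, (0, 1)).all():
        raise ValueError("resistance must be 0 or 1")
    out = np.where(cue == 1, resistance, 1 - resistance)
    return out.item() if out.ndim == 0 else out


def to_contingency_prediction(cue, y):
    """Map a cue-referenced prediction (P(resistance | cue)) into contingency
    space (P(o = 1)): identity for cue 1, reflection ``1 - y`` for cue 2.

    Missing responses (NaN) pass through unchanged.
    """
    cue = np.asarray(cue)
    y = np.asarray(y, dtype=float)
    if not np.isin(cue, (1, 2)).all():
        raise ValueError(f"cue labels must be 1 or 2, got {np.unique(cue)}")
    finite = np.isfinite(y)
    if np.any((y[finite] < 0) | (y[finite] > 1)):
        raise ValueError("predictions must lie in [0, 1]")
    out = np.where(cue == 1, y, 1.0 - y)
    return out.item() if out.ndim == 0 else out


def build_schedule(
    n_trials: int = 80,
    block_lengths=DEFAULT_BLOCK_LENGTHS,
    p_high: float = 0.8,
    realization: str = "exact_proportion",
    seed: int = 0,
) -> TrialSchedule:
    """Generate a BLT trial schedule.

    Cues are balanced within each block (as near as possible to equal counts)
    and presented in uniformly random order.  Within block ``b`` the dominant
    contingency-space outcome alternates: P(o = 1) equals ``p_high`` in even
    blocks and ``1 - p_high`` in odd blocks, which realises the reversals of
    the cue-to-resistance pairing.

    Parameters
    ----------
    realization : str
        ``"exact_proportion"`` fixes the count of o = 1 trials per block at
        ``round(P(o=1) * block_length)``, so contingency frequencies are
        identical across seeds; ``"bernoulli"`` draws each trial
        independently.
    """
    block_lengths = tuple(int(b) for b in block_lengths)
    if sum(block_lengths) != n_trials:
        raise ScheduleError(
            f"block_lengths sum to {sum(block_lengths)}, expected {n_trials}"
        )
    if any(b <= 0 for b in block_lengths):
        raise ScheduleError("block lengths must be positive")
    if not 0.5 < p_high <= 1.0:
        raise ValueError(f"p_high must lie in (0.5, 1.0], got {p_high}")
    if realization not in ("exact_proportion", "bernoulli"):
        raise ValueError(f"unknown realization {realization!r}")

    rng = np.random.default_rng(seed)
    cue_parts, o_parts, block_parts = [], [], []
    for b, length in enumerate(block_lengths):
        # balanced cue sequence; the extra cue of odd-length blocks is random
        n1 = length // 2 + (rng.integers(2) if length % 2 else 0)
        cues = np.array([1] * n1 + [2] * (length - n1))
        rng.shuffle(cues)

        p_block = p_high if b % 2 == 0 else 1.0 - p_high
        if realization == "exact_proportion":
            k = int(np.floor(p_block * length + 0.5))
            o_block = np.zeros(length, dtype=int)
            o_block[rng.choice(length, size=k, replace=False)] = 1
        else:
            o_block = (rng.random(length) < p_block).astype(int)

        cue_parts.append(cues)
        o_parts.append(o_block)
        block_parts.append(np.full(length, b))

    cue = np.concatenate(cue_parts)
    o = np.concatenate(o_parts)
    block_id = np.concatenate(block_parts)
    # invert the contingency coding to get the physical stimulus sequence
    resistance = np.where(cue == 1, o, 1 - o)

    return TrialSchedule(
        n_trials=n_trials,
        cue=cue,
        resistance=resistance,
        block_id=block_id,
        o=o,
        s=resistance.copy(),
        p_high=p_high,
        block_lengths=block_lengths,
        realization=realization,
        seed=seed,
    )
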