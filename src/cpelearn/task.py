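"""Synthetic experimental designs for the instrumental-conditioning task.

The task is a block-structured two-alternative value-learning paradigm.  In
every block a learner faces 5 new conditioned stimuli (CS) whose mean monetary
values are drawn from 4 distinct levels (one level is shared by two CS).
Each block has 27 trials split into three phases: an initial training phase
with trial-wise reward feedback (phase 1, length 9/12/15/18), a critical
no-feedback phase (phase 2, length 5/10/15, omitted in two control blocks),
and a final feedback phase (phase 3) filling the block to 27 trials.
Rewards are scratch-card payouts: integer euro amounts from a normal
distribution (SD 10) truncated to the 0-50 range of a 50-field card.

Everything here is deterministic given a seed, so a design can be regenerated
bit-for-bit from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "DesignConfig",
    "BlockParams",
    "BlockDesign",
    "ExperimentDesign",
    "TrialRecord",
    "generate_experiment_design",
    "generate_block_design",
    "build_pair_schedule",
    "draw_reward",
    "draw_rewards",
]


@dataclass(frozen=True)
class DesignConfig:
    """Configuration of the task design generator.

    Defaults reproduce the study conditions: 11 blocks of 27 trials, 5 CS on
    4 value levels, 2 control blocks without a no-feedback phase, block mean
    levels of 18/23/28 euros and CS spacing ("difficulty") of 3 or 6 euros.
    """

    n_blocks: int = 11
    n_control_blocks: int = 2
    trials_per_block: int = 27
    n_cs: int = 5
    phase1_lengths: tuple[int, ...] = (9, 12, 15, 18)
    phase2_lengths: tuple[int, ...] = (5, 10, 15)
    mean_levels: tuple[float, ...] = (18.0, 23.0, 28.0)
    difficulties: tuple[float, ...] = (3.0, 6.0)
    reward_sd: float = 10.0
    reward_bounds: tuple[float, float] = (0.0, 50.0)
    #: "adjacent": adjacent CS levels differ by exactly `difficulty` euros;
    #: "mean_pairwise": the *average pairwise* level difference equals it.
    spacing_mode: str = "adjacent"

    def __post_init__(self) -> None:
        if self.n_control_blocks > self.n_blocks:
            raise ValueError(
                f"n_control_blocks ({self.n_control_blocks}) cannot exceed "
                f"n_blocks ({self.n_blocks})"
            )
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_cs < 2:
            raise ValueError("need at least 2 CS per block")
        if self.spacing_mode not in ("adjacent", "mean_pairwise"):
            raise ValueError(f"unknown spacing_mode: {self.spacing_mode!r}")
        for n1 in self.phase1_lengths:
            if n1 >= self.trials_per_block:
                raise ValueError("phase-1 length must leave room for phase 3")
        for n2 in self.phase2_lengths:
            if n2 <= 0:
                raise ValueError("phase2_lengths are the non-control lengths (> 0)")


@dataclass(frozen=True)
class BlockParams:
    """Condition assignment for a single block (before randomization)."""

    block_index: int
    mean_level: float
    difficulty: float
    stimulus_type: int
    n1: int
    n2: int


@dataclass
class BlockDesign:
    """One block: CS values, phase lengths and the trial pair schedule."""

    block_index: int
    stimulus_type: int
    cs_ids: tuple[int, ...]
    cs_means: tuple[float, ...]
    mean_level: float
    difficulty: float
    n1: int
    n2: int
    n3: int
    pair_schedule: list[tuple[int, int]]

    @property
    def n_trials(self) -> int:
        return self.n1 + self.n2 + self.n3

    def phase_of_trial(self, t: int) -> int:
        """Phase (1, 2 or 3) of 0-based within-block trial index ``t``."""
        if t < 0 or t >= self.n_trials:
            raise IndexError(f"trial index {t} outside block of {self.n_trials}")
        if t < self.n1:
            return 1
        if t < self.n1 + self.n2:
            return 2
        return 3

    @property
    def value_levels(self) -> tuple[float, ...]:
        """The distinct CS mean values of this block, ascending."""
        return tuple(sorted(set(self.cs_means)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pair_schedule"] = [list(p) for p in self.pair_schedule]
        return d


@dataclass
class ExperimentDesign:
    """A full multi-block experiment design plus the seed that produced it."""

    blocks: list[BlockDesign]
    seed: int
    config: DesignConfig = field(default_factory=DesignConfig)

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "blocks": [b.to_dict() for b in self.blocks],
        }

    def to_json(self, path=None) -> Optional[str]:
        """Serialize to JSON; write to ``path`` if given, else return a string."""
        text = json.dumps(self.to_dict(), indent=2)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        cfg_d = dict(d["config"])
        for key in ("phase1_lengths", "phase2_lengths", "mean_levels",
                    "difficulties", "reward_bounds"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = DesignConfig(**cfg_d)
        blocks = []
        for bd in d["blocks"]:
            bd = dict(bd)
            bd["cs_ids"] = tuple(bd["cs_ids"])
            bd["cs_means"] = tuple(bd["cs_means"])
            bd["pair_schedule"] = [tuple(p) for p in bd["pair_schedule"]]
            blocks.append(BlockDesign(**bd))
        return cls(blocks=blocks, seed=d["seed"], config=cfg)


@dataclass
class TrialRecord:
    """One observed (or simulated) trial.

    ``confidence`` is the normalized 0-1 rating (raw rating / 10).  ``correct``
    is None when the two CS share a mean value, else True iff the chosen CS
    has the higher mean.  The reward exists on every trial but is *observed*
    by the learner only in the feedback phases 1 and 3.
    """

    subject_id: str
    block_index: int
    trial_index: int
    phase: int
    left_cs: int
    right_cs: int
    left_value: float
    right_value: float
    chosen_side: str  # "left" | "right"
    chosen_cs: int
    reward: float
    reward_observed: bool
    confidence_raw: float
    confidence: float
    correct: Optional[bool]

    def __post_init__(self) -> None:
        if self.chosen_side not in ("left", "right"):
            raise ValueError(f"chosen_side must be 'left' or 'right', got {self.chosen_side!r}")
        if not 0.0 <= self.confidence_raw <= 10.0:
            raise ValueError(f"confidence_raw {self.confidence_raw} outside [0, 10]")
        if abs(self.confidence - self.confidence_raw / 10.0) > 1e-9:
            raise ValueError("confidence must equal confidence_raw / 10")

    @property
    def chosen_value(self) -> float:
        return self.left_value if self.chosen_side == "left" else self.right_value


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _cs_level_values(mean_level: float, difficulty: float, mode: str) -> np.ndarray:
    """Four equally spaced CS value levels centered on the block mean level."""
    if mode == "adjacent":
        spacing = difficulty
    else:  # mean pairwise |difference| of 4 equispaced levels is spacing * 10/6
        spacing = difficulty * 6.0 / 10.0
    return mean_level + spacing * np.array([-1.5, -0.5, 0.5, 1.5])


def _cycled_assignment(levels: Sequence, n: int, rng: np.random.Generator) -> list:
    """Assign ``n`` slots to factor levels as evenly as possible, shuffled."""
    reps = -(-n // len(levels))  # ceil
    pool = (list(levels) * reps)[:n]
    rng.shuffle(pool)
    return pool


def build_pair_schedule(
    cs_ids: Sequence[int],
    n1: int,
    n2: int,
    n3: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Ordered (left, right) CS pairs for one block, balanced within phase.

    Within each phase every CS appears a near-equal number of times (the
    max-min appearance count never exceeds 2); no CS is paired with itself;
    left/right placement is randomized.
    """
    cs_ids = list(cs_ids)
    if len(cs_ids) < 2:
        raise ValueError("need at least 2 CS to build a pair schedule")
    schedule: list[tuple[int, int]] = []
    for n_phase in (n1, n2, n3):
        counts = {c: 0 for c in cs_ids}
        for _ in range(n_phase):
            # pick the two least-used CS, random among ties
            jitter = rng.random(len(cs_ids))
            order = sorted(cs_ids, key=lambda c: (counts[c], jitter[cs_ids.index(c)]))
            a, b = order[0], order[1]
            counts[a] += 1
            counts[b] += 1
            pair = (a, b) if rng.random() < 0.5 else (b, a)
            schedule.append(pair)
    return schedule


def generate_block_design(
    block_params: BlockParams,
    seed_or_rng,
    config: Optional[DesignConfig] = None,
) -> BlockDesign:
    """Build one block's CS values and pair schedule from a condition assignment."""
    config = config or DesignConfig()
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    p = block_params
    if p.n1 + p.n2 > config.trials_per_block:
        raise ValueError(
            f"n1 + n2 = {p.n1 + p.n2} exceeds the {config.trials_per_block}-trial block"
        )
    n3 = config.trials_per_block - p.n1 - p.n2
    levels = _cs_level_values(p.mean_level, p.difficulty, config.spacing_mode)
    # one of the four levels is shared by two CS ("randomly assigned")
    dup = rng.integers(len(levels))
    means = np.concatenate([levels, [levels[dup]]])
    rng.shuffle(means)
    cs_ids = tuple(range(config.n_cs))
    schedule = build_pair_schedule(cs_ids, p.n1, p.n2, n3, rng)
    return BlockDesign(
        block_index=p.block_index,
        stimulus_type=p.stimulus_type,
        cs_ids=cs_ids,
        cs_means=tuple(float(m) for m in means),
        mean_level=p.mean_level,
        difficulty=p.difficulty,
        n1=p.n1,
        n2=p.n2,
        n3=n3,
        pair_schedule=schedule,
    )


def generate_experiment_design(
    config: Optional[DesignConfig] = None,
    seed: int = 0,
) -> ExperimentDesign:
    """Generate a complete seeded experiment design.

    Condition factors (mean level, difficulty, stimulus type, phase lengths)
    are distributed across blocks as evenly as the block count allows, by
    cycling each factor's levels and shuffling the assignment (the factorial
    design has more cells than blocks, so a balanced subset is drawn
    pseudo-randomly).  Exactly ``n_control_blocks`` blocks omit phase 2.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(seed)
    n = config.n_blocks

    mean_levels = _cycled_assignment(config.mean_levels, n, rng)
    difficulties = _cycled_assignment(config.difficulties, n, rng)
    n1s = _cycled_assignment(config.phase1_lengths, n, rng)
    # stimulus types split half/half; the odd block (if any) falls by seed
    stim = _cycled_assignment((0, 1), n, rng)
    # phase-2 lengths: the control blocks get 0; the rest are filled as
    # evenly as feasibility allows (a long phase 2 fits only after a short
    # phase 1, since phase 3 needs at least one trial), assigning the most
    # constrained blocks first
    cap = config.trials_per_block - 1
    n2_pool = [0] * n
    control_idx = set(rng.choice(n, size=config.n_control_blocks, replace=False).tolist())
    counts = {v: 0 for v in config.phase2_lengths}
    open_idx = [i for i in range(n) if i not in control_idx]
    allowed = {
        i: [v for v in config.phase2_lengths if n1s[i] + v <= cap]
        for i in open_idx
    }
    for i in open_idx:
        if not allowed[i]:
            raise ValueError(
                f"no phase-2 length fits after a phase 1 of {n1s[i]} trials"
            )
    jitter = rng.random(n)
    for i in sorted(open_idx, key=lambda i: (len(allowed[i]), jitter[i])):
        min_count = min(counts[v] for v in allowed[i])
        options = [v for v in allowed[i] if counts[v] == min_count]
        pick = int(options[rng.integers(len(options))])
        n2_pool[i] = pick
        counts[pick] += 1

    blocks = []
    for i in range(n):
        params = BlockParams(
            block_index=i,
            mean_level=mean_levels[i],
            difficulty=difficulties[i],
            stimulus_type=stim[i],
            n1=n1s[i],
            n2=n2_pool[i],
        )
        blocks.append(generate_block_design(params, rng, config))
    return ExperimentDesign(blocks=blocks, seed=seed, config=config)


# ---------------------------------------------------------------------------
# Rewards
# ---------------------------------------------------------------------------

def draw_rewards(
    cs_mean: float,
    rng: np.random.Generator,
    size: int = 1,
    sd: float = 10.0,
    bounds: tuple[float, float] = (0.0, 50.0),
) -> np.ndarray:
    """Draw integer-euro scratch-card rewards for a CS.

    Values come from a normal distribution with the CS mean and the given SD,
    truncated to ``bounds`` (the card has 50 one-euro fields) and rounded to
    whole euros.
    """
    lo, hi = bounds
    if not lo < cs_mean < hi:
        raise ValueError(f"cs_mean {cs_mean} outside the open interval ({lo}, {hi})")
    # exact inverse-CDF sampling of the truncated normal (cheap per draw)
    u_lo = ndtr((lo - cs_mean) / sd)
    u_hi = ndtr((hi - cs_mean) / sd)
    draws = cs_mean + sd * ndtri(rng.uniform(u_lo, u_hi, size))
    return np.rint(np.clip(draws, lo, hi))


def draw_reward(cs_mean: float, rng: np.random.Generator, **kwargs) -> float:
    """Single reward draw; see :func:`draw_rewards`."""
    return float(draw_rewards(cs_mean, rng, size=1, **kwargs)[0])
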