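"""Forward simulation of synthetic subjects and latent-variable time courses.

A simulated subject plays the full task under one generative model: on each
trial the choice is sampled from the model's choice probability, the reported
confidence is the deterministic model confidence ``2 * (p_chosen - 0.5)``
(clipped at zero when the sampled choice went against the model's
preference), and a scratch-card reward is drawn for the chosen CS on every
trial but observed by the learner only in the feedback phases.  Latent
variables (expected values, expected confidence, confidence prediction
errors, choice probabilities) are logged before each trial's update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    LearnerState,
    ParameterSet,
    TrialContext,
    TrialObservation,
    choice_probability,
    step_trial,
)
from .task import (
    DesignConfig,
    ExperimentDesign,
    TrialRecord,
    draw_reward,
    generate_experiment_design,
)

__all__ = [
    "SimulatedSubject",
    "model_confidence",
    "simulate_subject",
    "simulate_cohort",
    "replay_latents",
    "latent_timecourses",
]


def model_confidence(p_chosen: float) -> float:
    """Choice-probability-derived confidence, ``max(0, 2 * (p_chosen - 0.5))``.

    Maps the chosen option's probability to the normalized 0-1 confidence
    scale: 0.5 (guessing) -> 0, 1.0 (certainty) -> 1.  Choices sampled
    against the model's preference (p_chosen < 0.5) map to 0.
    """
    return max(0.0, 2.0 * (p_chosen - 0.5))


LATENT_COLUMNS = [
    "subject", "block", "trial", "phase", "n1", "chosen_cs", "chosen_value",
    "p_right", "p_chosen", "p_correct", "model_confidence", "c_bar", "delta_c",
]


@dataclass
class SimulatedSubject:
    """A full synthetic subject: trials plus per-trial latent snapshots."""

    subject_id: str
    model_kind: str
    true_params: ParameterSet
    design: ExperimentDesign
    trials: list[TrialRecord]
    latents: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Trial records as a tidy table (one row per trial)."""
        from .io import trials_to_frame

        return trials_to_frame(self.trials)


def _p_correct(p_right: float, left_mean: float, right_mean: float) -> float:
    """Probability the model assigns to the objectively better CS (NaN if tied)."""
    if right_mean > left_mean:
        return p_right
    if left_mean > right_mean:
        return 1.0 - p_right
    return np.nan


def _correct_flag(chosen_mean: float, other_mean: float):
    if chosen_mean == other_mean:
        return None
    return chosen_mean > other_mean


def simulate_subject(
    model_kind: str,
    params: ParameterSet,
    design: ExperimentDesign,
    seed,
    subject_id: str = "s000",
    discretize_confidence: bool = False,
) -> SimulatedSubject:
    """Simulate one subject on a given design; reproducible by seed.

    ``discretize_confidence`` snaps the reported confidence to the 11-point
    0-10 rating scale (off by default: the generative confidence is the
    continuous model confidence).
    """
    if params.model_kind != model_kind:
        raise ValueError("parameter set does not match model kind")
    rng = np.random.default_rng(seed)
    cfg = design.config
    trials: list[TrialRecord] = []
    lat_rows = []
    v_snap_rows = []

    for block in design.blocks:
        state = LearnerState.initial(cfg.n_cs)
        for t, (left, right) in enumerate(block.pair_schedule):
            phase = block.phase_of_trial(t)
            ctx = TrialContext(phase=phase, left_cs=left, right_cs=right,
                               mode="generative")
            p_right = choice_probability(model_kind, params, state, ctx)
            take_right = rng.random() < p_right
            chosen = right if take_right else left
            p_chosen = p_right if take_right else 1.0 - p_right
            conf = model_confidence(p_chosen)
            if discretize_confidence:
                conf = round(conf * 10.0) / 10.0
            chosen_mean = block.cs_means[chosen]
            other_mean = block.cs_means[left if take_right else right]
            reward = draw_reward(chosen_mean, rng, sd=cfg.reward_sd,
                                 bounds=cfg.reward_bounds)
            observed = phase != 2

            # latent snapshot before this trial's updates
            c_bar = (state.c_cs[chosen] if model_kind == "ConfSpec"
                     else state.c_global)
            v_snap_rows.append(state.v.copy())
            lat_rows.append((
                subject_id, block.block_index, t, phase, block.n1, chosen,
                chosen_mean, p_right, p_chosen,
                _p_correct(p_right, block.cs_means[left], block.cs_means[right]),
                conf, c_bar, np.nan,
            ))

            obs = TrialObservation(
                chosen_cs=chosen,
                reward=reward if observed else None,
                reward_observed=observed,
                confidence=conf,
            )
            state, info = step_trial(model_kind, params, state, ctx, obs)
            if info.delta_c is not None:
                lat_rows[-1] = lat_rows[-1][:-1] + (info.delta_c,)

            trials.append(TrialRecord(
                subject_id=subject_id,
                block_index=block.block_index,
                trial_index=t,
                phase=phase,
                left_cs=left,
                right_cs=right,
                left_value=block.cs_means[left],
                right_value=block.cs_means[right],
                chosen_side="right" if take_right else "left",
                chosen_cs=chosen,
                reward=reward,
                reward_observed=observed,
                confidence_raw=conf * 10.0,
                confidence=conf,
                correct=_correct_flag(chosen_mean, other_mean),
            ))

    latents = pd.DataFrame(lat_rows, columns=LATENT_COLUMNS)
    v_snap = pd.DataFrame(
        np.asarray(v_snap_rows), columns=[f"v{i}" for i in range(cfg.n_cs)]
    )
    latents = pd.concat([latents, v_snap], axis=1)
    return SimulatedSubject(
        subject_id=subject_id,
        model_kind=model_kind,
        true_params=params,
        design=design,
        trials=trials,
        latents=latents,
    )


def simulate_cohort(
    model_kind: str,
    params: ParameterSet,
    n_subjects: int,
    design_config: DesignConfig | None = None,
    seed=0,
) -> list[SimulatedSubject]:
    """Simulate independent subjects, each on a freshly generated design.

    Per-subject seeds (for both the design and the behavior) are derived
    from the master seed, so the whole cohort is reproducible.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    design_config = design_config or DesignConfig()
    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    subjects = []
    for i, child in enumerate(master.spawn(n_subjects)):
        words = child.generate_state(2)
        design = generate_experiment_design(design_config, seed=int(words[0] % 2**31))
        subjects.append(simulate_subject(
            model_kind, params, design, seed=int(words[1] % 2**31),
            subject_id=f"s{i:03d}",
        ))
    return subjects


def replay_latents(
    model_kind: str,
    params: ParameterSet,
    trials: pd.DataFrame,
    design: ExperimentDesign | None = None,
    n_cs: int = 5,
) -> pd.DataFrame:
    """Run a model in fitting mode over an observed trial table, logging the
    per-trial latent variables (posterior-predictive time courses).

    State resets at every block start; reward updates use the observed
    choices and rewards, no-feedback updates target the model-predicted CS,
    and confidence updates use the reported confidence.
    """
    rows = []
    v_rows = []
    for subject, sdf in trials.groupby("subject", sort=False):
        for block, bdf in sdf.groupby("block", sort=False):
            state = LearnerState.initial(n_cs)
            n1 = int((bdf["phase"] == 1).sum())
            for row in bdf.itertuples(index=False):
                ctx = TrialContext(phase=int(row.phase), left_cs=int(row.left_cs),
                                   right_cs=int(row.right_cs), mode="fitting")
                chosen = int(row.chosen_cs)
                observed = row.phase != 2
                obs = TrialObservation(
                    chosen_cs=chosen,
                    reward=float(row.reward) if observed else None,
                    reward_observed=observed,
                    confidence=float(row.confidence),
                )
                p_right = choice_probability(model_kind, params, state, ctx)
                p_chosen = p_right if chosen == row.right_cs else 1.0 - p_right
                c_bar = (state.c_cs[chosen] if model_kind == "ConfSpec"
                         else state.c_global)
                v_rows.append(state.v.copy())
                chosen_value = (row.right_value if chosen == row.right_cs
                                else row.left_value)
                new_state, info = step_trial(model_kind, params, state, ctx, obs)
                rows.append((
                    subject, block, int(row.trial), int(row.phase), n1, chosen,
                    chosen_value, p_right, p_chosen,
                    _p_correct(p_right, row.left_value, row.right_value),
                    model_confidence(p_chosen), c_bar,
                    info.delta_c if info.delta_c is not None else np.nan,
                ))
                state = new_state
    latents = pd.DataFrame(rows, columns=LATENT_COLUMNS)
    v_snap = pd.DataFrame(np.asarray(v_rows),
                          columns=[f"v{i}" for i in range(n_cs)])
    return pd.concat([latents, v_snap], axis=1)


def latent_timecourses(subjects: list[SimulatedSubject]) -> dict[str, pd.DataFrame]:
    """Average latent trajectories aligned to phase-2 onset.

    Returns two frames: ``"values"`` holds the mean expected value per CS
    value rank (0 = lowest of the block's 4 levels), and ``"scalars"`` the
    mean model performance, model confidence, expected confidence, and
    (absolute) confidence prediction error, each per phase-1 duration and
    aligned trial index (trial - n1, so phase 2 starts at 0).  Averages are
    taken across blocks and subjects.
    """
    if not subjects:
        raise ValueError("need at least one simulated subject")
    value_rows = []
    scalar_frames = []
    for subj in subjects:
        lat = subj.latents.copy()
        lat["t_aligned"] = lat["trial"] - lat["n1"]
        lat["abs_delta_c"] = lat["delta_c"].abs()
        scalar_frames.append(lat[[
            "n1", "t_aligned", "p_correct", "model_confidence",
            "c_bar", "delta_c", "abs_delta_c",
        ]])
        for block in subj.design.blocks:
            levels = sorted(set(block.cs_means))
            rank = {m: i for i, m in enumerate(levels)}
            blat = lat[lat["block"] == block.block_index]
            v_cols = [f"v{i}" for i in range(len(block.cs_means))]
            for cs, mean in enumerate(block.cs_means):
                value_rows.append(pd.DataFrame({
                    "n1": blat["n1"].to_numpy(),
                    "t_aligned": blat["t_aligned"].to_numpy(),
                    "value_rank": rank[mean],
                    "v": blat[v_cols[cs]].to_numpy(),
                }))
    values = (
        pd.concat(value_rows)
        .groupby(["n1", "value_rank", "t_aligned"], as_index=False)["v"]
        .mean()
    )
    scalars = (
        pd.concat(scalar_frames)
        .groupby(["n1", "t_aligned"], as_index=False)
        .mean()
    )
    return {"values": values, "scalars": scalars}
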