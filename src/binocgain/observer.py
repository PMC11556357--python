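"""Synthetic 2IFC observers and experiment generators.

Simulates the three study designs as tidy trial tables:

- Experiment 1: contrast discrimination dippers for three pathways
  (achromatic gratings, L-M, S-(L+M)), four ocular arrangements x two
  target eyes run as eight interleaved 3-down-1-up staircases per block,
  one block per pedestal, three repetitions per participant.
- Experiment 2: dichoptic masking by method of constant stimuli; 12
  conditions (3 baselines + 9 target x mask pairings), 10 target levels,
  200-trial blocks, 10 repetitions, masks at ~16x monocular threshold.
- Experiment 3: the achromatic design of Experiment 1 with flickering
  disc parameters (the model itself does not distinguish flicker from
  gratings; the stimulus type is a condition label).

Per-trial percent correct comes from the generating model's d-prime via
the standard 2AFC link.  Participant heterogeneity is log-normal jitter
on (m, omega, k) around the group parameter values — the structure the
hierarchical fit assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .gain_model import (
    GainParams,
    OcularArrangement,
    PUBLISHED_PARAMS,
    SolverError,
    dprime,
    dprime_to_pc,
    solve_threshold,
)
from .crosspath import (
    PATHWAYS,
    CrossPathState,
    MaskingCondition,
    crosspath_dprime,
    masked_threshold,
)

__all__ = [
    "TRIAL_COLUMNS",
    "StaircaseConfig",
    "ParticipantSpec",
    "simulate_trial",
    "run_staircase",
    "jitter_params",
    "generate_experiment1",
    "generate_experiment2",
    "generate_experiment3",
    "write_trials",
    "read_trials",
    "aggregate_level_counts",
]

#: Exact CSV column order of the trial table.
TRIAL_COLUMNS = [
    "participant",
    "experiment",
    "pathway_target",
    "pathway_mask",
    "arrangement",
    "target_eye",
    "pedestal_norm",
    "target_norm",
    "correct",
    "block",
    "trial_index",
]

#: Default pedestal grids in % contrast (achromatic: Michelson; chromatic:
#: % of maximum displayable cone contrast), converted to normalized units
#: by each pathway's generating monocular threshold.
PEDESTALS_PCT = {
    "AC": (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0),
    "RG": (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0),
    "BY": (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0),
}

#: Default 2AFC lapse rate of the synthetic observer.
DEFAULT_LAPSE = 0.01


@dataclass(frozen=True)
class StaircaseConfig:
    """3-down-1-up transformed staircase in 3 dB logarithmic steps.

    The level drops one step after three consecutive correct responses
    and rises one step after any error; the procedure converges on the
    0.5**(1/3) ~ 79.4%-correct point.  Trials per staircase and the
    start level (dB above the generating threshold) are not dictated by
    the design and default to 50 and +10 dB.
    """

    step_db: float = 3.0
    n_trials: int = 50
    start_above_db: float = 10.0
    n_interleaved: int = 8

    def __post_init__(self) -> None:
        if self.step_db <= 0 or self.n_trials < 1:
            raise ValueError("step_db must be positive and n_trials >= 1")


@dataclass(frozen=True)
class ParticipantSpec:
    """How per-participant parameters deviate from the group values.

    ``jitter_sd`` is the standard deviation, in natural-log units, of
    multiplicative log-normal jitter applied to (m, omega, k).
    """

    n: int = 3
    jitter_sd: float = 0.1
    jittered: tuple[str, ...] = ("m", "omega", "k")


def simulate_trial(pc: float, rng: np.random.Generator) -> bool:
    """One Bernoulli 2IFC trial outcome at success probability ``pc``."""
    if not (0.0 <= pc <= 1.0):
        raise ValueError(f"pc must lie in [0, 1], got {pc}")
    return bool(rng.random() < pc)


def jitter_params(
    params: GainParams, spec: ParticipantSpec, rng: np.random.Generator
) -> GainParams:
    """Draw one participant's parameters around the group values."""
    updates = {
        name: getattr(params, name) * float(np.exp(rng.normal(0.0, spec.jitter_sd)))
        for name in spec.jittered
    }
    return params.replace(**updates)


def run_staircase(
    cfg: StaircaseConfig,
    observer: Callable[[float], float],
    rng: np.random.Generator,
    start_level_db: float = 0.0,
) -> tuple[list[dict], list[float]]:
    """Run one 3-down-1-up staircase.

    ``observer`` maps a level in dB (20*log10 of normalized target
    contrast) to probability correct; it should be non-decreasing in
    level for the procedure to converge (not enforced).  Returns the
    per-trial records (keys: level_db, correct) and the reversal levels.
    """
    level = float(start_level_db)
    trials: list[dict] = []
    reversals: list[float] = []
    run_correct = 0
    direction = 0  # -1 descending, +1 ascending, 0 undetermined
    for _ in range(cfg.n_trials):
        correct = simulate_trial(float(observer(level)), rng)
        trials.append({"level_db": level, "correct": correct})
        move = 0
        if correct:
            run_correct += 1
            if run_correct == 3:
                run_correct = 0
                move = -1
        else:
            run_correct = 0
            move = +1
        if move:
            if direction and move != direction:
                reversals.append(level)
            direction = move
            level += move * cfg.step_db
    return trials, reversals


def _model_observer(
    params: GainParams, arr: OcularArrangement, pedestal: float, lapse: float
) -> Callable[[float], float]:
    """Observer whose percent correct follows the gain-control model."""

    def pc_of_level(level_db: float) -> float:
        target = 10.0 ** (level_db / 20.0)
        return float(dprime_to_pc(dprime(target, pedestal, arr, params), lapse=lapse))

    return pc_of_level


def _participant_params(
    group: GainParams, spec: ParticipantSpec, rng: np.random.Generator
) -> list[GainParams]:
    return [jitter_params(group, spec, rng) for _ in range(spec.n)]


def generate_experiment1(
    params_per_pathway: dict[str, GainParams] | None = None,
    participants: ParticipantSpec = ParticipantSpec(),
    pedestals_pct: dict[str, tuple] | None = None,
    staircase: StaircaseConfig = StaircaseConfig(),
    repetitions: int = 3,
    mono_threshold_pct: float = 1.0,
    lapse: float = DEFAULT_LAPSE,
    rng: np.random.Generator | int = 0,
    experiment_label: str = "exp1",
    pathways: tuple[str, ...] = PATHWAYS,
) -> pd.DataFrame:
    """Simulate the dipper experiment as a trial table.

    Per pathway, pedestal and repetition, eight interleaved staircases
    (4 arrangements x 2 target eyes) are run trial-by-trial in
    round-robin order.  Pedestals in % contrast are converted to
    normalized units using ``mono_threshold_pct`` (the generating
    monocular detection threshold, default 1% contrast).
    """
    rng = np.random.default_rng(rng)
    if params_per_pathway is None:
        params_per_pathway = {
            "AC": PUBLISHED_PARAMS["bayes_achromatic"],
            "RG": PUBLISHED_PARAMS["bayes_lm"],
            "BY": PUBLISHED_PARAMS["bayes_s"],
        }
    if pedestals_pct is None:
        pedestals_pct = {pw: PEDESTALS_PCT[pw] for pw in pathways}

    arrangements = [
        OcularArrangement(tag, eye)
        for tag in ("monocular", "binocular", "half_binocular", "dichoptic")
        for eye in ("left", "right")
    ]
    rows: list[tuple] = []
    for pathway in pathways:
        group = params_per_pathway[pathway]
        per_part = _participant_params(group, participants, rng)
        for part_i, params in enumerate(per_part):
            pid = f"P{part_i + 1}"
            block = 0
            for pedestal_pct in pedestals_pct[pathway]:
                pedestal = pedestal_pct / mono_threshold_pct
                starts = {}
                for arr in arrangements:
                    # Some jittered parameter draws (m < 1 with strong
                    # suppression) saturate before the criterion at high
                    # pedestals, so that observer has no finite
                    # threshold there; start from the group threshold
                    # (or 0 dB) and let the staircase drift.
                    try:
                        thr = solve_threshold(pedestal, arr, params)
                    except SolverError:
                        try:
                            thr = solve_threshold(pedestal, arr, group)
                        except SolverError:
                            thr = 1.0
                    starts[arr] = 20.0 * np.log10(thr) + staircase.start_above_db
                for _rep in range(repetitions):
                    block += 1
                    states = [
                        {
                            "arr": arr,
                            "level": starts[arr],
                            "run": 0,
                            "obs": _model_observer(params, arr, pedestal, lapse),
                        }
                        for arr in arrangements
                    ]
                    trial_index = 0
                    for _t in range(staircase.n_trials):
                        for st in states:
                            trial_index += 1
                            level = st["level"]
                            target = 10.0 ** (level / 20.0)
                            correct = simulate_trial(st["obs"](level), rng)
                            rows.append(
                                (
                                    pid,
                                    experiment_label,
                                    pathway,
                                    "none",
                                    st["arr"].tag,
                                    st["arr"].target_eye,
                                    pedestal,
                                    target,
                                    int(correct),
                                    block,
                                    trial_index,
                                )
                            )
                            if correct:
                                st["run"] += 1
                                if st["run"] == 3:
                                    st["run"] = 0
                                    st["level"] -= staircase.step_db
                            else:
                                st["run"] = 0
                                st["level"] += staircase.step_db
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _exp2_target_levels(
    cond: MaskingCondition, state: CrossPathState, n_levels: int = 10
) -> np.ndarray:
    """Ten target levels straddling the predicted masked threshold.

    Mimics pilot-informed level placement: levels in 3 dB steps from
    -15 dB to +12 dB around the model's predicted 75% point.
    """
    thr_db = 20.0 * np.log10(masked_threshold(cond, state))
    offsets = np.arange(n_levels) * 3.0 - 15.0
    return 10.0 ** ((thr_db + offsets) / 20.0)


def generate_experiment2(
    state: CrossPathState | None = None,
    participants: ParticipantSpec = ParticipantSpec(),
    mask_contrast_norm: float = 16.0,
    trials_per_block: int = 200,
    repetitions: int = 10,
    n_levels: int = 10,
    lapse: float = DEFAULT_LAPSE,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Simulate the dichoptic masking experiment (method of constant stimuli).

    12 conditions — baseline detection for each pathway plus the nine
    factorial target x mask pairings — each run as ``repetitions``
    blocks of ``trials_per_block`` trials spread evenly over
    ``n_levels`` target levels.  Masks sit at ~16x their pathway's
    monocular detection threshold.  Default design: 3 participants x 12
    conditions x 2,000 trials = 72,000 trials.
    """
    rng = np.random.default_rng(rng)
    if state is None:
        state = CrossPathState(
            (
                PUBLISHED_PARAMS["bayes_achromatic"],
                PUBLISHED_PARAMS["bayes_lm"],
                PUBLISHED_PARAMS["bayes_s"],
            )
        )
    if trials_per_block % n_levels:
        raise ValueError("trials_per_block must be a multiple of n_levels")

    conditions: list[MaskingCondition] = [MaskingCondition(pw) for pw in PATHWAYS]
    conditions += [
        MaskingCondition(tgt, msk, mask_contrast_norm)
        for tgt in PATHWAYS
        for msk in PATHWAYS
    ]
    levels = {c: _exp2_target_levels(c, state, n_levels) for c in conditions}

    per_level = trials_per_block // n_levels
    rows: list[tuple] = []
    for part_i in range(participants.n):
        pid = f"P{part_i + 1}"
        # participant-level jitter applied mechanism-wise to (m, omega, k)
        mechs = tuple(jitter_params(m, participants, rng) for m in state.mechs)
        pstate = CrossPathState(mechs, state.weights)
        for cond in conditions:
            dp = np.array([crosspath_dprime(cond, t, pstate) for t in levels[cond]])
            pcs = np.asarray(dprime_to_pc(dp, lapse=lapse))
            for block in range(1, repetitions + 1):
                # each block presents every level per_level times, shuffled
                order = np.repeat(np.arange(n_levels), per_level)
                rng.shuffle(order)
                draws = rng.random(order.size) < pcs[order]
                for ti, (li, corr) in enumerate(zip(order, draws), start=1):
                    rows.append(
                        (
                            pid,
                            "exp2",
                            cond.target_pathway,
                            cond.mask_pathway or "none",
                            "dichoptic_mocs",
                            cond.target_eye,
                            cond.mask_contrast,
                            float(levels[cond][li]),
                            int(corr),
                            block,
                            ti,
                        )
                    )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_experiment3(
    params: GainParams | None = None,
    participants: ParticipantSpec = ParticipantSpec(),
    **kwargs,
) -> pd.DataFrame:
    """Simulate the flickering-disc dipper experiment.

    Identical machinery to the achromatic condition of the dipper
    experiment, with the flickering-disc parameter set as generator.
    """
    if params is None:
        params = PUBLISHED_PARAMS["bayes_disc"]
    return generate_experiment1(
        params_per_pathway={"AC": params},
        participants=participants,
        pathways=("AC",),
        pedestals_pct={"AC": PEDESTALS_PCT["AC"]},
        experiment_label="exp3",
        **kwargs,
    )


def write_trials(trials: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a trial table as CSV plus a JSON provenance sidecar."""
    path = Path(path)
    out = trials[TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False)
    meta = {"n_trials": int(len(out)), "seed": seed, "columns": TRIAL_COLUMNS}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_trials(path) -> pd.DataFrame:
    """Read a trial table CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = df.index[~df["correct"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"non-binary 'correct' values at rows {list(bad[:5])}")
    bad = df.index[~(df["target_norm"] > 0)]
    if len(bad):
        raise ValueError(f"non-positive target contrast at rows {list(bad[:5])}")
    return df[TRIAL_COLUMNS]


def aggregate_level_counts(trials: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Collapse trials to binomial counts per condition cell and target level."""
    if by is None:
        by = [
            "participant",
            "experiment",
            "pathway_target",
            "pathway_mask",
            "arrangement",
            "pedestal_norm",
        ]
    grouped = trials.groupby(by + ["target_norm"], as_index=False).agg(
        n_correct=("correct", "sum"), n_total=("correct", "size")
    )
    return grouped
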