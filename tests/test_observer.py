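"""Tests for the synthetic 2IFC observer, staircases and experiment designs."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from binocgain.gain_model import MEESE_2006, OcularArrangement, solve_threshold
from binocgain.observer import (
    PEDESTALS_PCT,
    TRIAL_COLUMNS,
    ParticipantSpec,
    StaircaseConfig,
    generate_experiment1,
    generate_experiment2,
    generate_experiment3,
    jitter_params,
    read_trials,
    run_staircase,
    simulate_trial,
    write_trials,
)


class TestSimulateTrial:
    def test_certain_success(self, rng):
        assert all(simulate_trial(1.0, rng) for _ in range(100))

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_trial(1.2, rng)

    def test_proportion_matches_probability(self):
        rng = np.random.default_rng(7)
        n = 10_000
        hits = sum(simulate_trial(0.5, rng) for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se

    def test_seed_reproducibility(self):
        seq1 = [simulate_trial(0.6, np.random.default_rng(3)) for _ in range(1)]
        a = np.random.default_rng(3)
        b = np.random.default_rng(3)
        assert [simulate_trial(0.6, a) for _ in range(50)] == [
            simulate_trial(0.6, b) for _ in range(50)
        ]


class TestStaircase:
    def test_perfect_observer_steps_down_every_three_trials(self):
        trials, _ = run_staircase(
            StaircaseConfig(n_trials=9), lambda lvl: 1.0, np.random.default_rng(0)
        )
        assert [t["level_db"] for t in trials] == [0, 0, 0, -3, -3, -3, -6, -6, -6]

    def test_steps_are_exactly_three_db(self):
        obs = lambda lvl: 0.5 + 0.5 * norm.cdf((lvl - 5.0) / 4.0)
        trials, _ = run_staircase(
            StaircaseConfig(n_trials=300), obs, np.random.default_rng(1), 15.0
        )
        levels = np.array([t["level_db"] for t in trials])
        dl = np.diff(levels)
        assert set(np.round(dl[dl != 0], 9)) <= {3.0, -3.0}

    def test_converges_near_79_percent_point(self):
        # 3-down-1-up targets the 0.5**(1/3) ~ 0.794-correct level
        obs = lambda lvl: 0.5 + 0.5 * norm.cdf((lvl - 10.0) / 3.0)
        _, reversals = run_staircase(
            StaircaseConfig(n_trials=4000), obs, np.random.default_rng(3), 20.0
        )
        x794 = 10.0 + 3.0 * norm.ppf((0.5 ** (1 / 3) - 0.5) / 0.5)
        assert np.mean(reversals[2:]) == pytest.approx(x794, abs=1.0)


@pytest.fixture(scope="module")
def small_exp1():
    return generate_experiment1(
        params_per_pathway={"AC": MEESE_2006},
        pathways=("AC",),
        participants=ParticipantSpec(n=2, jitter_sd=0.05),
        staircase=StaircaseConfig(n_trials=10),
        repetitions=3,
        rng=5,
    )


class TestExperiment1:
    def test_pedestal_grid_matches_design(self, small_exp1):
        assert sorted(small_exp1.pedestal_norm.unique()) == [
            0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0,
        ]
        assert sorted(PEDESTALS_PCT["RG"]) == [0, 1, 2, 4, 8, 16, 32, 64]

    def test_eight_interleaved_staircases_per_block(self, small_exp1):
        one_block = small_exp1[
            (small_exp1.participant == "P1")
            & (small_exp1.pedestal_norm == 4.0)
            & (small_exp1.block == small_exp1[small_exp1.pedestal_norm == 4.0].block.min())
        ]
        combos = one_block.groupby(["arrangement", "target_eye"]).size()
        assert len(combos) == 8
        assert (combos == 10).all()

    def test_three_repetitions_per_pedestal(self, small_exp1):
        blocks = small_exp1[small_exp1.participant == "P1"].groupby("pedestal_norm")[
            "block"
        ].nunique()
        assert (blocks == 3).all()

    def test_trial_count_determined_by_design(self, small_exp1):
        # 2 participants x 8 pedestals x 3 reps x 8 staircases x 10 trials
        assert len(small_exp1) == 2 * 8 * 3 * 8 * 10


class TestExperiment2:
    def test_default_design_emits_72000_trials(self):
        df = generate_experiment2(rng=0)
        assert len(df) == 72_000

    def test_mask_contrast_is_16x_threshold(self):
        df = generate_experiment2(rng=0, repetitions=1)
        masked = df[df.pathway_mask != "none"]
        assert (masked.pedestal_norm == 16.0).all()

    def test_600_trials_per_level_pooled(self):
        df = generate_experiment2(rng=0)
        counts = df.groupby(["pathway_target", "pathway_mask", "target_norm"]).size()
        assert (counts == 600).all()

    def test_twelve_conditions(self):
        df = generate_experiment2(rng=0, repetitions=1)
        assert len(df.groupby(["pathway_target", "pathway_mask"])) == 12


class TestExperiment3:
    def test_uses_achromatic_machinery_with_disc_label(self):
        df = generate_experiment3(
            participants=ParticipantSpec(n=1, jitter_sd=0.0),
            staircase=StaircaseConfig(n_trials=5),
            repetitions=1,
            rng=0,
        )
        assert (df.experiment == "exp3").all()
        assert set(df.arrangement.unique()) == {
            "monocular", "binocular", "half_binocular", "dichoptic",
        }


class TestTrialTableIO:
    def test_csv_round_trip_lossless(self, tmp_path):
        df = generate_experiment1(
            params_per_pathway={"AC": MEESE_2006},
            pathways=("AC",),
            participants=ParticipantSpec(n=1, jitter_sd=0.0),
            staircase=StaircaseConfig(n_trials=5),
            repetitions=1,
            rng=9,
        )
        path = tmp_path / "trials.csv"
        write_trials(df, path, seed=9)
        back = read_trials(path)
        assert list(back.columns) == TRIAL_COLUMNS
        pd.testing.assert_frame_equal(back, df.reset_index(drop=True), check_dtype=False)

    def test_schema_violations_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"participant": ["P1"]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_trials(path)

    def test_identical_seed_identical_table(self):
        kw = dict(
            params_per_pathway={"AC": MEESE_2006},
            pathways=("AC",),
            participants=ParticipantSpec(n=1),
            staircase=StaircaseConfig(n_trials=5),
            repetitions=1,
        )
        a = generate_experiment1(rng=42, **kw)
        b = generate_experiment1(rng=42, **kw)
        pd.testing.assert_frame_equal(a, b)


class TestParticipantJitter:
    def test_jitter_only_touches_m_omega_k(self, rng):
        spec = ParticipantSpec(jitter_sd=0.2)
        jit = jitter_params(MEESE_2006, spec, rng)
        assert (jit.p, jit.q, jit.S, jit.Z) == (
            MEESE_2006.p, MEESE_2006.q, MEESE_2006.S, MEESE_2006.Z,
        )
        assert jit.m != MEESE_2006.m

    def test_zero_sd_is_identity(self, rng):
        spec = ParticipantSpec(jitter_sd=0.0)
        jit = jitter_params(MEESE_2006, spec, rng)
        assert jit == MEESE_2006


class TestClosedLoop:
    def test_fitted_thresholds_converge_to_model_thresholds(self):
        """Simulate -> aggregate -> psychometric fit recovers the
        generating model's thresholds within 0.5 dB at large trial
        counts (the simulate/fit loop closes)."""
        from binocgain.pipeline import _staircase_thresholds

        df = generate_experiment1(
            params_per_pathway={"AC": MEESE_2006},
            pathways=("AC",),
            participants=ParticipantSpec(n=3, jitter_sd=0.0),
            staircase=StaircaseConfig(n_trials=120),
            repetitions=5,
            rng=8,
        )
        thr = _staircase_thresholds(df)
        assert len(thr) == 4 * 8
        for _, row in thr.iterrows():
            t_true = solve_threshold(
                row.pedestal_norm, OcularArrangement(row.arrangement), MEESE_2006
            )
            assert abs(row.threshold_dB - 20 * np.log10(t_true)) < 0.5
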