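import dataclasses

import numpy as np
import pandas as pd
import pytest

from dualcontrol.proactive import (
    context_effect,
    label_history,
    post_error_slowing,
    post_error_stop_accuracy_effect,
)
from dualcontrol.simulate import simulate_session
from dualcontrol.trial_data import trials_to_frame


def make_run(spec, task="SST", run=1):
    """spec: list of (trial_type, responded, correct) tuples."""
    rows = []
    for i, (ttype, responded, correct) in enumerate(spec):
        rows.append(
            dict(
                subject_id="s",
                group="TD",
                task=task,
                run=run,
                trial_index=i + 1,
                trial_type=ttype,
                ssd=200.0 if ttype == "stop" else np.nan,
                responded=responded,
                choice_correct=correct if responded else None,
                rt=500.0 if responded else np.nan,
            )
        )
    df = pd.DataFrame(rows)
    df["choice_correct"] = df["choice_correct"].astype("boolean")
    return df


class TestLabelHistory:
    def test_hand_labeled_sequence(self):
        df = make_run(
            [
                ("go", True, True),     # first trial -> other
                ("stop", True, True),   # after successful go -> StopPSG; responded (unsucc)
                ("go", True, True),     # after unsuccessful stop -> GoPUS
                ("go", True, True),     # after successful go -> GoPSG
                ("stop", False, None),  # after successful go -> StopPSG; withheld
                ("go", True, True),     # after withheld stop -> other
            ]
        )
        labels = label_history(df)
        assert list(labels) == ["other", "StopPSG", "GoPUS", "GoPSG", "StopPSG", "other"]

    def test_run_boundary_breaks_history(self):
        run1 = make_run([("go", True, True), ("stop", True, True)], run=1)
        run2 = make_run([("go", True, True), ("go", True, True)], run=2)
        df = pd.concat([run1, run2], ignore_index=True)
        labels = label_history(df)
        # the go opening run 2 follows an unsuccessful stop only across the
        # break, so it stays 'other'
        assert list(labels) == ["other", "StopPSG", "other", "GoPSG"]

    def test_all_correct_go_run(self):
        df = make_run([("go", True, True)] * 5)
        assert list(label_history(df)) == ["other"] + ["GoPSG"] * 4

    def test_every_trial_gets_exactly_one_label(self, sst_trials):
        labels = label_history(sst_trials)
        assert labels.isin(["GoPUS", "GoPSG", "StopPUS", "StopPSG", "other"]).all()
        n_unsucc_stop = (
            (sst_trials.trial_type == "stop") & sst_trials.responded
        ).sum()
        assert (labels == "GoPUS").sum() <= n_unsucc_stop


class TestPostErrorSlowing:
    def test_arithmetic_on_known_means(self):
        df = pd.concat(
            [
                make_run(
                    [
                        ("stop", True, True), ("go", True, True),
                        ("stop", True, True), ("go", True, True),
                        ("stop", True, True), ("go", True, True),
                        ("go", True, True), ("go", True, True), ("go", True, True),
                    ]
                )
            ],
            ignore_index=True,
        )
        labels = label_history(df)
        df.loc[labels == "GoPUS", "rt"] = [500.0, 520.0, 510.0]
        df.loc[labels == "GoPSG", "rt"] = [480.0, 500.0, 490.0]
        pes, flagged = post_error_slowing(df, labels)
        assert not flagged and pes == pytest.approx(20.0)

    def test_identical_rts_give_zero(self):
        df = make_run(
            [("stop", True, True), ("go", True, True)] * 3
            + [("go", True, True)] * 4
        )
        pes, _ = post_error_slowing(df)
        assert pes == pytest.approx(0.0)

    def test_insufficient_trials_flagged(self):
        df = make_run([("go", True, True)] * 6)
        pes, flagged = post_error_slowing(df)
        assert flagged and np.isnan(pes)

    def test_translation_invariance(self, sst_trials):
        labels = label_history(sst_trials)
        pes0, _ = post_error_slowing(sst_trials, labels)
        shifted = sst_trials.copy()
        shifted["rt"] = shifted["rt"] + 250.0
        pes1, _ = post_error_slowing(shifted, labels)
        assert pes1 == pytest.approx(pes0)

    def test_recovers_planted_post_error_cost(self, plain_profile):
        # beta_antic = 0 isolates the post-error term from anticipation
        ests = []
        for seed in range(50):
            prof = dataclasses.replace(plain_profile, subject_id=f"s{seed}", beta_pes=40.0)
            rng = np.random.default_rng(3000 + seed)
            recs = []
            for run in (1, 2):
                recs += simulate_session(prof, "SST", run, rng)
            pes, flagged = post_error_slowing(trials_to_frame(recs))
            if not flagged:
                ests.append(pes)
        assert np.mean(ests) == pytest.approx(40.0, abs=12.0)

    def test_centered_at_zero_without_generative_effects(self, plain_profile):
        ests = []
        for seed in range(40):
            prof = dataclasses.replace(plain_profile, subject_id=f"s{seed}")
            rng = np.random.default_rng(4000 + seed)
            recs = []
            for run in (1, 2):
                recs += simulate_session(prof, "SST", run, rng)
            pes, flagged = post_error_slowing(trials_to_frame(recs))
            if not flagged:
                ests.append(pes)
        assert abs(np.mean(ests)) < 10.0


class TestPostErrorStopAccuracy:
    def test_arithmetic_on_known_rates(self):
        spec = []
        # 4 StopPUS (3 withheld), 2 StopPSG (1 withheld)
        for withhold in (True, True, True, False):
            spec += [("stop", True, True), ("stop", not withhold, True if not withhold else None)]
        for withhold in (True, False):
            spec += [("go", True, True), ("stop", not withhold, True if not withhold else None)]
        df = make_run(spec)
        eff, flagged = post_error_stop_accuracy_effect(df)
        assert not flagged and eff == pytest.approx(0.75 - 0.5)

    def test_positive_in_cohort_with_post_error_slowing(self, plain_profile):
        effs = []
        for seed in range(30):
            prof = dataclasses.replace(plain_profile, subject_id=f"s{seed}", beta_pes=80.0)
            rng = np.random.default_rng(5000 + seed)
            recs = []
            for run in (1, 2):
                recs += simulate_session(prof, "SST", run, rng)
            eff, flagged = post_error_stop_accuracy_effect(trials_to_frame(recs))
            if not flagged:
                effs.append(eff)
        # slowing after errors wins more races -> positive mean effect
        assert np.mean(effs) > 0.0


class TestContextEffect:
    def test_arithmetic_on_known_means(self):
        spec = [("uncertain_go", True, True)] * 5 + [("certain_go", True, True)] * 5
        df = make_run(spec, task="CSST")
        df.loc[df.trial_type == "uncertain_go", "rt"] = 540.0
        df.loc[df.trial_type == "certain_go", "rt"] = 512.0
        eff, flagged = context_effect(df)
        assert not flagged and eff == pytest.approx(28.0)

    def test_equal_means_give_zero(self):
        spec = [("uncertain_go", True, True)] * 5 + [("certain_go", True, True)] * 5
        eff, _ = context_effect(make_run(spec, task="CSST"))
        assert eff == pytest.approx(0.0)

    def test_sst_trials_rejected(self, sst_trials):
        with pytest.raises(ValueError):
            context_effect(sst_trials)

    def test_recovers_planted_context_cost(self, plain_profile):
        ests = []
        for seed in range(50):
            prof = dataclasses.replace(
                plain_profile, subject_id=f"s{seed}", beta_context=30.0
            )
            rng = np.random.default_rng(6000 + seed)
            recs = []
            for run in (1, 2):
                recs += simulate_session(prof, "CSST", run, rng)
            eff, flagged = context_effect(trials_to_frame(recs))
            if not flagged:
                ests.append(eff)
        assert np.mean(ests) == pytest.approx(30.0, abs=10.0)
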