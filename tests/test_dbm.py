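import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualcontrol.dbm import (
    DBMConfig,
    anticipation_correlation,
    calibrate_alpha,
    dbm_forward,
    dbm_forward_batch,
    pstop_per_run,
)


def conjugate_pstop(seq, a, b):
    """Beta-binomial closed form for the non-forgetting limit alpha=1."""
    out, n_stop = [], 0
    for k, s in enumerate(seq):
        out.append((a + n_stop) / (a + b + k))
        n_stop += s
    return np.array(out)


class TestForwardPass:
    def test_alpha_zero_resamples_prior_every_trial(self):
        cfg = DBMConfig(alpha=0.0, pm=1 / 3, scale=2.0, grid_size=1000)
        p, _ = dbm_forward(np.array([1, 0, 1, 1, 0, 0, 1]), cfg)
        assert np.allclose(p, 1 / 3, atol=1e-4)

    def test_first_prediction_is_prior_mean(self):
        cfg = DBMConfig(alpha=0.6, pm=0.25, scale=3.0)
        p, _ = dbm_forward(np.array([1, 0]), cfg)
        assert p[0] == pytest.approx(0.25, abs=1e-4)  # grid tolerance

    def test_uniform_prior_conjugate_sequence(self):
        # alpha=1, Beta(1,1): p after one stop = 2/3, then (after one go) 2/4
        cfg = DBMConfig(alpha=1.0, pm=0.5, scale=2.0, grid_size=2000)
        p, _ = dbm_forward(np.array([1, 0, 0]), cfg)
        assert np.allclose(p, [0.5, 2 / 3, 0.5], atol=1e-6)

    def test_partial_forgetting_worked_value(self):
        # alpha=0.5, uniform prior: after one stop the predictive mean is
        # 0.5 * 2/3 + 0.5 * 1/2 = 7/12
        cfg = DBMConfig(alpha=0.5, pm=0.5, scale=2.0, grid_size=10000)
        p, _ = dbm_forward(np.array([1, 0]), cfg)
        assert p[1] == pytest.approx(7 / 12, abs=1e-6)

    @given(
        pm=st.floats(0.15, 0.85),
        scale=st.floats(0.5, 8.0),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_conjugate_closed_form_at_alpha_one(self, pm, scale, seed):
        cfg = DBMConfig(alpha=1.0, pm=pm, scale=scale, grid_size=4000)
        rng = np.random.default_rng(seed)
        seq = (rng.random(50) < 0.33).astype(int)
        p, _ = dbm_forward(seq, cfg)
        expect = conjugate_pstop(seq, cfg.beta_a, cfg.beta_b)
        assert np.abs(p - expect).max() < 1e-6

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.9])
    def test_grid_refinement_agreement(self, alpha):
        rng = np.random.default_rng(3)
        seq = (rng.random(100) < 0.33).astype(int)
        p_a, _ = dbm_forward(seq, DBMConfig(alpha=alpha, grid_size=1000))
        p_b, _ = dbm_forward(seq, DBMConfig(alpha=alpha, grid_size=10000))
        assert np.abs(p_a - p_b).max() < 1e-4

    def test_mass_conservation_and_open_interval(self):
        rng = np.random.default_rng(4)
        for alpha in (0.0, 0.3, 1.0):
            seq = (rng.random(200) < 0.33).astype(int)
            p, state = dbm_forward(seq, DBMConfig(alpha=alpha))
            assert abs(state.mass.sum() - 1.0) < 1e-10
            assert (p > 0).all() and (p < 1).all()

    def test_stop_observation_raises_next_prediction(self):
        cfg = DBMConfig(alpha=0.4)
        base = np.array([0, 1, 0, 0, 0, 0])
        for k in range(len(base)):
            swapped = base.copy()
            if swapped[k] == 1:
                continue
            swapped[k] = 1
            p0, _ = dbm_forward(base, cfg)
            p1, _ = dbm_forward(swapped, cfg)
            if k + 1 < len(base):
                assert p1[k + 1] >= p0[k + 1]

    def test_batch_matches_single_sequence_filter(self):
        rng = np.random.default_rng(5)
        S = (rng.random((6, 48)) < 0.33).astype(int)
        cfg = DBMConfig(alpha=0.35, grid_size=500)
        P = dbm_forward_batch(S, cfg)
        for i in range(len(S)):
            assert np.allclose(P[i], dbm_forward(S[i], cfg)[0], atol=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dbm_forward(np.array([]), DBMConfig())
        with pytest.raises(ValueError):
            dbm_forward(np.array([0, 2]), DBMConfig())
        with pytest.raises(ValueError):
            DBMConfig(alpha=1.5)
        with pytest.raises(ValueError):
            DBMConfig(grid_size=10)


class TestAnticipationCorrelation:
    def test_perfectly_linear_rt_gives_unit_correlation(self, sst_trials):
        p_stop = pstop_per_run(sst_trials)
        trials = sst_trials.copy()
        go = trials["trial_type"] == "go"
        trials.loc[go, "rt"] = 400.0 + 1000.0 * p_stop[go]
        trials.loc[go, "responded"] = True
        trials.loc[go, "choice_correct"] = True
        r, p, flagged = anticipation_correlation(trials, p_stop)
        assert not flagged and r == pytest.approx(1.0)

    def test_unrelated_rt_centered_at_zero(self, plain_profile):
        import dataclasses

        from dualcontrol.simulate import simulate_session
        from dualcontrol.trial_data import trials_to_frame

        rs = []
        for seed in range(30):
            prof = dataclasses.replace(plain_profile, subject_id=f"s{seed}")
            trials = trials_to_frame(simulate_session(prof, "SST", 1, seed))
            r, _, flagged = anticipation_correlation(trials, pstop_per_run(trials))
            if not flagged:
                rs.append(r)
        assert abs(np.mean(rs)) < 0.06

    def test_correlation_increases_with_anticipatory_gain(self, plain_profile):
        import dataclasses

        from dualcontrol.simulate import simulate_session
        from dualcontrol.trial_data import trials_to_frame

        means = []
        for beta in (0.0, 200.0, 500.0):
            rs = []
            for seed in range(25):
                prof = dataclasses.replace(
                    plain_profile, subject_id=f"s{seed}", beta_antic=beta
                )
                rng = np.random.default_rng(7000 + seed)
                recs = []
                for run in (1, 2):
                    recs += simulate_session(prof, "SST", run, rng)
                trials = trials_to_frame(recs)
                r, _, flagged = anticipation_correlation(trials, pstop_per_run(trials))
                if not flagged:
                    rs.append(r)
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]

    def test_too_few_trials_flagged(self, sst_trials):
        few = sst_trials.head(8)
        r, p, flagged = anticipation_correlation(few, pstop_per_run(few))
        assert flagged and np.isnan(r)


class TestCalibrateAlpha:
    def test_default_grid_has_eleven_candidates(self, small_cohort):
        trials, _ = small_cohort
        curve, _ = calibrate_alpha(
            trials, cfg=DBMConfig(grid_size=200)
        )
        assert len(curve) == 11
        assert curve["alpha"].iloc[0] == pytest.approx(0.2)
        assert curve["alpha"].iloc[-1] == pytest.approx(0.7)

    def test_flat_curve_without_anticipatory_signal(self, plain_profile):
        import dataclasses

        from dualcontrol.simulate import simulate_session
        from dualcontrol.trial_data import trials_to_frame

        recs = []
        for seed in range(12):
            prof = dataclasses.replace(plain_profile, subject_id=f"s{seed:02d}")
            rng = np.random.default_rng(8000 + seed)
            for run in (1, 2):
                recs += simulate_session(prof, "SST", run, rng)
        trials = trials_to_frame(recs)
        curve, _ = calibrate_alpha(trials, cfg=DBMConfig(grid_size=300))
        # no anticipation in the generator: binned correlations hover near 0
        assert curve["binned_r"].abs().max() < 0.6

    def test_bin_count_validation(self, small_cohort):
        trials, _ = small_cohort
        with pytest.raises(ValueError):
            calibrate_alpha(trials, n_bins=2)
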