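"""Photometry: generation, preprocessing, warping, regressions."""

import numpy as np
import pandas as pd
import pytest

from twostep.photometry import (PhotoGenParams, PhotometrySession,
                                build_predictors, cue_response,
                                group_stats, lagged_cue_response_regression,
                                per_timepoint_lasso, preprocess,
                                reward_rate_ema, synth_photometry,
                                timewarp_align)

from conftest import simulate_subjects


@pytest.fixture(scope="module")
def session_df():
    return simulate_subjects(1, 250, seed=31).reset_index(drop=True)


@pytest.fixture(scope="module")
def raw_session(session_df):
    rng = np.random.default_rng(2)
    return synth_photometry(session_df, rng=rng)


@pytest.fixture(scope="module")
def clean_session(raw_session):
    return preprocess(raw_session)


class TestSynth:
    def test_zero_amplitudes_leave_pure_bleaching(self, session_df):
        gp = PhotoGenParams(amp_reward=0, amp_ss_value=0, amp_chosen_value=0,
                            amp_reward_rate=0, amp_movement=0, noise_sd=0,
                            motion_sd=0)
        ps = synth_photometry(session_df, gen_params=gp,
                              rng=np.random.default_rng(0))
        t = np.arange(len(ps.signal)) / ps.sample_rate
        bleach = gp.bleach_amp * (
            gp.bleach_frac_fast * np.exp(-t / gp.bleach_tau_fast)
            + (1 - gp.bleach_frac_fast) * np.exp(-t / gp.bleach_tau_slow))
        assert np.allclose(ps.signal, bleach)

    def test_reward_raises_outcome_window(self, session_df):
        gp = PhotoGenParams(amp_reward=1.0, amp_ss_value=0,
                            amp_chosen_value=0, amp_reward_rate=0,
                            amp_movement=0, noise_sd=0.01, motion_sd=0,
                            bleach_amp=0)
        ps = synth_photometry(session_df, gen_params=gp,
                              rng=np.random.default_rng(0))
        fs = ps.sample_rate
        means = []
        for i, row in ps.events.iterrows():
            i0 = int(row["outcome_cue_on"] * fs)
            means.append(ps.signal[i0:i0 + int(0.5 * fs)].mean())
        means = np.array(means)
        rewarded = ps.session_link["outcome"].to_numpy() == 1
        assert means[rewarded].mean() > means[~rewarded].mean() + 0.3

    def test_event_times_strictly_ordered(self, raw_session):
        ev = raw_session.events.to_numpy()
        assert np.all(np.diff(ev, axis=1) > 0)

    def test_mismatched_channels_rejected(self):
        with pytest.raises(ValueError):
            PhotometrySession(sample_rate=130.0, signal=np.zeros(10),
                              control=np.zeros(9),
                              events=pd.DataFrame(columns=[
                                  "init_illum", "init_poke", "choice_poke",
                                  "ss_cue_on", "ss_poke", "outcome_cue_on"]),
                              session_link=pd.DataFrame())


class TestPreprocess:
    def test_output_is_z_scored(self, clean_session):
        assert clean_session.signal.mean() == pytest.approx(0.0, abs=1e-10)
        assert clean_session.signal.std() == pytest.approx(1.0, abs=1e-10)

    def test_single_sample_impulse_removed(self):
        n = 2000
        sig = np.zeros(n)
        sig[1000] = 50.0
        ev = pd.DataFrame(columns=["init_illum", "init_poke", "choice_poke",
                                   "ss_cue_on", "ss_poke", "outcome_cue_on"])
        ps = PhotometrySession(130.0, sig, np.zeros(n), ev, pd.DataFrame())
        out = preprocess(ps)
        # a width-1 impulse cannot survive the width-5 median filter
        assert np.abs(out.signal).max() < 5.0

    def test_shared_motion_artifact_is_removed(self, session_df):
        gp = PhotoGenParams(noise_sd=0.02, motion_sd=1.0)
        rng = np.random.default_rng(7)
        ps = synth_photometry(session_df, gen_params=gp, rng=rng)
        # reconstruct the artifact: it is the common component of the two
        # channels beyond their bleaching curves; approximate via control
        from scipy.signal import butter, filtfilt
        b, a = butter(2, [0.001 / 65.0, 5.0 / 65.0], btype="band")
        artifact = filtfilt(b, a, ps.control)
        out = preprocess(ps)
        r = np.corrcoef(out.signal, artifact)[0, 1]
        assert abs(r) < 0.1


class TestTimewarp:
    def test_identity_warp_preserves_samples(self, clean_session):
        fs = clean_session.sample_rate
        ev = clean_session.events
        d1 = (ev["choice_poke"] - ev["init_poke"]).to_numpy()
        trial = 5
        mat = timewarp_align(clean_session,
                             target_lengths={"init_choice": float(d1[trial]),
                                             "cue_poke": 1.3})
        n1 = int(round(d1[trial] * fs))
        cols = mat.segment_labels == "init_choice"
        i0 = int(round(ev["init_poke"].iloc[trial] * fs))
        seg_raw = clean_session.signal[i0:i0 + n1]
        seg_warp = mat.values[trial, cols]
        # a warp to (approximately) the native length reproduces the ramp
        assert np.allclose(seg_warp[0], seg_raw[0], atol=1e-9)
        assert np.corrcoef(seg_warp, seg_raw[:len(seg_warp)])[0, 1] > 0.99

    def test_linear_ramp_stays_linear(self, clean_session):
        ramp_session = PhotometrySession(
            sample_rate=clean_session.sample_rate,
            signal=np.arange(len(clean_session.signal), dtype=float),
            control=np.zeros(len(clean_session.signal)),
            events=clean_session.events,
            session_link=clean_session.session_link)
        mat = timewarp_align(ramp_session)
        cols = mat.segment_labels == "init_choice"
        for trial in range(3):
            seg = mat.values[trial, cols]
            diffs = np.diff(seg)
            assert np.allclose(diffs, diffs[0], atol=1e-6)

    def test_unwarped_outcome_segment_is_bit_exact(self, clean_session):
        mat = timewarp_align(clean_session)
        fs = clean_session.sample_rate
        cols = mat.segment_labels == "outcome"
        n_out = cols.sum()
        for trial in np.flatnonzero(mat.mask)[:10]:
            i0 = int(round(clean_session.events["ss_poke"].iloc[trial] * fs))
            raw = clean_session.signal[i0:i0 + n_out]
            assert np.array_equal(mat.values[trial, cols], raw)

    def test_fixed_timepoint_count_across_trials(self, clean_session):
        mat = timewarp_align(clean_session)
        assert mat.values.shape[1] == len(mat.time_axis)
        assert np.isfinite(mat.values[mat.mask]).all()


class TestPredictors:
    def test_methods_codings(self, session_df):
        spec = build_predictors(session_df, "base")
        X, df = spec.X, session_df
        prev = df.shift(1)
        i = 10
        assert X["reward"].iloc[i] == (0.5 if df["outcome"].iloc[i] == 1
                                       else -0.5)
        same_ss = df["second_step"].iloc[i] == prev["second_step"].iloc[i]
        if same_ss:
            assert X["prev_reward_same_ss"].iloc[i] == \
                (0.5 if prev["outcome"].iloc[i] == 1 else -0.5)
            assert X["prev_reward_diff_ss"].iloc[i] == 0.0
        else:
            assert X["prev_reward_same_ss"].iloc[i] == 0.0

    def test_neutral_block_zeroes_block_codes(self, session_df):
        spec = build_predictors(session_df, "base")
        neutral = session_df["hidden_state"] == "neutral"
        if neutral.any():
            assert (spec.X.loc[neutral, "good_second_step"] == 0).all()
            assert (spec.X.loc[neutral, "correct_choice"] == 0).all()

    def test_reward_rate_ema_limits(self):
        rr = reward_rate_ema(np.ones(300), tau=10.0)
        assert np.all(np.diff(rr) >= 0) and rr[-1] > 0.99
        rr0 = reward_rate_ema(np.zeros(300), tau=10.0)
        assert rr0[-1] < 0.01

    def test_first_trial_flagged_invalid(self, session_df):
        spec = build_predictors(session_df, "base")
        assert not spec.valid[0] and spec.valid[1:].all()

    def test_value_variant_uses_agent_values(self, session_df):
        spec = build_predictors(session_df, "value")
        assert {"second_step_value", "chosen_value"} <= set(spec.X.columns)
        vals = spec.X["second_step_value"].iloc[1:]
        assert vals.between(0, 1).all()

    def test_outcome_split_codes_are_exclusive(self, session_df):
        spec = build_predictors(session_df, "outcome_split")
        X = spec.X.iloc[1:]
        rew = X["same_vs_diff_prev_rewarded"] != 0
        unrew = X["same_vs_diff_prev_unrewarded"] != 0
        assert not (rew & unrew).any()
        assert (rew | unrew).all()

    def test_unknown_variant_rejected(self, session_df):
        with pytest.raises(ValueError):
            build_predictors(session_df, "bogus")


class TestLasso:
    def test_zero_penalty_matches_ols_oracle(self, clean_session, session_df):
        mat = timewarp_align(clean_session)
        design = build_predictors(session_df, "base")
        betas = per_timepoint_lasso(mat, design, stride=40,
                                    alpha_override=0.0)
        # OLS oracle at one timepoint
        rows = mat.mask & design.valid
        X = design.X[rows]
        keep = [c for c in X.columns if X[c].nunique() > 1]
        Xs = X[keep].to_numpy()
        Xs = (Xs - Xs.mean(0)) / Xs.std(0)
        col = 40
        y = mat.values[np.asarray(rows), col]
        coef = np.linalg.lstsq(
            np.column_stack([np.ones(len(Xs)), Xs]), y, rcond=None)[0][1:]
        assert np.allclose(betas.iloc[1].to_numpy(), coef, atol=1e-8)

    def test_pure_noise_coefficients_shrink(self):
        session_df = simulate_subjects(1, 4000, seed=33).reset_index(drop=True)
        rng = np.random.default_rng(12)
        design = build_predictors(session_df, "base")
        n = len(session_df)
        from twostep.photometry import WarpedTrialMatrix
        noise = rng.normal(0, 1, (n, 10))
        mat = WarpedTrialMatrix(
            values=noise, time_axis=np.arange(10) / 130.0,
            segment_labels=np.array(["outcome"] * 10),
            anchors={}, mask=np.ones(n, dtype=bool), sample_rate=130.0)
        betas = per_timepoint_lasso(mat, design, stride=1, seed=0)
        assert np.nanmax(np.abs(betas.to_numpy())) < 0.05


class TestGroupStats:
    def test_bh_step_up_arithmetic(self):
        """p = .01,.02,.03,.04 over four timepoints all adjust to .04.

        BH adjusts over timepoints (rows) within each predictor, so build
        one predictor observed at four timepoints with those exact p-values.
        """
        rng = np.random.default_rng(0)
        targets = [0.01, 0.02, 0.03, 0.04]
        from scipy import stats as ss
        n = 4  # subjects
        base = rng.normal(0, 1, (n, 4))
        base = (base - base.mean(0)) / base.std(0, ddof=1)
        means = [ss.t.ppf(1 - p / 2, df=n - 1) / np.sqrt(n) for p in targets]
        betas = [pd.DataFrame({"x": base[s] + means}) for s in range(n)]
        out = group_stats(betas)
        assert np.allclose(out["p"]["x"].to_numpy(), targets, atol=1e-9)
        assert np.allclose(out["p_adj"]["x"].to_numpy(), 0.04, atol=1e-9)

    def test_cohens_d_definition(self):
        cols = ["x"]
        vals = [-1.0, 1.0, 3.0]  # mean 1, sd 2 -> d = 0.5
        betas = [pd.DataFrame([[v]], columns=cols) for v in vals]
        out = group_stats(betas)
        assert out["cohens_d"].iloc[0, 0] == pytest.approx(0.5)

    def test_zero_variance_is_flagged(self):
        betas = [pd.DataFrame([[1.0]], columns=["x"]) for _ in range(3)]
        out = group_stats(betas)
        assert out["d_capped"].iloc[0, 0]
        assert out["cohens_d"].iloc[0, 0] >= 1e6

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError):
            group_stats([pd.DataFrame([[1.0]]), pd.DataFrame([[2.0]])])


class TestCueResponse:
    def test_flat_signal_gives_zero_responses(self, clean_session):
        flat = PhotometrySession(
            sample_rate=clean_session.sample_rate,
            signal=np.full(len(clean_session.signal), 3.14),
            control=np.zeros(len(clean_session.signal)),
            events=clean_session.events,
            session_link=clean_session.session_link)
        resp = cue_response(flat)
        assert np.allclose(resp[np.isfinite(resp)], 0.0)

    def test_toy_window_means(self):
        fs = 130.0
        n = int(20 * fs)
        sig = np.zeros(n)
        ev = pd.DataFrame({
            "init_illum": [2.0], "init_poke": [3.0], "choice_poke": [4.0],
            "ss_cue_on": [4.2], "ss_poke": [5.5], "outcome_cue_on": [5.7]})
        # baseline window [3.5, 4.0): value 1; cue-end window [4.7, 5.2): 3
        sig[int(3.5 * fs):int(4.0 * fs)] = 1.0
        sig[int(4.7 * fs):int(5.2 * fs)] = 3.0
        ps = PhotometrySession(fs, sig, np.zeros(n), ev,
                               pd.DataFrame({"outcome": [1]}))
        resp = cue_response(ps)
        assert resp[0] == pytest.approx(2.0, abs=0.05)

    def test_planted_lag1_effect_recovered(self, session_df):
        """A cue response driven by the previous trial's same-port reward
        loads on the lag-1 same-second-step coefficient."""
        rng = np.random.default_rng(4)
        fs = 130.0
        df = session_df
        base = synth_photometry(
            df, gen_params=PhotoGenParams(
                amp_reward=0, amp_ss_value=0, amp_chosen_value=0,
                amp_reward_rate=0, amp_movement=0, noise_sd=0.05,
                motion_sd=0, bleach_amp=0),
            rng=rng)
        sig = base.signal.copy()
        prev = df.shift(1)
        planted = 1.0
        for i in range(1, len(df)):
            same = df["second_step"].iloc[i] == prev["second_step"].iloc[i]
            code = (0.5 if prev["outcome"].iloc[i] == 1 else -0.5) if same \
                else 0.0
            i0 = int((base.events["ss_cue_on"].iloc[i] + 0.5) * fs)
            sig[i0:i0 + int(0.5 * fs)] += planted * code
        ps = PhotometrySession(fs, sig, base.control, base.events,
                               base.session_link)
        rep = lagged_cue_response_regression(ps, max_lag=4)
        # lag-1 same + lag-1 diff equals the unlagged previous-reward code,
        # so single coefficients are minimum-norm; the same-minus-different
        # contrast is identified and must recover the planted amplitude
        est = (rep.loc["same_ss_rew_lag1", "coef"]
               - rep.loc["diff_ss_rew_lag1", "coef"])
        se = np.hypot(rep.loc["same_ss_rew_lag1", "se"],
                      rep.loc["diff_ss_rew_lag1", "se"])
        assert abs(est - planted) < 3 * se + 0.05
        # no effect leaks into later lags
        assert abs(rep.loc["same_ss_rew_lag3", "coef"]
                   - rep.loc["diff_ss_rew_lag3", "coef"]) < 0.1
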