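"""Behavioral statistics for two-step sessions.

Implements the stay-probability table, the stay logistic regression (with the
optional stimulation terms and the matched-history trial filter), the lagged
choice-history regression, the Bayes-factor computation for null stimulation
effects, and the stim/non-stim trial-initiation latency comparison.

Group-level inference uses per-subject fixed-effects fits followed by
cross-subject one-sample t-tests on the coefficients (a two-stage
approximation to a random-effects model); predictors use sum-to-zero
codings with left / rewarded / common as the positive level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionReport",
    "stay_table",
    "stay_design",
    "stay_logistic",
    "lagged_design",
    "lagged_choice_regression",
    "bayes_factor",
    "latency_compare",
]

DEFAULT_LAG_BUNDLES = ((1, 1), (2, 2), (3, 4), (5, 8), (9, 12))


@dataclass
class RegressionReport:
    """Per-subject coefficients plus cross-subject tests."""

    coefficients: pd.DataFrame        # subjects x predictors
    summary: pd.DataFrame             # per predictor: mean, se, t, p, p_adj
    n_trials: int
    adjustment: str = "none"
    per_subject_se: Optional[pd.DataFrame] = None

    def coef(self, name: str) -> pd.Series:
        return self.coefficients[name]


# ---------------------------------------------------------------------------
# Stay-opportunity bookkeeping
# ---------------------------------------------------------------------------

def _stay_pairs(sessions: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-trial pairs where the *next* trial is free choice.

    Returns one row per stay opportunity with the previous trial's events
    (prefixed ``prev_``) and the stay indicator.  Pairs never cross session
    boundaries.
    """
    df = sessions.sort_values(["subject_id", "session_id", "trial"],
                              kind="stable").reset_index(drop=True)
    g = df.groupby(["subject_id", "session_id"], sort=False)
    prev = g.shift(1)
    ok = prev["choice"].notna() & (df["free_choice"] == 1)
    out = pd.DataFrame({
        "subject_id": df["subject_id"],
        "session_id": df["session_id"],
        "trial": df["trial"],
        "stay": (df["choice"] == prev["choice"]).astype(float),
        "choice": df["choice"],
        "prev_choice": prev["choice"],
        "prev_transition": prev["transition"],
        "prev_second_step": prev["second_step"],
        "prev_outcome": prev["outcome"],
        "prev_hidden_state": prev["hidden_state"],
        "prev_stim": prev["stim"],
        "prev_free": prev["free_choice"],
        "latency_ms": df["latency_ms"],
    })
    return out[ok].reset_index(drop=True)


def stay_table(sessions: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stay probability by previous {transition} x {outcome}.

    Returns ``(per_subject, summary)``: a long per-subject table with columns
    (subject_id, transition, outcome, stay_prob, n) and a cross-subject
    summary (mean, sem, n_subjects) per cell; empty cells are missing rows.
    """
    pairs = _stay_pairs(sessions)
    grp = pairs.groupby(["subject_id", "prev_transition", "prev_outcome"])
    per = grp["stay"].agg(["mean", "count"]).reset_index()
    per.columns = ["subject_id", "transition", "outcome", "stay_prob", "n"]
    summ = (per.groupby(["transition", "outcome"])["stay_prob"]
            .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
                 n_subjects="count")
            .reset_index())
    return per, summ


# ---------------------------------------------------------------------------
# Logistic regressions
# ---------------------------------------------------------------------------

def _fit_logistic(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-subject logistic fit with a ridge fallback on separation."""
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    try:
        res = model.fit(disp=0, maxiter=200)
        params = res.params
        bse = res.bse
        if (not np.all(np.isfinite(params)) or np.abs(params).max() > 15
                or not np.all(np.isfinite(bse))):
            raise ValueError("separation suspected")
    except Exception:
        res = model.fit_regularized(alpha=0.5, L1_wt=0.0, disp=0, maxiter=500)
        params = pd.Series(np.asarray(res.params), index=Xc.columns)
        bse = pd.Series(np.nan, index=Xc.columns)
    return params.drop("const"), bse.drop("const")


def _cross_subject_tests(coefs: pd.DataFrame,
                         adjustment: str = "none") -> pd.DataFrame:
    means = coefs.mean(axis=0)
    sds = coefs.std(axis=0, ddof=1)
    n = len(coefs)
    ses = sds / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = means / ses
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n - 1)
    out = pd.DataFrame({"mean": means, "se": ses, "t": tvals, "p": pvals})
    if adjustment == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    elif adjustment == "BH":
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    else:
        out["p_adj"] = out["p"]
    return out


def stay_design(sessions: pd.DataFrame, include_stim: bool = False,
                group_map: Optional[dict] = None) -> pd.DataFrame:
    """Design matrix for the stay regression, one row per stay opportunity.

    Codings (sum-to-zero, positive level left/rewarded/common):

    * ``correct_vs_incorrect``: previous choice correct +1, incorrect -1,
      neutral block 0;
    * ``nonneutral_vs_neutral``: correct or incorrect +0.5, neutral -1
      (the orthogonal complement of the 3-level correct factor);
    * ``bias``: previous choice left +0.5 / right -0.5;
    * ``transition``: previous transition common +0.5 / rare -0.5;
    * ``outcome``: previous trial rewarded +0.5 / unrewarded -0.5;
    * ``transition_x_outcome``: product rescaled to +/-0.5.

    With ``include_stim``, a ``stim`` code (previous trial stimulated +0.5 /
    not -0.5) and its interactions with transition, outcome and
    transition x outcome are added, and only stay opportunities whose
    previous trial *could* have been stimulated are kept (the two trials of
    the post-stimulation lockout are dropped).  ``group_map`` (subject ->
    +/-0.5) adds group terms for between-group designs.
    """
    pairs = _stay_pairs(sessions).reset_index(drop=True)
    nonneutral = (pairs["prev_hidden_state"] != "neutral").to_numpy()
    good_up = (pairs["prev_hidden_state"] == "up_good").to_numpy()
    # The previous choice was correct if it commonly led to the good port;
    # its common second step is derived from the transition label and the
    # realized second step (transition-type independent).
    prev_ss = pairs["prev_second_step"]
    other = prev_ss.map({"up": "down", "down": "up"})
    common_ss = np.where(pairs["prev_transition"] == "common", prev_ss, other)
    good_ss = np.where(good_up, "up", "down")
    correct = common_ss == good_ss
    prev_correct = np.where(nonneutral, np.where(correct, 1.0, -1.0), 0.0)
    nonneutral_code = np.where(nonneutral, 0.5, -1.0)

    X = pd.DataFrame({
        "correct_vs_incorrect": prev_correct,
        "nonneutral_vs_neutral": nonneutral_code,
        "bias": np.where(pairs["prev_choice"] == "left", 0.5, -0.5),
        "transition": np.where(pairs["prev_transition"] == "common", 0.5, -0.5),
        "outcome": np.where(pairs["prev_outcome"] == 1, 0.5, -0.5),
    })
    X["transition_x_outcome"] = 2.0 * X["transition"] * X["outcome"]

    meta = pairs[["subject_id", "session_id", "trial", "stay"]].reset_index(drop=True)
    out = pd.concat([meta, X], axis=1)

    if include_stim:
        stim_prev = (pairs["prev_stim"] != "none").to_numpy()
        out["stim"] = np.where(stim_prev, 0.5, -0.5)
        out["stim_x_transition"] = 2.0 * out["stim"] * out["transition"]
        out["stim_x_outcome"] = 2.0 * out["stim"] * out["outcome"]
        out["stim_x_transition_x_outcome"] = (
            2.0 * out["stim"] * out["transition_x_outcome"])
        # matched-history filter: drop pairs whose previous trial sat in the
        # 2-trial lockout after a stimulation (could never have been stimmed).
        df2 = sessions.sort_values(["subject_id", "session_id", "trial"],
                                   kind="stable").reset_index(drop=True)
        stim_flag = (df2["stim"] != "none").to_numpy()
        grp = df2.groupby(["subject_id", "session_id"], sort=False)
        lock = np.zeros(len(df2), dtype=bool)
        for _, idx in grp.indices.items():
            idx = np.sort(idx)
            flags = stim_flag[idx]
            for j in np.flatnonzero(flags):
                lock[idx[j + 1:j + 3]] = True
        lockable = pd.DataFrame({
            "subject_id": df2["subject_id"], "session_id": df2["session_id"],
            "trial": df2["trial"], "locked": lock})
        # The lockout applies to the previous (predictor) trial of each stay
        # opportunity: previous trial index = stay trial - 1.
        prev_key = out[["subject_id", "session_id"]].copy()
        prev_key["trial"] = out["trial"] - 1
        prev_locked = prev_key.merge(
            lockable, on=["subject_id", "session_id", "trial"],
            how="left")["locked"].fillna(False).to_numpy()
        out = out[~prev_locked].reset_index(drop=True)

    if group_map is not None:
        out["group"] = out["subject_id"].map(group_map)
        for c in ("transition", "outcome", "transition_x_outcome", "stim",
                  "stim_x_transition", "stim_x_transition_x_outcome"):
            if c in out:
                out[f"group_x_{c}"] = 2.0 * out["group"] * out[c]
    return out


def stay_logistic(sessions: pd.DataFrame, include_stim: bool = False,
                  group_map: Optional[dict] = None) -> RegressionReport:
    """Per-subject stay logistic regression + cross-subject t-tests."""
    design = stay_design(sessions, include_stim=include_stim,
                         group_map=group_map)
    pred_cols = [c for c in design.columns
                 if c not in ("subject_id", "session_id", "trial", "stay")]
    coefs, ses = {}, {}
    for subject, d in design.groupby("subject_id"):
        X = d[pred_cols]
        keep = [c for c in pred_cols if X[c].nunique() > 1]
        params, bse = _fit_logistic(d["stay"].to_numpy(), X[keep])
        coefs[subject] = params.reindex(pred_cols)
        ses[subject] = bse.reindex(pred_cols)
    coef_df = pd.DataFrame(coefs).T
    summary = _cross_subject_tests(coef_df)
    return RegressionReport(coefficients=coef_df, summary=summary,
                            n_trials=len(design), adjustment="none",
                            per_subject_se=pd.DataFrame(ses).T)


def lagged_design(sessions: pd.DataFrame,
                  lag_bundles=DEFAULT_LAG_BUNDLES,
                  max_lag: int = 12) -> pd.DataFrame:
    """Design for the lagged choice-history regression.

    For each free-choice trial with at least ``max_lag`` predecessors in its
    session, codes four trial-type predictors per lag (common/rare x
    rewarded/unrewarded; +0.5 left, -0.5 right, 0 otherwise) and sums them
    within each lag bundle.  The outcome column ``y`` is 1 for left choices.
    """
    df = sessions.sort_values(["subject_id", "session_id", "trial"],
                              kind="stable").reset_index(drop=True)
    rows = []
    for (subj, sess), d in df.groupby(["subject_id", "session_id"],
                                      sort=False):
        d = d.reset_index(drop=True)
        sign = np.where(d["choice"] == "left", 0.5, -0.5)
        common = (d["transition"] == "common").to_numpy()
        rew = (d["outcome"] == 1).to_numpy()
        codes = {
            "common_rewarded": np.where(common & rew, sign, 0.0),
            "rare_rewarded": np.where(~common & rew, sign, 0.0),
            "common_unrewarded": np.where(common & ~rew, sign, 0.0),
            "rare_unrewarded": np.where(~common & ~rew, sign, 0.0),
        }
        free = d["free_choice"].to_numpy() == 1
        for t in range(max_lag, len(d)):
            if not free[t]:
                continue
            row = {"subject_id": subj, "session_id": sess,
                   "trial": int(d["trial"].iloc[t]),
                   "y": 1.0 if d["choice"].iloc[t] == "left" else 0.0}
            for lo, hi in lag_bundles:
                sl = slice(t - hi, t - lo + 1)
                for name, code in codes.items():
                    row[f"{name}_lag{lo}_{hi}"] = float(code[sl].sum())
            rows.append(row)
    return pd.DataFrame(rows)


def lagged_choice_regression(sessions: pd.DataFrame,
                             lag_bundles=DEFAULT_LAG_BUNDLES,
                             max_lag: int = 12) -> RegressionReport:
    """Per-subject lagged logistic regression, Bonferroni-adjusted t-tests."""
    design = lagged_design(sessions, lag_bundles=lag_bundles, max_lag=max_lag)
    pred_cols = [c for c in design.columns
                 if c not in ("subject_id", "session_id", "trial", "y")]
    coefs = {}
    for subject, d in design.groupby("subject_id"):
        params, _ = _fit_logistic(d["y"].to_numpy(), d[pred_cols])
        coefs[subject] = params.reindex(pred_cols)
    coef_df = pd.DataFrame(coefs).T
    summary = _cross_subject_tests(coef_df, adjustment="bonferroni")
    return RegressionReport(coefficients=coef_df, summary=summary,
                            n_trials=len(design), adjustment="bonferroni")


# ---------------------------------------------------------------------------
# Bayes factor and latency
# ---------------------------------------------------------------------------

def bayes_factor(beta_mean: float, beta_sd: float, h1_bound: float) -> float:
    """Bayes factor for a coefficient against a point null at zero.

    The data likelihood is Normal(beta_mean, beta_sd) in the coefficient;
    H1 places a uniform prior on the coefficient between 0 and ``h1_bound``
    (either sign), H0 is the point mass at 0:

    B = [ (1/|b|) * int_0^b N(m; beta, s) dbeta ] / N(m; 0, s).
    """
    if beta_sd <= 0:
        raise ValueError("beta_sd must be positive")
    if h1_bound == 0:
        raise ValueError("h1_bound must be nonzero")
    from scipy.special import log_ndtr

    lo, hi = sorted((0.0, h1_bound))
    a = (hi - beta_mean) / beta_sd
    b = (lo - beta_mean) / beta_sd
    # log(Phi(a) - Phi(b)) computed stably in either tail
    if a + b < 0:
        la, lb = log_ndtr(a), log_ndtr(b)
    else:  # Phi(a) - Phi(b) = sf(b) - sf(a) = ndtr(-b) - ndtr(-a)
        la, lb = log_ndtr(-b), log_ndtr(-a)
    log_mass = la + np.log1p(-np.exp(min(lb - la, -1e-16)))
    log_num = log_mass - np.log(abs(h1_bound))
    log_den = stats.norm.logpdf(beta_mean, loc=0.0, scale=beta_sd)
    return float(np.exp(log_num - log_den))


def latency_compare(sessions: pd.DataFrame) -> dict:
    """Trial-initiation latency after stimulated vs non-stimulated trials.

    Per-subject means by condition, then a paired t-test across subjects with
    Cohen's d on the paired differences.  Trials with missing latency are
    dropped (count reported).
    """
    pairs = _stay_pairs(sessions)
    lat = pairs["latency_ms"]
    n_missing = int(lat.isna().sum())
    pairs = pairs[lat.notna()]
    pairs = pairs.assign(stimmed=(pairs["prev_stim"] != "none"))
    per = (pairs.groupby(["subject_id", "stimmed"])["latency_ms"]
           .mean().unstack())
    per = per.dropna()
    if per.shape[1] < 2 or len(per) < 2:
        return {"per_subject": per, "t": np.nan, "p": np.nan,
                "cohens_d": np.nan, "n_missing": n_missing}
    diff = per[True] - per[False]
    sd = diff.std(ddof=1)
    if sd == 0:  # no variance in the paired differences
        t = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
        p = 1.0 if diff.mean() == 0 else 0.0
    else:
        t, p = stats.ttest_rel(per[True], per[False])
    d = diff.mean() / sd if sd > 0 else (0.0 if diff.mean() == 0 else np.inf)
    return {"per_subject": per, "t": float(t), "p": float(p),
            "cohens_d": float(d), "n_missing": n_missing,
            "mean_diff": float(diff.mean())}
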