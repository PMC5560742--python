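"""Linking replay duration to memory behavior.

Trial-level behavior is modeled with a linear mixed-effects model: the
length (ms) of the longest retention-period replay epoch of the probed
stimulus is the fixed effect, and subject identity enters as a random
intercept.  Binary accuracy is modeled on the 0/1 scale with the linear
model (a logistic variant is available behind a flag).  For visualization
and the group-level ANOVA, probes are grouped by replay duration: none
(no epoch of the probe category), short (20-1100 ms) or long (> 1100 ms),
followed by a one-way repeated-measures ANOVA on hit rate with paired
t tests (long vs short, long vs none) post hoc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError
from .replay import PredominanceSummary

__all__ = [
    "MixedModelFit",
    "fit_replay_behavior_lmm",
    "build_behavior_table",
    "group_by_replay_duration",
    "behavior_anova_posthoc",
]

OUTCOMES = ("detail_hit", "detail_rt", "order_hit", "order_rt")


@dataclass
class MixedModelFit:
    """Coefficient table of one mixed-model fit (one behavioral outcome)."""

    outcome: str
    coef: float
    se: float
    t: float
    df: float
    p: float
    random_intercept_var: float
    n_observations: int
    singular: bool = False
    method: str = "MixedLM (REML), random subject intercept"


def build_behavior_table(
    summaries_by_subject: dict,
    behavior_by_subject: dict,
) -> pd.DataFrame:
    """One row per probed trial: subject, replay length of the probe, outcomes.

    ``summaries_by_subject`` maps subject -> list of
    :class:`PredominanceSummary`; ``behavior_by_subject`` maps subject ->
    list of TrialDesign with responses filled.  Replay length is the probe
    category's longest retention epoch.
    """
    rows = []
    for subj, summaries in summaries_by_subject.items():
        by_trial = {s.trial_id: s for s in summaries}
        for trial in behavior_by_subject[subj]:
            s = by_trial.get(trial.trial_id)
            if s is None:
                continue
            replay_ms = s.longest_epoch_ms.get(trial.probe_category, 0.0)
            hit = (
                None
                if trial.detail_response is None
                else int(trial.detail_response == trial.probe_same)
            )
            order_hit = (
                None
                if trial.order_response is None
                else int(trial.order_response == trial.probe_position)
            )
            rows.append(
                {
                    "subject": subj,
                    "trial_id": trial.trial_id,
                    "replay_ms": replay_ms,
                    "replay_group": s.replay_group,
                    "detail_hit": hit,
                    "detail_rt": trial.detail_rt,
                    "order_hit": order_hit,
                    "order_rt": trial.order_rt,
                }
            )
    return pd.DataFrame(rows)


def fit_replay_behavior_lmm(
    table: pd.DataFrame,
    outcomes: tuple[str, ...] = OUTCOMES,
    rt_correct_only: bool = True,
    logistic: bool = False,
) -> dict[str, MixedModelFit]:
    """Fit ``outcome ~ replay_ms + (1 | subject)`` for each outcome.

    REML fit via statsmodels MixedLM.  A singular fit (random-intercept
    variance collapsing to zero or non-convergence) is flagged and falls
    back to pooled ordinary regression with a warning.  With
    ``rt_correct_only``, response-time outcomes use correct trials only.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if table["subject"].nunique() < 2:
        raise ValidationError("need >= 2 subjects for a mixed model")
    counts = table.groupby("subject").size()
    if (counts < 10).any():
        raise ValidationError("need >= 10 trials per subject")

    fits: dict[str, MixedModelFit] = {}
    for outcome in outcomes:
        df = table.dropna(subset=[outcome, "replay_ms"]).copy()
        if outcome.endswith("_rt") and rt_correct_only:
            acc_col = outcome.replace("_rt", "_hit")
            if acc_col in df:
                df = df[df[acc_col] == 1]
        y = df[outcome].astype(float)
        if logistic and outcome.endswith("_hit"):
            # logistic variant: GLM with subject fixed intercepts is not a
            # true mixed model; use BinomialBayesMixedGLM-free approximation
            # via MixedLM on the logit scale is unavailable, so plain GLM.
            model = smf.glm(
                f"{outcome} ~ replay_ms", data=df,
                family=sm.families.Binomial(),
            ).fit()
            coef = float(model.params["replay_ms"])
            se = float(model.bse["replay_ms"])
            fits[outcome] = MixedModelFit(
                outcome=outcome, coef=coef, se=se,
                t=coef / se, df=float(len(df) - 2),
                p=float(model.pvalues["replay_ms"]),
                random_intercept_var=float("nan"),
                n_observations=len(df),
                method="GLM logistic (pooled)",
            )
            continue
        singular = False
        fit = None
        re_var = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = smf.mixedlm(
                    f"{outcome} ~ replay_ms", data=df, groups=df["subject"]
                )
                fit = md.fit(reml=True)
                re_var = float(fit.cov_re.iloc[0, 0])
                if not fit.converged or not np.isfinite(fit.bse["replay_ms"]):
                    raise np.linalg.LinAlgError("mixed model did not converge")
            except (np.linalg.LinAlgError, ValueError):
                singular = True
        if singular:
            warnings.warn(
                f"singular mixed-model fit for {outcome}; "
                "falling back to pooled regression",
                stacklevel=2,
            )
            ols = smf.ols(f"{outcome} ~ replay_ms", data=df).fit()
            fits[outcome] = MixedModelFit(
                outcome=outcome,
                coef=float(ols.params["replay_ms"]),
                se=float(ols.bse["replay_ms"]),
                t=float(ols.tvalues["replay_ms"]),
                df=float(ols.df_resid),
                p=float(ols.pvalues["replay_ms"]),
                random_intercept_var=0.0,
                n_observations=len(df),
                singular=True,
                method="pooled OLS fallback (singular mixed fit)",
            )
        else:
            coef = float(fit.params["replay_ms"])
            se = float(fit.bse["replay_ms"])
            dof = float(len(df) - 2)
            fits[outcome] = MixedModelFit(
                outcome=outcome, coef=coef, se=se, t=coef / se, df=dof,
                p=float(2 * stats.t.sf(abs(coef / se), dof)),
                random_intercept_var=re_var,
                n_observations=len(df),
            )
    return fits


def group_by_replay_duration(
    table: pd.DataFrame, rt_correct_only: bool = True
) -> pd.DataFrame:
    """Per subject x replay group: trial count, hit rate (%), mean RT (ms).

    Groups come from the probe category's longest retention epoch: ``none``
    (no epoch), ``short`` (20-1100 ms), ``long`` (> 1100 ms); the three
    groups partition each subject's probed trials.
    """
    rows = []
    for (subj, group), g in table.groupby(["subject", "replay_group"]):
        row = {"subject": subj, "group": group, "n_trials": len(g)}
        for test in ("detail", "order"):
            acc = g[f"{test}_hit"].dropna()
            row[f"{test}_hit_rate"] = (
                100.0 * float(acc.mean()) if len(acc) else np.nan
            )
            rt = g
            if rt_correct_only:
                rt = g[g[f"{test}_hit"] == 1]
            rts = rt[f"{test}_rt"].dropna()
            row[f"{test}_mean_rt"] = float(rts.mean()) if len(rts) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def behavior_anova_posthoc(
    grouped: pd.DataFrame, measure: str = "detail_hit_rate"
) -> dict:
    """Repeated-measures ANOVA on ``measure`` across the three replay groups,
    with paired t tests (long vs short, long vs none) post hoc.

    Subjects missing any group are excluded and reported.
    """
    import pingouin as pg

    wide = grouped.pivot(index="subject", columns="group", values=measure)
    for g in ("none", "short", "long"):
        if g not in wide:
            wide[g] = np.nan
    complete = wide.dropna(subset=["none", "short", "long"])
    excluded = sorted(set(wide.index) - set(complete.index))
    if len(complete) < 2:
        raise ValidationError(
            "need >= 2 subjects with all three replay groups populated"
        )
    long_df = complete.reset_index().melt(
        id_vars="subject", value_vars=["none", "short", "long"],
        var_name="group", value_name="value",
    )
    aov = pg.rm_anova(
        data=long_df, dv="value", within="group", subject="subject",
        detailed=True,
    )
    def _paired_t(a, b):
        # identical paired samples: zero difference everywhere, no evidence
        if np.allclose(a, b):
            return 0.0, 1.0
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p)

    t_ls, p_ls = _paired_t(complete["long"], complete["short"])
    t_ln, p_ln = _paired_t(complete["long"], complete["none"])
    if "F" in aov.columns:
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        f_val, p_val = float(aov.loc[0, "F"]), float(aov.loc[0, p_col])
    else:
        # degenerate design with zero variance: no evidence of any effect
        f_val, p_val = 0.0, 1.0
    return {
        "measure": measure,
        "anova": aov,
        "F": f_val,
        "p": p_val,
        "posthoc": {
            "long_vs_short": {"t": float(t_ls), "p": float(p_ls)},
            "long_vs_none": {"t": float(t_ln), "p": float(p_ln)},
        },
        "n_subjects": int(len(complete)),
        "excluded_subjects": excluded,
        "group_means": {
            g: float(complete[g].mean()) for g in ("none", "short", "long")
        },
    }
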