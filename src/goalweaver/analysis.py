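"""Behavioural summaries and regressions on trial-record tables.

The analyses mirror the study's model-free pipeline: every classifiable
mixed-offer trial is scored against the deterministic optimal agent's
g-choice in the identical context, goal-reaching outcomes are summarised
per difficulty condition, and two regressions probe how the influence of
the heuristic strategy preference changes across the miniblock (an OLS of
per-half g2-choice proportions on subject parameters, and a trial-level
logistic of g-choice on the absolute point difference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import TaskConfig
from .planner import TIE_TOL, ValueTables, backward_induction
from .contexts import ContextSet, extract_contexts

logger = logging.getLogger(__name__)

#: miniblock halves: trials 1-7 vs 8-15
FIRST_HALF_MAX_TRIAL = 7


@dataclass
class SuboptimalitySummary:
    """Suboptimal g-choice proportions with their denominators.

    ``per_trial`` and ``per_condition`` carry columns ``n_scored``,
    ``p_suboptimal``, ``p_suboptimal_g1`` (one-goal choices where the
    optimal agent would balance) and ``p_suboptimal_g2`` (the reverse);
    empty denominators yield NaN, never 0. ``exclusions`` accounts for
    every non-scored row.
    """

    per_trial: pd.DataFrame
    per_condition: pd.DataFrame
    per_condition_trial: pd.DataFrame
    pooled: pd.Series
    exclusions: dict


def _proportions(frame: pd.DataFrame, by) -> pd.DataFrame:
    g = frame.groupby(by, sort=True)
    out = g.agg(n_scored=("suboptimal", "size"),
                p_suboptimal=("suboptimal", "mean"),
                p_suboptimal_g1=("suboptimal_g1", "mean"),
                p_suboptimal_g2=("suboptimal_g2", "mean"))
    return out.reset_index()


def score_suboptimal_gchoices(records: pd.DataFrame,
                              tables: ValueTables | None = None,
                              config: TaskConfig = TaskConfig(),
                              ) -> SuboptimalitySummary:
    """Score each classifiable mixed-offer trial against the optimal
    agent's g-choice in the same (points, offer, trial) context.

    Excluded from scoring: basic-offer trials, unclassifiable mixed trials,
    trials where both scales already reach threshold, and exact DEV ties
    (the optimal reference is ambiguous there). The reference tables use
    gamma = 1, kappa = 1.
    """
    if tables is None:
        tables = backward_induction(config, gamma=1.0, kappa=1.0)
    ctx = extract_contexts(records, tables.config)
    dev = ctx.dev(tables.V, tables.gamma)
    tie = np.abs(dev) <= TIE_TOL
    scored = ctx.defined & ~ctx.post_g2 & ~tie
    optimal_g2 = dev > 0
    suboptimal = ctx.y_g2 != optimal_g2
    frame = pd.DataFrame({
        "trial": ctx.trial,
        "condition": records["condition"].to_numpy(),
        "suboptimal": suboptimal,
        "suboptimal_g1": ~ctx.y_g2 & optimal_g2 & suboptimal,
        "suboptimal_g2": ctx.y_g2 & ~optimal_g2 & suboptimal,
    })[scored]
    n_total = len(records)
    exclusions = {
        "total": n_total,
        "scored": int(scored.sum()),
        "basic_offer": int(ctx.basic.sum()),
        "undefined_mixed": int((~ctx.basic & ~ctx.defined).sum()),
        "post_g2": int((ctx.defined & ctx.post_g2).sum()),
        "dev_tie": int((ctx.defined & ~ctx.post_g2 & tie).sum()),
    }
    assert exclusions["scored"] + exclusions["basic_offer"] + \
        exclusions["undefined_mixed"] + exclusions["post_g2"] + \
        exclusions["dev_tie"] == n_total
    all_trials = pd.DataFrame({"trial": np.arange(1, tables.config.n_trials + 1)})
    per_trial = all_trials.merge(_proportions(frame, "trial"), how="left", on="trial")
    pooled = pd.Series({
        "n_scored": len(frame),
        "p_suboptimal": frame["suboptimal"].mean() if len(frame) else np.nan,
        "p_suboptimal_g1": frame["suboptimal_g1"].mean() if len(frame) else np.nan,
        "p_suboptimal_g2": frame["suboptimal_g2"].mean() if len(frame) else np.nan,
    })
    return SuboptimalitySummary(
        per_trial=per_trial,
        per_condition=_proportions(frame, "condition"),
        per_condition_trial=_proportions(frame, ["condition", "trial"]),
        pooled=pooled,
        exclusions=exclusions,
    )


@dataclass
class GoalSuccessSummary:
    per_condition: pd.DataFrame   # condition, p_g2, p_g1, p_fail, n_blocks
    per_participant: pd.DataFrame  # participant, total_reward (cents)
    total_reward: float


def summarize_goal_success(records: pd.DataFrame,
                           config: TaskConfig = TaskConfig()) -> GoalSuccessSummary:
    """Outcome proportions (G2/G1/fail) per condition and total reward.

    Outcomes are read from the post-final state of each complete miniblock;
    incomplete miniblocks are skipped with a warning.
    """
    rows = []
    for (p, b), g in records.groupby(["participant", "block"], sort=False):
        if len(g) != config.n_trials:
            logger.warning("skipping incomplete miniblock participant=%s block=%s "
                           "(%d trials)", p, b, len(g))
            continue
        last = g.loc[g["trial"].idxmax()]
        a_ok = last["pts_a_next"] >= config.threshold
        b_ok = last["pts_b_next"] >= config.threshold
        outcome = "G2" if (a_ok and b_ok) else ("G1" if (a_ok or b_ok) else "fail")
        reward = config.reward_both if outcome == "G2" else (
            config.reward_one if outcome == "G1" else 0.0)
        rows.append({"participant": p, "block": b,
                     "condition": last["condition"],
                     "outcome": outcome, "reward": reward})
    blocks = pd.DataFrame(rows)
    per_condition = (blocks.groupby("condition")["outcome"]
                     .value_counts(normalize=True).unstack(fill_value=0.0)
                     .reindex(columns=["G2", "G1", "fail"], fill_value=0.0)
                     .rename(columns={"G2": "p_g2", "G1": "p_g1", "fail": "p_fail"}))
    per_condition["n_blocks"] = blocks.groupby("condition").size()
    per_participant = (blocks.groupby("participant")["reward"].sum()
                       .rename("total_reward").reset_index())
    return GoalSuccessSummary(per_condition=per_condition.reset_index(),
                              per_participant=per_participant,
                              total_reward=float(blocks["reward"].sum()))


def g2_proportions_by_half(records: pd.DataFrame,
                           config: TaskConfig = TaskConfig()) -> pd.DataFrame:
    """Per (participant, half) proportion of g2-choices among classifiable
    mixed-offer trials; ``first_half`` is 1 for trials 1-7."""
    ctx = extract_contexts(records, config)
    frame = pd.DataFrame({
        "participant": records["participant"].to_numpy(),
        "first_half": (ctx.trial <= FIRST_HALF_MAX_TRIAL).astype(int),
        "g2": ctx.y_g2,
    })[ctx.defined]
    out = (frame.groupby(["participant", "first_half"])["g2"]
           .agg(["mean", "size"]).rename(columns={"mean": "p_g2", "size": "n"}))
    return out.reset_index()


def halfblock_interaction_regression(records: pd.DataFrame, subject_params,
                                     config: TaskConfig = TaskConfig()
                                     ) -> pd.DataFrame:
    """OLS of per-half g2-choice proportions on subject parameters, a
    miniblock-half indicator, and the strategy-preference-by-half
    interaction (two observations per subject).

    ``subject_params`` maps participant id to natural-scale parameters
    (SubjectParams or dict). A positive ``theta:first_half`` coefficient
    means the heuristic preference predicts g2-choice proportions more
    strongly in the first half, when goals are distant.
    """
    props = g2_proportions_by_half(records, config)
    rows = []
    for r in props.itertuples():
        p = subject_params[r.participant]
        p = p.to_dict() if hasattr(p, "to_dict") else dict(p)
        rows.append({"p_g2": r.p_g2, "theta": p["theta"], "beta": p["beta"],
                     "gamma": p["gamma"], "kappa": p["kappa"],
                     "first_half": r.first_half,
                     "theta_x_first_half": p["theta"] * r.first_half})
    X = pd.DataFrame(rows)
    y = X.pop("p_g2")
    keep = [c for c in X.columns if X[c].nunique() > 1]
    if "theta" not in keep and "theta_x_first_half" in keep:
        # constant theta makes the interaction a scaled copy of the dummy
        keep.remove("theta_x_first_half")
    for c in X.columns:
        if c not in keep:
            logger.warning("dropping zero-variance predictor %r", c)
    fit = sm.OLS(y, sm.add_constant(X[keep])).fit()
    return pd.DataFrame({"estimate": fit.params, "se": fit.bse,
                         "t": fit.tvalues, "p": fit.pvalues})


def absolute_difference_logistic(records: pd.DataFrame,
                                 config: TaskConfig = TaskConfig()
                                 ) -> pd.DataFrame:
    """Trial-level logistic regression of g-choice (g2 = 1) on the absolute
    point difference, the miniblock-half indicator (first half = 1) and
    their interaction. Perfect separation falls back to an L2-penalised
    fit, flagged in the ``method`` column."""
    ctx = extract_contexts(records, config)
    sel = ctx.defined
    a = records["pts_a"].to_numpy()
    b = records["pts_b"].to_numpy()
    X = pd.DataFrame({
        "abs_diff": np.abs(a - b)[sel],
        "first_half": (ctx.trial[sel] <= FIRST_HALF_MAX_TRIAL).astype(int),
    })
    X["abs_diff_x_first_half"] = X["abs_diff"] * X["first_half"]
    y = ctx.y_g2[sel].astype(int)
    Xc = sm.add_constant(X)
    model = sm.Logit(y, Xc)
    try:
        with np.errstate(all="ignore"):
            fit = model.fit(disp=0)
        if not np.all(np.isfinite(fit.bse)):
            raise sm.tools.sm_exceptions.PerfectSeparationError
        method = "mle"
        se, z, p = fit.bse, fit.tvalues, fit.pvalues
        est = fit.params
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        logger.warning("separation detected; reporting L2-penalised logistic fit")
        fit = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        method = "l2_penalised"
        est = fit.params
        se = z = p = pd.Series(np.nan, index=est.index)
    out = pd.DataFrame({"estimate": est, "se": se, "z": z, "p": p})
    out["method"] = method
    return out
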