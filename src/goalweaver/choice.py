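"""Behavioural choice model: heuristic bias plus forward-planning signal.

On classifiable mixed-offer trials the probability of a two-goal (g2)
choice is

    p(g2) = sigma(beta * DEV(gamma, kappa) + theta),

a logistic in the differential expected value DEV with response precision
``beta`` and an additive heuristic strategy preference ``theta`` (positive:
parallel goal pursuit; negative: sequential). Basic offers carry an
infinite bias towards accepting, implemented structurally: they are forced
accepts with probability one and contribute nothing to the likelihood.
``gamma`` (temporal discount) and ``kappa`` (subjective two-goal reward
ratio) enter through the value tables that define DEV.

Free parameters live on a natural scale (beta > 0, theta unbounded,
gamma in (0,1), kappa in (0,2)) and an unconstrained scale
x = (ln beta, theta, logit gamma, ln(kappa/(2-kappa))) used by the
hierarchical prior.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit, logit

from .task import (ACCEPT, WAIT, MiniblockSpec, TaskConfig, TaskState,
                   apply_offer, classify_g_choice, g_actions, get_offer)
from .planner import ValueTables, compute_dev

logger = logging.getLogger(__name__)

PARAM_NAMES = ("beta", "theta", "gamma", "kappa")


@dataclass(frozen=True)
class SubjectParams:
    """One participant's free parameters on the natural scale."""

    beta: float
    theta: float
    gamma: float
    kappa: float

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in the open interval (0, 1)")
        if not 0 < self.kappa < 2:
            raise ValueError("kappa must lie in the open interval (0, 2)")

    @property
    def x(self) -> np.ndarray:
        return transform_params(self)

    @classmethod
    def from_unconstrained(cls, x) -> "SubjectParams":
        return inverse_transform(np.asarray(x, dtype=float))

    def to_dict(self) -> dict:
        return {"beta": self.beta, "theta": self.theta,
                "gamma": self.gamma, "kappa": self.kappa}


def transform_params(params: SubjectParams) -> np.ndarray:
    """Map natural parameters to the unconstrained 4-vector
    (ln beta, theta, logit gamma, ln(kappa / (2 - kappa)))."""
    return np.array([np.log(params.beta), params.theta,
                     logit(params.gamma), np.log(params.kappa / (2 - params.kappa))])


def inverse_transform(x: np.ndarray) -> SubjectParams:
    """Inverse of :func:`transform_params`."""
    x = np.asarray(x, dtype=float)
    if x.shape != (4,):
        raise ValueError("expected a 4-vector")
    return SubjectParams(beta=float(np.exp(x[0])), theta=float(x[1]),
                         gamma=float(expit(x[2])), kappa=float(2 * expit(x[3])))


def heuristic_bias(offer, state: TaskState, action: str, theta: float,
                   config: TaskConfig = TaskConfig()) -> float:
    """Additive choice bias: +inf for accepting a basic offer, ``theta``
    for a g2-classified action on a mixed offer, 0 otherwise."""
    offer = get_offer(offer)
    if offer.is_basic:
        return np.inf if action == ACCEPT else 0.0
    if classify_g_choice(state, offer, action, config) == "g2":
        return theta
    return 0.0


def g2_choice_probability(dev: float, beta: float, theta: float) -> float:
    """Logistic probability of a two-goal choice; p(g1) = 1 - p(g2)."""
    return float(expit(beta * np.asarray(dev) + theta))


def dataset_log_likelihood(records, params: SubjectParams,
                           tables: ValueTables) -> float:
    """Sum of log response probabilities over classifiable mixed-offer
    trials of a trial-record table.

    Basic-offer trials and difference-preserving mixed trials contribute
    zero (their response probability is structurally 1 and 1/2 independent
    of the parameters). Waits on basic offers are impossible under the
    model and are dropped with a warning. ``tables`` must have been built
    with the same (gamma, kappa) as ``params``.
    """
    if not (np.isclose(tables.gamma, params.gamma, atol=1e-9)
            and np.isclose(tables.kappa, params.kappa, atol=1e-9)):
        raise ValueError("value tables were computed for a different (gamma, kappa) "
                         "than the subject parameters")
    config = tables.config
    total = 0.0
    for row in records.itertuples():
        offer = get_offer(row.offer)
        if offer.is_basic:
            if row.response == WAIT:
                logger.warning("dropping impossible basic-offer wait at "
                               "participant=%s block=%s trial=%s",
                               row.participant, row.block, row.trial)
            continue
        state = TaskState(row.pts_a, row.pts_b, row.trial)
        g = classify_g_choice(state, offer, row.response, config)
        if g == "undefined":
            continue
        dev = compute_dev(state, offer, tables)
        sign = 1.0 if g == "g2" else -1.0
        total += float(log_expit(sign * (params.beta * dev + params.theta)))
    return total


def sample_choices(params: SubjectParams, spec: MiniblockSpec,
                   tables: ValueTables, rng: np.random.Generator,
                   participant: str = "sim", block: int = 0) -> list[dict]:
    """Simulate one miniblock generatively from the choice model.

    Basic offers are always accepted; classifiable mixed offers are sampled
    from the logistic g2-probability; difference-preserving mixed offers
    (equal Q for both actions, by the scale-swap symmetry) are a fair coin.
    Returns chained trial records in the CSV schema.
    """
    config = tables.config
    state = TaskState(*spec.initial_pts, trial=1)
    records = []
    for t, offer in enumerate(spec.offers, start=1):
        if offer.is_basic:
            action = ACCEPT
        else:
            cls = classify_g_choice(state, offer, ACCEPT, config)
            if cls == "undefined":
                action = ACCEPT if rng.random() < 0.5 else WAIT
            else:
                dev = compute_dev(state, offer, tables)
                p_g2 = g2_choice_probability(dev, params.beta, params.theta)
                g2_act, g1_act = g_actions(state, offer, config)
                action = g2_act if rng.random() < p_g2 else g1_act
        nxt = apply_offer(state, offer, action, config)
        records.append({
            "participant": participant, "block": block, "trial": t,
            "condition": spec.condition,
            "pts_a": state.pts_a, "pts_b": state.pts_b,
            "offer": offer.label, "response": action,
            "g_choice": classify_g_choice(state, offer, action, config),
            "pts_a_next": nxt.pts_a, "pts_b_next": nxt.pts_b,
        })
        state = nxt
    return records


def write_params(params: dict[str, SubjectParams], path) -> None:
    """Write per-subject natural-scale parameters as JSON."""
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in params.items()}, fh, indent=1)


def read_params(path) -> dict[str, SubjectParams]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: SubjectParams(**v) for k, v in raw.items()}
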