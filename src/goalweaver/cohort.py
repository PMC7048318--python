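"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the behavioural study design: miniblocks of 15
trials, four offer types with balanced pseudo-random frequency, three
difficulty conditions whose initial points are calibrated so that the
deterministic optimal agent's two-goal success rate is 75% (easy), 35%
(medium) and 7% (hard) over 10,000 uniform-offer miniblocks, and
participants whose choices follow the heuristic-biased logistic model with
parameters drawn from the hierarchical population model
x^n ~ N(mu, lambda * sigma) on the unconstrained scale.

Default population locations are the group posterior medians reported for
the real cohort (theta = 0.55, beta = 1.82, gamma = 0.984, kappa = 1.05);
group scales are package defaults chosen to roughly match the spread of
per-participant estimates (see docs/methods.md) and are overridable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import (MiniblockSpec, TaskConfig, generate_offer_sequences,
                   records_to_frame)
from .planner import backward_induction, optimal_policy_table, simulate_blocks
from .choice import SubjectParams, inverse_transform, sample_choices, transform_params

logger = logging.getLogger(__name__)

#: Group posterior medians of the four-parameter model (natural scale).
GROUP_MEDIANS = SubjectParams(beta=1.82, theta=0.55, gamma=0.984, kappa=1.05)

#: Default group scales on the unconstrained scale (ln beta, theta,
#: logit gamma, ln(kappa/(2-kappa))); see docs/methods.md.
DEFAULT_SIGMA = (0.5, 0.5, 0.5, 0.3)

#: Fig 1C difficulty targets: optimal-agent G2 success per condition.
CONDITION_TARGETS = {"easy": 0.75, "medium": 0.35, "hard": 0.07}


class CalibrationFailure(RuntimeError):
    """No initial-point configuration reaches the target within 0.05."""

    def __init__(self, target, best_pair, best_rate):
        self.best_pair, self.best_rate = best_pair, best_rate
        super().__init__(f"no configuration within 0.05 of target {target}; "
                         f"best candidate {best_pair} at rate {best_rate:.4f}")


@dataclass
class PopulationParams:
    """Hierarchical population model on the unconstrained scale."""

    mu: np.ndarray = field(
        default_factory=lambda: transform_params(GROUP_MEDIANS))
    sigma: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_SIGMA))
    lam: float = 1.0
    hyper_m: np.ndarray = field(default_factory=lambda: np.zeros(4))
    hyper_s: np.ndarray = field(default_factory=lambda: np.ones(4))

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < 0) or self.lam <= 0 or np.any(np.asarray(self.hyper_s) <= 0):
            raise ValueError("sigma must be >= 0; lam and hyper_s must be > 0")


@dataclass
class CohortSpec:
    """Cohort size and design: subjects, miniblocks, condition counts."""

    n_subjects: int = 89
    n_blocks: int = 60
    blocks_per_condition: tuple[int, int, int] = (20, 20, 20)
    config: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self):
        if sum(self.blocks_per_condition) != self.n_blocks:
            raise ValueError("blocks_per_condition must sum to n_blocks")


def default_search_space(config: TaskConfig) -> list[tuple[int, int]]:
    """All integer initial-point pairs below threshold."""
    lo = config.point_min
    hi = config.threshold - 1
    return [(a, b) for a in range(lo, hi + 1) for b in range(lo, hi + 1)]


def calibrate_initial_points(target_p_g2: float, n_sim: int = 10_000,
                             config: TaskConfig = TaskConfig(),
                             seed: int = 0,
                             search_space: list[tuple[int, int]] | None = None,
                             ) -> tuple[tuple[int, int], float, float]:
    """Find the initial-point pair whose optimal-agent G2 rate over
    ``n_sim`` uniform-offer miniblocks is closest to the target.

    The same pseudo-random offer draws are shared across candidates
    (common random numbers). Symmetric pairs are preferred on exact ties,
    then lexicographic order. Returns ``(initial_pts, achieved_rate,
    binomial_se)``; raises :class:`CalibrationFailure` if no candidate
    comes within 0.05 of the target.
    """
    if not 0 < target_p_g2 <= 1:
        raise ValueError("target must lie in (0, 1]")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    if search_space is None:
        search_space = default_search_space(config)
    rng = np.random.default_rng(seed)
    offer_idx = rng.integers(0, 4, size=(n_sim, config.n_trials))
    tables = backward_induction(config, gamma=1.0, kappa=1.0)
    pol = optimal_policy_table(tables)
    thr = config.threshold
    results = {}
    for pair in search_space:
        starts = np.tile(np.asarray(pair), (n_sim, 1))
        A, B, _ = simulate_blocks(starts, offer_idx, config, accept_table=pol)
        results[pair] = float(np.mean((A[:, -1] >= thr) & (B[:, -1] >= thr)))

    def sort_key(pair):
        a, b = pair
        return (abs(results[pair] - target_p_g2), a != b, pair)

    best = min(results, key=sort_key)
    rate = results[best]
    if abs(rate - target_p_g2) > 0.05:
        raise CalibrationFailure(target_p_g2, best, rate)
    se = float(np.sqrt(rate * (1 - rate) / n_sim))
    return best, rate, se


def calibrate_conditions(targets: dict[str, float] = CONDITION_TARGETS,
                         n_sim: int = 10_000,
                         config: TaskConfig = TaskConfig(),
                         seed: int = 0) -> dict[str, dict]:
    """Calibrate all difficulty conditions; returns a report mapping
    condition -> {initial_pts, achieved_rate, se, target, n_sim}."""
    report = {}
    for i, (name, target) in enumerate(targets.items()):
        pair, rate, se = calibrate_initial_points(
            target, n_sim=n_sim, config=config, seed=seed + i)
        report[name] = {"initial_pts": list(pair), "achieved_rate": rate,
                        "se": se, "target": target, "n_sim": n_sim,
                        "seed": seed + i}
    return report


def sample_population(pop: PopulationParams, n_subjects: int,
                      seed: int | np.random.Generator = 0) -> list[SubjectParams]:
    """Draw per-subject unconstrained vectors x^n ~ N(mu, lambda*sigma)
    independently per coordinate and map them to the natural scale."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = pop.mu + pop.lam * pop.sigma * rng.standard_normal((n_subjects, 4))
    return [inverse_transform(xi) for xi in x]


def _condition_order(blocks_per_condition, conditions, rng) -> list[str]:
    labels = []
    for name, count in zip(conditions, blocks_per_condition):
        labels.extend([name] * count)
    order = rng.permutation(len(labels))
    return [labels[i] for i in order]


def generate_dataset(spec: CohortSpec, pop: PopulationParams | None = None,
                     conditions: dict[str, tuple[int, int]] | None = None,
                     subjects: list[SubjectParams] | None = None,
                     ) -> tuple[pd.DataFrame, dict]:
    """Simulate a full cohort.

    All subjects share one balanced pseudo-random offer list and one
    pseudo-randomised condition order (as in the experiment). Per-subject
    choices come from :func:`~goalweaver.choice.sample_choices` with value
    tables built for that subject's (gamma, kappa). ``conditions`` maps
    condition label -> initial points; when omitted the conditions are
    calibrated from scratch at the spec's seed.

    Returns ``(records, ground_truth)`` where ``ground_truth`` holds the
    per-subject natural parameters, the population settings and the
    condition definitions.
    """
    pop = pop if pop is not None else PopulationParams()
    ss = np.random.SeedSequence(spec.seed)
    s_cal, s_offers, s_order, s_pop, s_choice = ss.spawn(5)
    if conditions is None:
        report = calibrate_conditions(config=spec.config,
                                      seed=int(s_cal.generate_state(1)[0] % (2**31)))
        conditions = {k: tuple(v["initial_pts"]) for k, v in report.items()}
    offer_lists = generate_offer_sequences(
        spec.n_blocks, spec.config,
        seed=np.random.default_rng(s_offers), balanced=True)
    order = _condition_order(spec.blocks_per_condition, list(conditions),
                             np.random.default_rng(s_order))
    block_specs = [
        MiniblockSpec(condition=cond, initial_pts=conditions[cond],
                      offers=offer_lists[b])
        for b, cond in enumerate(order)
    ]
    if subjects is None:
        subjects = sample_population(pop, spec.n_subjects,
                                     np.random.default_rng(s_pop))
    elif len(subjects) != spec.n_subjects:
        raise ValueError("len(subjects) must equal spec.n_subjects")
    table_cache: dict[tuple[float, float], object] = {}
    all_records = []
    truth_subjects = {}
    for n, params in enumerate(subjects):
        pid = f"sub{n + 1:03d}"
        truth_subjects[pid] = params.to_dict()
        key = (params.gamma, params.kappa)
        if key not in table_cache:
            table_cache[key] = backward_induction(spec.config,
                                                  gamma=params.gamma,
                                                  kappa=params.kappa)
        tables = table_cache[key]
        # per-subject choice substream, deterministic in (seed, subject)
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 7, n)))
        for b, bspec in enumerate(block_specs):
            all_records.extend(sample_choices(params, bspec, tables, rng,
                                              participant=pid, block=b))
    records = records_to_frame(all_records)
    ground_truth = {
        "subjects": truth_subjects,
        "population": {"mu": pop.mu.tolist(), "sigma": pop.sigma.tolist(),
                       "lam": pop.lam},
        "conditions": {k: list(v) for k, v in conditions.items()},
        "seed": spec.seed,
    }
    return records, ground_truth


def simulate_agent_records(conditions: dict[str, tuple[int, int]],
                           n_blocks_per_condition: int,
                           agent: str = "optimal", seed: int = 0,
                           config: TaskConfig = TaskConfig()) -> pd.DataFrame:
    """Vectorised simulation of a reference agent on uniform random offers.

    ``agent`` is ``"optimal"`` (deterministic argmax-Q, gamma=1, kappa=1)
    or ``"random"`` (accepts basic offers, guesses on mixed ones). Returns
    trial records in the CSV schema, one participant per agent.
    """
    from .task import OFFERS
    from .contexts import _EFFECTS, _IS_BASIC
    if agent not in ("optimal", "random"):
        raise ValueError("agent must be 'optimal' or 'random'")
    rng = np.random.default_rng(seed)
    tables = backward_induction(config, gamma=1.0, kappa=1.0)
    pol = optimal_policy_table(tables) if agent == "optimal" else None
    frames = []
    block_offset = 0
    T = config.n_trials
    for cond, start in conditions.items():
        M = n_blocks_per_condition
        offer_idx = rng.integers(0, 4, size=(M, T))
        starts = np.tile(np.asarray(start), (M, 1))
        A, B, ACC = simulate_blocks(
            starts, offer_idx, config, accept_table=pol,
            guess_mixed_rng=None if pol is not None else rng)
        # flatten to trial rows
        blk = np.repeat(np.arange(M) + block_offset, T)
        tr = np.tile(np.arange(1, T + 1), M)
        a = A[:, :-1].ravel()
        b = B[:, :-1].ravel()
        o = offer_idx.ravel()
        acc = ACC.ravel()
        a_next = A[:, 1:].ravel()
        b_next = B[:, 1:].ravel()
        d_acc = np.abs(np.clip(a + _EFFECTS[o, 0], config.point_min, config.point_max)
                       - np.clip(b + _EFFECTS[o, 1], config.point_min, config.point_max))
        d_wait = np.abs(a - b)
        g2_is_accept = d_acc < d_wait
        defined = ~_IS_BASIC[o] & (d_acc != d_wait)
        g = np.where(defined, np.where(acc == g2_is_accept, "g2", "g1"), "undefined")
        frames.append(pd.DataFrame({
            "participant": f"{agent}_agent", "block": blk, "trial": tr,
            "condition": cond, "pts_a": a, "pts_b": b,
            "offer": np.asarray([OFFERS[i].label for i in range(4)])[o],
            "response": np.where(acc, "accept", "wait"),
            "g_choice": g, "pts_a_next": a_next, "pts_b_next": b_next,
        }))
        block_offset += M
    return pd.concat(frames, ignore_index=True)[
        ["participant", "block", "trial", "condition", "pts_a", "pts_b",
         "offer", "response", "g_choice", "pts_a_next", "pts_b_next"]]


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
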