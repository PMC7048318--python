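"""Two-goal sequential decision task as a finite-horizon MDP.

A miniblock is a fixed-length episode (default 15 trials) in which an agent
collects points on two scales (A and B) by accepting or rejecting offers.
Reaching the threshold (default 10 points) on one scale at the end of the
episode pays 5 cents, on both scales 10 cents. Four offer types occur with
equal probability: basic offers (``A``, ``B``) add one point to one scale;
mixed offers (``Ab``, ``aB``) transfer one point from one scale to the other.
Rejecting ("wait") never changes the points. Transitions are deterministic;
the only stochasticity is the offer sequence.

Mixed-offer responses are classified by goal strategy: the action that
minimises the absolute point difference is a two-goal choice (``g2``,
parallel strategy), the action that maximises it a one-goal choice (``g1``,
sequential strategy). When both actions leave the absolute difference
unchanged the classification is undefined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACCEPT = "accept"
WAIT = "wait"

#: CSV column order for trial records.
RECORD_COLUMNS = [
    "participant", "block", "trial", "condition",
    "pts_a", "pts_b", "offer", "response", "g_choice",
    "pts_a_next", "pts_b_next",
]


class InvalidStateError(ValueError):
    """A task state lies outside the admissible point grid."""


class PolicyError(RuntimeError):
    """A policy returned something other than 'accept' or 'wait'."""


class UndefinedDEV(ValueError):
    """DEV requested for a basic offer or a difference-preserving state."""


@dataclass(frozen=True)
class Offer:
    """One of the four trial stimuli.

    ``effect`` is the point change (dA, dB) applied when the offer is
    accepted. Basic offers add a point on one scale; mixed offers move a
    point across scales.
    """

    label: str
    effect: tuple[int, int]

    @property
    def is_mixed(self) -> bool:
        return self.label in ("Ab", "aB")

    @property
    def is_basic(self) -> bool:
        return not self.is_mixed

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


OFFER_A = Offer("A", (1, 0))
OFFER_B = Offer("B", (0, 1))
OFFER_AB = Offer("Ab", (1, -1))
OFFER_BA = Offer("aB", (-1, 1))

#: Canonical offer order used everywhere an offer axis appears in an array.
OFFERS: tuple[Offer, ...] = (OFFER_A, OFFER_B, OFFER_AB, OFFER_BA)
OFFER_INDEX = {o.label: i for i, o in enumerate(OFFERS)}
OFFERS_BY_LABEL = {o.label: o for o in OFFERS}


def get_offer(label: str | Offer) -> Offer:
    if isinstance(label, Offer):
        return label
    try:
        return OFFERS_BY_LABEL[label]
    except KeyError:
        raise KeyError(f"unknown offer label {label!r}; expected one of A, B, Ab, aB")


@dataclass(frozen=True)
class TaskConfig:
    """Task parameters: horizon, threshold, rewards and point bounds."""

    n_trials: int = 15
    threshold: int = 10
    reward_one: float = 5.0
    reward_both: float = 10.0
    point_min: int = 0
    point_max: int = 20

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (self.point_min <= self.threshold <= self.point_max):
            raise ValueError("threshold must lie within the point bounds")
        if not (self.reward_both >= self.reward_one >= 0):
            raise ValueError("rewards must satisfy reward_both >= reward_one >= 0")

    @property
    def n_points(self) -> int:
        """Number of admissible values on each point scale."""
        return self.point_max - self.point_min + 1


@dataclass(frozen=True)
class TaskState:
    """Point counts on both scales plus the 1-based trial index.

    Trial ``n_trials + 1`` denotes the post-final state in which the
    terminal reward is evaluated.
    """

    pts_a: int
    pts_b: int
    trial: int = 1


def _check_state(state: TaskState, config: TaskConfig) -> None:
    if not (config.point_min <= state.pts_a <= config.point_max
            and config.point_min <= state.pts_b <= config.point_max):
        raise InvalidStateError(f"state {state} outside point bounds "
                                f"[{config.point_min}, {config.point_max}]")


def apply_offer(state: TaskState, offer: Offer | str, action: str,
                config: TaskConfig = TaskConfig()) -> TaskState:
    """Deterministic transition: accept shifts points by the offer effect
    (saturated at the point bounds), wait leaves them unchanged; the trial
    index advances either way."""
    _check_state(state, config)
    offer = get_offer(offer)
    if action not in (ACCEPT, WAIT):
        raise PolicyError(f"invalid action {action!r}")
    if action == WAIT:
        return replace(state, trial=state.trial + 1)
    da, db = offer.effect
    a = min(max(state.pts_a + da, config.point_min), config.point_max)
    b = min(max(state.pts_b + db, config.point_min), config.point_max)
    return TaskState(a, b, state.trial + 1)


def terminal_reward(state: TaskState, kappa: float = 1.0,
                    config: TaskConfig = TaskConfig()) -> float:
    """Reward of the post-final state: ``reward_both * kappa`` if both scales
    reach threshold, ``reward_one`` if exactly one does, else 0.

    ``kappa`` is the subjective reward ratio; kappa != 1 models an agent
    that over- or under-values the two-goal outcome.
    """
    if not (0 < kappa <= 2):
        raise ValueError("kappa must lie in (0, 2]")
    a_ok = state.pts_a >= config.threshold
    b_ok = state.pts_b >= config.threshold
    if a_ok and b_ok:
        return config.reward_both * kappa
    if a_ok or b_ok:
        return config.reward_one
    return 0.0


def classify_g_choice(state: TaskState, offer: Offer | str, action: str,
                      config: TaskConfig = TaskConfig()) -> str:
    """Classify a mixed-offer response by goal strategy.

    The action whose resulting state has the smaller absolute point
    difference is the two-goal choice (``g2``); the other is the one-goal
    choice (``g1``). Returns ``"undefined"`` for basic offers and whenever
    both actions leave the absolute difference equal (for mixed offers this
    is the point difference -1 with Ab and +1 with aB).
    """
    offer = get_offer(offer)
    if offer.is_basic:
        return "undefined"
    s_acc = apply_offer(state, offer, ACCEPT, config)
    s_wait = apply_offer(state, offer, WAIT, config)
    d_acc = abs(s_acc.pts_a - s_acc.pts_b)
    d_wait = abs(s_wait.pts_a - s_wait.pts_b)
    if d_acc == d_wait:
        return "undefined"
    if action == ACCEPT:
        return "g2" if d_acc < d_wait else "g1"
    return "g2" if d_wait < d_acc else "g1"


def g_actions(state: TaskState, offer: Offer | str,
              config: TaskConfig = TaskConfig()) -> tuple[str, str]:
    """Return ``(g2_action, g1_action)`` for a classifiable mixed trial."""
    offer = get_offer(offer)
    c = classify_g_choice(state, offer, ACCEPT, config)
    if c == "undefined":
        raise UndefinedDEV(f"g-choice undefined for state {state}, offer {offer.label}")
    return (ACCEPT, WAIT) if c == "g2" else (WAIT, ACCEPT)


@dataclass(frozen=True)
class MiniblockSpec:
    """Start condition and offer sequence of one miniblock."""

    condition: str
    initial_pts: tuple[int, int]
    offers: tuple[Offer, ...]

    def __post_init__(self):
        object.__setattr__(self, "offers",
                           tuple(get_offer(o) for o in self.offers))


def generate_offer_sequences(n_blocks: int, config: TaskConfig = TaskConfig(),
                             seed: int | np.random.Generator = 0,
                             balanced: bool = True) -> list[tuple[Offer, ...]]:
    """Pseudo-random offer lists with equal offer occurrence probability.

    With ``balanced=True`` the pooled counts of the four offers across the
    whole list are equal up to remainder (a balanced permutation); otherwise
    offers are drawn i.i.d. uniform.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = n_blocks * config.n_trials
    if balanced:
        base, rem = divmod(total, 4)
        counts = np.full(4, base)
        if rem:
            counts[rng.permutation(4)[:rem]] += 1
            logger.info("offer list length %d not divisible by 4; counts differ by 1", total)
        flat = np.repeat(np.arange(4), counts)
        rng.shuffle(flat)
    else:
        flat = rng.integers(0, 4, size=total)
    seqs = []
    for b in range(n_blocks):
        idx = flat[b * config.n_trials:(b + 1) * config.n_trials]
        seqs.append(tuple(OFFERS[i] for i in idx))
    return seqs


def run_miniblock(policy: Callable[[TaskState, Offer], str], spec: MiniblockSpec,
                  config: TaskConfig = TaskConfig(),
                  participant: str = "sim", block: int = 0,
                  ) -> tuple[list[dict], str, float]:
    """Roll a policy through one miniblock.

    Returns the trial records (dicts in the CSV schema), the outcome label
    (``G2``/``G1``/``fail`` from the post-final state at kappa=1) and the
    reward in cents.
    """
    if len(spec.offers) != config.n_trials:
        raise ValueError("offer sequence length must equal n_trials")
    state = TaskState(*spec.initial_pts, trial=1)
    _check_state(state, config)
    records = []
    for t, offer in enumerate(spec.offers, start=1):
        action = policy(state, offer)
        if action not in (ACCEPT, WAIT):
            raise PolicyError(f"policy returned {action!r} at trial {t}")
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
    reward = terminal_reward(state, 1.0, config)
    a_ok = state.pts_a >= config.threshold
    b_ok = state.pts_b >= config.threshold
    outcome = "G2" if (a_ok and b_ok) else ("G1" if (a_ok or b_ok) else "fail")
    return records, outcome, reward


def records_to_frame(records: Iterable[dict]) -> pd.DataFrame:
    return pd.DataFrame(list(records), columns=RECORD_COLUMNS)


def read_records(path) -> pd.DataFrame:
    """Read a trial-record CSV and validate the schema and chaining."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial-record CSV missing columns: {missing}")
    return df[RECORD_COLUMNS]


def write_records(df: pd.DataFrame, path) -> None:
    df[RECORD_COLUMNS].to_csv(path, index=False)


def validate_chaining(df: pd.DataFrame, config: TaskConfig = TaskConfig()) -> None:
    """Check that within each (participant, block) the next-state of every
    trial equals the state of the following trial and matches the offer
    transition. Raises ``ValueError`` on the first violation."""
    for (p, b), g in df.groupby(["participant", "block"], sort=False):
        g = g.sort_values("trial")
        for row in g.itertuples():
            nxt = apply_offer(TaskState(row.pts_a, row.pts_b, row.trial),
                              row.offer, row.response, config)
            if (nxt.pts_a, nxt.pts_b) != (row.pts_a_next, row.pts_b_next):
                raise ValueError(f"broken transition chain at participant={p} "
                                 f"block={b} trial={row.trial}")
        a = g[["pts_a_next", "pts_b_next"]].to_numpy()[:-1]
        s = g[["pts_a", "pts_b"]].to_numpy()[1:]
        if not np.array_equal(a, s):
            raise ValueError(f"records do not chain at participant={p} block={b}")
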