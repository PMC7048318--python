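"""Backward-induction planning over the two-goal task.

The task is a finite-horizon MDP with deterministic transitions and i.i.d.
uniform offers, so the optimal state values satisfy

    V_{T+1}(s) = terminal reward of s,
    Q_t(s, o, a) = gamma * V_{t+1}(s'),      s' = transition(s, o, a),
    V_t(s)      = (1/4) * sum_o max_a Q_t(s, o, a),

iterated from the final trial back to trial 1. ``gamma`` discounts each
backward step (an action t trials before the end is discounted by
gamma**(T-t)); ``kappa`` rescales the two-goal reward to ``10*kappa``.

The differential expected value DEV = Q(g2-action) - Q(g1-action) is the
forward-planning decision signal used by the behavioural choice model: it is
positive when balancing the two point scales is expected to pay off.

Besides the dynamic program this module provides the deterministic optimal
agent, a random reference agent, and two brute-force oracles (explicit
expectimax recursion and 2**T enumeration of action sequences) used to
cross-check the dynamic program.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .task import (ACCEPT, WAIT, OFFERS, OFFER_INDEX, Offer, TaskConfig,
                   TaskState, UndefinedDEV, get_offer, g_actions,
                   terminal_reward)

#: action axis order in Q arrays
A_ACC, A_WAIT = 0, 1

#: Q ties below this magnitude are treated as exact ties (agent waits).
TIE_TOL = 1e-12


def _transition_indices(config: TaskConfig) -> tuple[np.ndarray, np.ndarray]:
    """Next-state index arrays ``ia, ib`` of shape (4, 2, n, n):
    ``ia[o, a]`` maps the point grid to the next A-index under offer o,
    action a, with saturation at the bounds."""
    n = config.n_points
    grid_a, grid_b = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ia = np.empty((4, 2, n, n), dtype=np.intp)
    ib = np.empty((4, 2, n, n), dtype=np.intp)
    for o, offer in enumerate(OFFERS):
        da, db = offer.effect
        ia[o, A_ACC] = np.clip(grid_a + da, 0, n - 1)
        ib[o, A_ACC] = np.clip(grid_b + db, 0, n - 1)
        ia[o, A_WAIT] = grid_a
        ib[o, A_WAIT] = grid_b
    return ia, ib


def _terminal_values(config: TaskConfig, kappas: np.ndarray) -> np.ndarray:
    """Terminal V for a batch of kappa values; shape (B, n, n)."""
    n = config.n_points
    pts = np.arange(config.point_min, config.point_max + 1)
    a_ok = pts[:, None] >= config.threshold
    b_ok = pts[None, :] >= config.threshold
    both = a_ok & b_ok
    one = a_ok ^ b_ok
    v = np.zeros((len(kappas), n, n))
    v += one * config.reward_one
    v += both[None] * (config.reward_both * kappas[:, None, None])
    return v


def values_batched(gammas, kappas, config: TaskConfig = TaskConfig(),
                   derivatives: bool = False):
    """Backward induction for a batch of (gamma, kappa) pairs at once.

    Returns ``V`` of shape (B, T+1, n, n) where axis 1 index ``t`` holds the
    value of trial ``t+1`` (index ``T`` is the post-final slice). With
    ``derivatives=True`` also returns ``dV/dgamma`` and ``dV/dkappa``
    propagated through the recursion (the argmax is held fixed at ties,
    consistent with the wait-on-tie rule).
    """
    gammas = np.atleast_1d(np.asarray(gammas, dtype=float))
    kappas = np.atleast_1d(np.asarray(kappas, dtype=float))
    if gammas.shape != kappas.shape:
        raise ValueError("gammas and kappas must have the same length")
    if np.any((gammas < 0) | (gammas > 1)):
        raise ValueError("gamma must lie in [0, 1]")
    if np.any((kappas <= 0) | (kappas > 2)):
        raise ValueError("kappa must lie in (0, 2]")
    B, T, n = len(gammas), config.n_trials, config.n_points
    ia, ib = _transition_indices(config)
    g = gammas[:, None, None]
    V = np.empty((B, T + 1, n, n))
    V[:, T] = _terminal_values(config, kappas)
    if derivatives:
        dVg = np.zeros_like(V)
        dVk = np.zeros_like(V)
        pts = np.arange(config.point_min, config.point_max + 1)
        both = (pts[:, None] >= config.threshold) & (pts[None, :] >= config.threshold)
        dVk[:, T] = config.reward_both * both
    for t in range(T - 1, -1, -1):
        vnext = V[:, t + 1]
        acc = np.empty((B, 4, n, n))
        for o in range(4):
            q_acc = g * vnext[:, ia[o, A_ACC], ib[o, A_ACC]]
            q_wait = g * vnext[:, ia[o, A_WAIT], ib[o, A_WAIT]]
            take = q_acc > q_wait + TIE_TOL
            acc[:, o] = take
            if o == 0:
                vt = np.where(take, q_acc, q_wait)
            else:
                vt = vt + np.where(take, q_acc, q_wait)
        V[:, t] = vt / 4.0
        if derivatives:
            dg = np.zeros((B, n, n))
            dk = np.zeros((B, n, n))
            for o in range(4):
                take = acc[:, o].astype(bool)
                iacc_a, iacc_b = ia[o, A_ACC], ib[o, A_ACC]
                v_sel = np.where(take, vnext[:, iacc_a, iacc_b], vnext)
                dg_sel = np.where(take, dVg[:, t + 1][:, iacc_a, iacc_b], dVg[:, t + 1])
                dk_sel = np.where(take, dVk[:, t + 1][:, iacc_a, iacc_b], dVk[:, t + 1])
                dg += v_sel + g * dg_sel
                dk += g * dk_sel
            dVg[:, t] = dg / 4.0
            dVk[:, t] = dk / 4.0
    if derivatives:
        return V, dVg, dVk
    return V


@dataclass
class ValueTables:
    """V and Q arrays from backward induction for one (gamma, kappa).

    ``V[t-1]`` holds trial-t values for t = 1..T+1 (the last slice is the
    post-final state in which the terminal reward is paid). ``Q[t-1]`` has
    shape (n, n, 4 offers, 2 actions) with action axis (accept, wait).
    """

    config: TaskConfig
    gamma: float
    kappa: float
    V: np.ndarray
    Q: np.ndarray

    def v(self, trial: int, pts_a: int, pts_b: int) -> float:
        return float(self.V[trial - 1,
                            pts_a - self.config.point_min,
                            pts_b - self.config.point_min])

    def q(self, trial: int, pts_a: int, pts_b: int, offer, action: str) -> float:
        o = OFFER_INDEX[get_offer(offer).label]
        a = A_ACC if action == ACCEPT else A_WAIT
        return float(self.Q[trial - 1,
                            pts_a - self.config.point_min,
                            pts_b - self.config.point_min, o, a])

    def config_hash(self) -> str:
        payload = json.dumps({"config": self.config.__dict__}, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()

    def save(self, path) -> None:
        """Write the arrays to an .npz plus a JSON sidecar recording
        (gamma, kappa, config hash)."""
        np.savez(path, V=self.V, Q=self.Q)
        side = str(path) + ".json" if not str(path).endswith(".npz") \
            else str(path)[:-4] + ".json"
        with open(side, "w") as fh:
            json.dump({"gamma": self.gamma, "kappa": self.kappa,
                       "config": self.config.__dict__,
                       "config_sha1": self.config_hash()}, fh, indent=1)


def backward_induction(config: TaskConfig = TaskConfig(), gamma: float = 1.0,
                       kappa: float = 1.0) -> ValueTables:
    """Exact dynamic program over the full point grid for one (gamma, kappa)."""
    V = values_batched([gamma], [kappa], config)[0]
    T, n = config.n_trials, config.n_points
    ia, ib = _transition_indices(config)
    Q = np.empty((T, n, n, 4, 2))
    for t in range(T):
        for o in range(4):
            for a in (A_ACC, A_WAIT):
                Q[t, :, :, o, a] = gamma * V[t + 1][ia[o, a], ib[o, a]]
    return ValueTables(config=config, gamma=gamma, kappa=kappa, V=V, Q=Q)


def compute_dev(state: TaskState, offer, tables: ValueTables) -> float:
    """DEV = Q(g2-action) - Q(g1-action) for a classifiable mixed trial."""
    offer = get_offer(offer)
    if offer.is_basic:
        raise UndefinedDEV("DEV is only defined for mixed offers")
    g2_act, g1_act = g_actions(state, offer, tables.config)
    return (tables.q(state.trial, state.pts_a, state.pts_b, offer, g2_act)
            - tables.q(state.trial, state.pts_a, state.pts_b, offer, g1_act))


def optimal_action(state: TaskState, offer, tables: ValueTables) -> str:
    """Deterministic optimal agent: accepts basic offers; on mixed offers
    takes the argmax-Q action, waiting on exact ties."""
    offer = get_offer(offer)
    if offer.is_basic:
        return ACCEPT
    qa = tables.q(state.trial, state.pts_a, state.pts_b, offer, ACCEPT)
    qw = tables.q(state.trial, state.pts_a, state.pts_b, offer, WAIT)
    return ACCEPT if qa > qw + TIE_TOL else WAIT


def optimal_policy_table(tables: ValueTables) -> np.ndarray:
    """Boolean accept-table of shape (T, n, n, 4) for the optimal agent."""
    q_acc = tables.Q[..., A_ACC]
    q_wait = tables.Q[..., A_WAIT]
    pol = q_acc > q_wait + TIE_TOL
    for o, offer in enumerate(OFFERS):
        if offer.is_basic:
            pol[..., o] = True
    return pol


def random_agent_action(state: TaskState, offer, rng: np.random.Generator) -> str:
    """Reference agent: always accepts basic offers, guesses on mixed ones."""
    offer = get_offer(offer)
    if offer.is_basic:
        return ACCEPT
    return ACCEPT if rng.random() < 0.5 else WAIT


def simulate_blocks(starts: np.ndarray, offer_idx: np.ndarray,
                    config: TaskConfig, accept_table: np.ndarray | None = None,
                    guess_mixed_rng: np.random.Generator | None = None):
    """Vectorised roll-out of many miniblocks under a deterministic
    accept-table and/or coin-flip mixed-offer guessing.

    ``starts``: (M, 2) initial points; ``offer_idx``: (M, T) offer indices.
    Exactly one of ``accept_table`` (optimal-style agent) or
    ``guess_mixed_rng`` (random agent) decides mixed offers; basic offers
    are always accepted when ``accept_table`` is None.

    Returns ``(A, B, ACC)`` where ``A``/``B`` have shape (M, T+1) holding
    point trajectories (index t = state at trial t+1) and ``ACC`` (M, T)
    the accept decisions.
    """
    M, T = offer_idx.shape
    n = config.n_points
    a = np.asarray(starts[:, 0], dtype=np.intp) - config.point_min
    b = np.asarray(starts[:, 1], dtype=np.intp) - config.point_min
    da = np.array([o.effect[0] for o in OFFERS])
    db = np.array([o.effect[1] for o in OFFERS])
    basic = np.array([o.is_basic for o in OFFERS])
    A = np.empty((M, T + 1), dtype=np.intp)
    Bv = np.empty((M, T + 1), dtype=np.intp)
    ACC = np.empty((M, T), dtype=bool)
    for t in range(T):
        A[:, t] = a
        Bv[:, t] = b
        o = offer_idx[:, t]
        if accept_table is not None:
            acc = accept_table[t, a, b, o]
        else:
            acc = basic[o].copy()
            mixed = ~basic[o]
            if guess_mixed_rng is None:
                raise ValueError("need accept_table or guess_mixed_rng")
            acc[mixed] = guess_mixed_rng.random(int(mixed.sum())) < 0.5
        ACC[:, t] = acc
        a = np.where(acc, np.clip(a + da[o], 0, n - 1), a)
        b = np.where(acc, np.clip(b + db[o], 0, n - 1), b)
    A[:, T] = a
    Bv[:, T] = b
    A += config.point_min
    Bv += config.point_min
    return A, Bv, ACC


def g2_success_probability(tables: ValueTables, initial_pts: tuple[int, int]) -> float:
    """Exact probability that the optimal agent ends with both scales at
    threshold, by forward recursion over the uniform offer distribution."""
    config = tables.config
    T, n = config.n_trials, config.n_points
    ia, ib = _transition_indices(config)
    pol = optimal_policy_table(tables)
    pts = np.arange(config.point_min, config.point_max + 1)
    p = ((pts[:, None] >= config.threshold) &
         (pts[None, :] >= config.threshold)).astype(float)
    for t in range(T - 1, -1, -1):
        nxt = np.zeros((n, n))
        for o in range(4):
            take = pol[t, :, :, o]
            nxt += np.where(take, p[ia[o, A_ACC], ib[o, A_ACC]], p)
        p = nxt / 4.0
    return float(p[initial_pts[0] - config.point_min,
                   initial_pts[1] - config.point_min])


MAX_EXPECTIMAX_HORIZON = 8


def expectimax_oracle(state: TaskState, trials_left: int, gamma: float = 1.0,
                      kappa: float = 1.0, mode: str = "value",
                      config: TaskConfig = TaskConfig()) -> float:
    """Explicit recursion over all offer outcomes and both actions.

    ``mode="value"`` returns the optimal expected (discounted) reward;
    ``mode="g2_probability"`` the probability that both thresholds hold in
    the post-final state under the reward-optimal policy (basic offers
    accepted, ties broken towards waiting). Refuses horizons beyond
    ``MAX_EXPECTIMAX_HORIZON`` — the recursion is meant as a small-scale
    oracle, not a planner.
    """
    if trials_left > MAX_EXPECTIMAX_HORIZON:
        raise ValueError(f"horizon {trials_left} too large for explicit enumeration")
    if mode not in ("value", "g2_probability"):
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = config.point_min, config.point_max
    thr = config.threshold

    @lru_cache(maxsize=None)
    def value(a: int, b: int, k: int) -> float:
        if k == 0:
            return terminal_reward(TaskState(a, b), kappa, config)
        tot = 0.0
        for offer in OFFERS:
            da, db = offer.effect
            na = min(max(a + da, lo), hi)
            nb = min(max(b + db, lo), hi)
            q_acc = gamma * value(na, nb, k - 1)
            q_wait = gamma * value(a, b, k - 1)
            tot += max(q_acc, q_wait)
        return tot / 4.0

    @lru_cache(maxsize=None)
    def g2prob(a: int, b: int, k: int) -> float:
        if k == 0:
            return 1.0 if (a >= thr and b >= thr) else 0.0
        tot = 0.0
        for offer in OFFERS:
            da, db = offer.effect
            na = min(max(a + da, lo), hi)
            nb = min(max(b + db, lo), hi)
            if offer.is_basic:
                take = True
            else:
                q_acc = gamma * value(na, nb, k - 1)
                q_wait = gamma * value(a, b, k - 1)
                take = q_acc > q_wait + TIE_TOL
            tot += g2prob(na, nb, k - 1) if take else g2prob(a, b, k - 1)
        return tot / 4.0

    fn = value if mode == "value" else g2prob
    return fn(state.pts_a, state.pts_b, trials_left)


def exhaustive_feasibility_oracle(spec, config: TaskConfig = TaskConfig()
                                  ) -> tuple[bool, float]:
    """Enumerate all 2**T accept/wait sequences against the known offer
    sequence; return whether a two-goal success is reachable and the maximum
    terminal reward (kappa = 1)."""
    T = config.n_trials
    if T > 20:
        raise ValueError("horizon too large for 2**T enumeration")
    n_seq = 1 << T
    bits = (np.arange(n_seq)[:, None] >> np.arange(T)) & 1
    a = np.full(n_seq, spec.initial_pts[0], dtype=np.int64)
    b = np.full(n_seq, spec.initial_pts[1], dtype=np.int64)
    for t, offer in enumerate(spec.offers):
        da, db = get_offer(offer).effect
        acc = bits[:, t].astype(bool)
        a = np.where(acc, np.clip(a + da, config.point_min, config.point_max), a)
        b = np.where(acc, np.clip(b + db, config.point_min, config.point_max), b)
    a_ok = a >= config.threshold
    b_ok = b >= config.threshold
    g2 = bool(np.any(a_ok & b_ok))
    reward = np.where(a_ok & b_ok, config.reward_both,
                      np.where(a_ok | b_ok, config.reward_one, 0.0))
    return g2, float(reward.max())
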