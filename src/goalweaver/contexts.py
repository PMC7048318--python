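"""Vectorised trial-context extraction from trial-record tables.

Both the behavioural summaries and the hierarchical likelihood need, for
every classifiable mixed-offer trial, the indices of the two candidate
next states (under the g2- and the g1-action) so that

    DEV = gamma * (V[s'_g2] - V[s'_g1])

can be gathered from a value table in one shot. This module turns a
trial-record DataFrame into flat numpy arrays once, so the per-trial
geometry is never recomputed inside optimisation loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import ACCEPT, OFFERS, OFFER_INDEX, TaskConfig

_EFFECTS = np.array([o.effect for o in OFFERS])
_IS_BASIC = np.array([o.is_basic for o in OFFERS])


@dataclass
class ContextSet:
    """Per-row geometry of a trial-record table (aligned with df order)."""

    trial: np.ndarray        # 1-based trial index
    offer_idx: np.ndarray    # 0..3 in canonical offer order
    basic: np.ndarray        # basic-offer rows
    defined: np.ndarray      # classifiable mixed rows
    post_g2: np.ndarray      # both scales at threshold before responding
    y_g2: np.ndarray         # observed response was the g2 action (defined rows)
    ia_g2: np.ndarray        # next-state A index under the g2 action
    ib_g2: np.ndarray
    ia_g1: np.ndarray
    ib_g1: np.ndarray
    basic_wait: np.ndarray   # impossible-under-the-model rows
    config: TaskConfig

    def dev(self, V: np.ndarray, gamma: float | np.ndarray) -> np.ndarray:
        """Gather DEV for every row (meaningful on ``defined`` rows only).

        ``V`` is a value array of shape (T+1, n, n) whose slice ``t`` holds
        trial-(t+1) values, as produced by backward induction.
        """
        v2 = V[self.trial, self.ia_g2, self.ib_g2]
        v1 = V[self.trial, self.ia_g1, self.ib_g1]
        return gamma * (v2 - v1)


def extract_contexts(df: pd.DataFrame, config: TaskConfig = TaskConfig()) -> ContextSet:
    o_idx = df["offer"].map(OFFER_INDEX).to_numpy(dtype=np.intp)
    a = df["pts_a"].to_numpy(dtype=np.intp) - config.point_min
    b = df["pts_b"].to_numpy(dtype=np.intp) - config.point_min
    trial = df["trial"].to_numpy(dtype=np.intp)
    accept = (df["response"] == ACCEPT).to_numpy()

    n = config.n_points
    da = _EFFECTS[o_idx, 0]
    db = _EFFECTS[o_idx, 1]
    ia_acc = np.clip(a + da, 0, n - 1)
    ib_acc = np.clip(b + db, 0, n - 1)
    d_acc = np.abs(ia_acc - ib_acc)
    d_wait = np.abs(a - b)

    basic = _IS_BASIC[o_idx]
    defined = ~basic & (d_acc != d_wait)
    g2_is_accept = d_acc < d_wait

    ia_g2 = np.where(g2_is_accept, ia_acc, a)
    ib_g2 = np.where(g2_is_accept, ib_acc, b)
    ia_g1 = np.where(g2_is_accept, a, ia_acc)
    ib_g1 = np.where(g2_is_accept, b, ib_acc)

    thr = config.threshold - config.point_min
    post_g2 = (a >= thr) & (b >= thr)
    y_g2 = accept == g2_is_accept
    basic_wait = basic & ~accept
    return ContextSet(trial=trial, offer_idx=o_idx, basic=basic,
                      defined=defined, post_g2=post_g2, y_g2=y_g2,
                      ia_g2=ia_g2, ib_g2=ib_g2, ia_g1=ia_g1, ib_g1=ib_g1,
                      basic_wait=basic_wait, config=config)
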