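"""Synthetic patient-episode generator.

Emulates the hospital admissions underlying the model's aggregate inputs:
each episode is a colorectal-cancer surgical admission with a surgery
type (colon vs rectal, Bernoulli on the colon share), at most one
adverse event (categorical over the six mutually exclusive event
branches plus "none"), and a right-skewed episode cost drawn from a
gamma distribution around the AR-DRG mean of the matching
(surgery type, complicated?) cell.

This is a stand-in data-generating process for testing the pipeline
end-to-end — rate estimation, evidence pooling, and the decision model
can be exercised against a known truth with no external data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evidence import EVENT_TYPES
from .model import BRANCHES, branch_probabilities
from .parameters import ParameterSet, validate
from .uncertainty import gamma_from_mean_cv

#: Episode-table columns, fixed order.
EPISODE_COLUMNS = ("patient_id", "surgery_type", "event", "cost")

_EVENT_LABELS = EVENT_TYPES + ("none",)


def simulate_episodes(
    true_params: ParameterSet, n: int, seed: int, reduction: float = 0.0
) -> pd.DataFrame:
    """Simulate ``n`` patient episodes under the given truth parameters.

    Events follow ``branch_probabilities(rates, reduction)``; the cost of
    an episode is gamma-distributed with mean equal to the DRG cost of
    its (surgery type, complicated?) cell and cv
    ``cost_range_fraction / 1.96``.  Seeded and reproducible.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    findings = validate(true_params)
    if findings:
        raise ValueError("invalid parameters: " + "; ".join(findings))
    rng = np.random.default_rng(seed)

    rates = [true_params.event_rates[e].mean for e in EVENT_TYPES]
    probs = np.array(branch_probabilities(rates, reduction))
    surgery = np.where(rng.random(n) < true_params.colon_share.base, "colon", "rectal")
    event_idx = rng.choice(len(BRANCHES), size=n, p=probs)
    event = np.array(_EVENT_LABELS, dtype=object)[event_idx]

    cv = true_params.cost_range_fraction / 1.96
    cost = np.empty(n, dtype=float)
    complicated = event != "none"
    for s in ("colon", "rectal"):
        for comp in (True, False):
            mask = (surgery == s) & (complicated == comp)
            k = int(mask.sum())
            if k == 0:
                continue
            mean = true_params.drg_costs[f"{s}_comp" if comp else f"{s}_uncomp"]
            if cv > 0:
                cost[mask] = gamma_from_mean_cv(mean, cv).sample(rng, size=k)
            else:
                cost[mask] = mean

    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "surgery_type": surgery,
            "event": event,
            "cost": cost,
        }
    )


def estimate_rates(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-event-category proportions with binomial standard errors.

    Returns one row per category (six events plus "none") with columns
    count, rate and se, where se = sqrt(p_hat (1 - p_hat) / n).
    """
    if len(episodes) == 0:
        raise ValueError("cannot estimate rates from an empty episode table")
    n = len(episodes)
    counts = episodes["event"].value_counts()
    rows = []
    for label in _EVENT_LABELS:
        c = int(counts.get(label, 0))
        p = c / n
        rows.append({"event": label, "count": c, "rate": p, "se": np.sqrt(p * (1 - p) / n)})
    return pd.DataFrame(rows)


def simulate_pre_post(
    true_params: ParameterSet, reduction: float, n_pre: int, n_post: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pre/post-audit episode sets (post rates scaled by 1 - reduction)."""
    if n_pre < 1 or n_post < 1:
        raise ValueError("n_pre and n_post must be >= 1")
    pre = simulate_episodes(true_params, n_pre, seed=seed, reduction=0.0)
    post = simulate_episodes(true_params, n_post, seed=seed + 1, reduction=reduction)
    return pre, post


def estimated_reduction(pre: pd.DataFrame, post: pd.DataFrame) -> float:
    """Observed relative reduction in the any-event rate, pre vs post."""
    p_pre = float((pre["event"] != "none").mean())
    p_post = float((post["event"] != "none").mean())
    if p_pre == 0.0:
        raise ValueError("pre-audit any-event rate is zero; reduction undefined")
    return 1.0 - p_post / p_pre
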