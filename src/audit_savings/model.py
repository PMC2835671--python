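"""Two-arm decision tree for a surgical self-audit program vs usual practice.

Structure
---------
Each arm splits by surgery type (colon vs rectal, weighted by the colon
share of the casemix), then by a single chance node with SEVEN mutually
exclusive branches: the six adverse-event categories plus "no event".
Branch probabilities are additive (no concurrent complications in the
generative model).  Every adverse-event branch is costed at the
"with complications" AR-DRG for that surgery type; the no-event branch at
the "no complications" AR-DRG.  The audit arm multiplies every event rate
by ``(1 - reduction_fraction)`` and adds a per-case administration cost
(software subscription amortized over the annual caseload plus data entry
per audit).  Rolling back sums probability x cost over all 14 leaves; the
incremental saving is the usual-practice expectation minus the audit one.

The analytic horizon is 12 months and no discounting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .evidence import EVENT_TYPES
from .parameters import ParameterSet, validate

#: Branch order at each chance node: the six events, then "no_event".
BRANCHES: tuple[str, ...] = EVENT_TYPES + ("no_event",)

Arm = Literal["usual", "audit"]


class ModelStructureError(ValueError):
    """The tree cannot be built (e.g. reduced rates sum to >= 1)."""


@dataclass(frozen=True)
class LeafContribution:
    """One (surgery type x branch) leaf of the rolled-back tree."""

    surgery_type: str
    branch: str
    weight: float        # casemix weight of the surgery type
    probability: float   # branch probability within the surgery type
    cost: float          # AUD for this leaf
    product: float       # weight * probability * cost


@dataclass(frozen=True)
class ArmCostBreakdown:
    """Rolled-back expected per-case cost of one strategy arm."""

    arm: Arm
    expected_cost: float
    p_any_event: float
    branch_contributions: tuple[LeafContribution, ...]
    admin_cost_per_case: float

    @property
    def base_cost(self) -> float:
        """Expected episode cost before audit administration."""
        return sum(leaf.product for leaf in self.branch_contributions)

    def to_frame(self) -> pd.DataFrame:
        """One row per leaf, ready for CSV export."""
        df = pd.DataFrame([vars(leaf) for leaf in self.branch_contributions])
        df.insert(0, "arm", self.arm)
        return df


def branch_probabilities(
    event_rates: Sequence[float],
    reduction: float,
    *,
    death_attrib_fraction: float | None = None,
) -> tuple[float, ...]:
    """Branch probabilities for one chance node, in ``BRANCHES`` order.

    Each of the six event rates is multiplied by ``(1 - reduction)``; the
    seventh entry is the no-event complement.  When
    ``death_attrib_fraction`` is given, the reduction applied to the
    30-day death branch is scaled by that fraction (only deaths
    attributable to complications are preventable); the base model leaves
    it off and reduces the full death rate.
    """
    if len(event_rates) != len(EVENT_TYPES):
        raise ValueError(f"expected {len(EVENT_TYPES)} event rates, got {len(event_rates)}")
    if not (0.0 <= reduction <= 1.0):
        raise ValueError(f"reduction must be in [0, 1], got {reduction}")
    reduced = []
    for event, rate in zip(EVENT_TYPES, event_rates):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{event}: rate {rate} outside [0, 1]")
        eff = reduction
        if event == "death_30d" and death_attrib_fraction is not None:
            eff = reduction * death_attrib_fraction
        reduced.append(rate * (1.0 - eff))
    total = sum(reduced)
    if total >= 1.0:
        raise ModelStructureError(f"reduced event rates sum to {total} >= 1")
    return tuple(reduced) + (1.0 - total,)


def admin_cost_per_case(
    software_cost_per_year: float, annual_caseload: int, data_entry_cost_per_audit: float
) -> float:
    """Per-case audit administration cost.

    The annual software subscription is amortized over the surgeon's
    annual caseload; data entry is priced per audited case.
    """
    if annual_caseload < 1:
        raise ValueError(f"annual_caseload must be >= 1, got {annual_caseload}")
    return software_cost_per_year / annual_caseload + data_entry_cost_per_audit


def expected_arm_cost(params: ParameterSet, arm: Arm) -> ArmCostBreakdown:
    """Roll back one arm to its expected per-case cost (2009 AUD)."""
    if arm not in ("usual", "audit"):
        raise ValueError(f"arm must be 'usual' or 'audit', got {arm!r}")
    findings = validate(params)
    if findings:
        raise ValueError("invalid parameters: " + "; ".join(findings))

    reduction = params.reduction_fraction if arm == "audit" else 0.0
    attrib = params.death_attrib_fraction if params.apply_death_attribution else None
    rates = [params.event_rates[e].mean for e in EVENT_TYPES]
    probs = branch_probabilities(rates, reduction, death_attrib_fraction=attrib)

    admin = (
        admin_cost_per_case(
            params.audit_software_cost_per_year,
            params.annual_caseload,
            params.data_entry_cost_per_audit,
        )
        if arm == "audit"
        else 0.0
    )

    weights = {"colon": params.colon_share.base, "rectal": 1.0 - params.colon_share.base}
    leaves: list[LeafContribution] = []
    for surgery, weight in weights.items():
        comp = params.drg_costs[f"{surgery}_comp"]
        uncomp = params.drg_costs[f"{surgery}_uncomp"]
        for branch, p in zip(BRANCHES, probs):
            cost = uncomp if branch == "no_event" else comp
            leaves.append(
                LeafContribution(
                    surgery_type=surgery,
                    branch=branch,
                    weight=weight,
                    probability=p,
                    cost=cost,
                    product=weight * p * cost,
                )
            )
    expected = sum(leaf.product for leaf in leaves) + admin
    return ArmCostBreakdown(
        arm=arm,
        expected_cost=expected,
        p_any_event=1.0 - probs[-1],
        branch_contributions=tuple(leaves),
        admin_cost_per_case=admin,
    )


def incremental_saving(params: ParameterSet) -> float:
    """Per-case saving: usual-practice cost minus self-audit cost.

    Negative when the effect size is small enough that audit
    administration costs dominate.  Computed as the difference of the
    pre-admin episode expectations minus the audit admin cost, so that at
    zero reduction the saving is exactly the negated admin cost.
    """
    usual = expected_arm_cost(params, "usual")
    audit = expected_arm_cost(params, "audit")
    return (usual.base_cost - audit.base_cost) - audit.admin_cost_per_case + usual.admin_cost_per_case


def rollback_report(params: ParameterSet) -> pd.DataFrame:
    """Both arms' leaf tables stacked, for CSV/JSON export."""
    return pd.concat(
        [expected_arm_cost(params, "usual").to_frame(), expected_arm_cost(params, "audit").to_frame()],
        ignore_index=True,
    )
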