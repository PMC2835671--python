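"""Deterministic roll-back of the two-arm decision tree at the base case.

Rolls back 'usual practice' and 'self-audit' (50% reduction in adverse
event rates, admin costs amortized over 20 cases/year) to expected
per-case episode costs and the incremental saving, and writes the full
leaf table to results/rollback.csv.
"""

import json
from pathlib import Path

from audit_savings.model import expected_arm_cost, incremental_saving, rollback_report
from audit_savings.parameters import default_parameters

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    params = default_parameters()
    usual = expected_arm_cost(params, "usual")
    audit = expected_arm_cost(params, "audit")
    saving = incremental_saving(params)

    print(f"usual practice expected cost per case : ${usual.expected_cost:,.0f}")
    print(f"self-audit expected cost per case     : ${audit.expected_cost:,.0f}")
    print(f"  audit administration per case       : ${audit.admin_cost_per_case:,.2f}")
    print(f"  any-event probability usual / audit : {usual.p_any_event:.3f} / {audit.p_any_event:.3f}")
    print(f"deterministic per-case saving         : ${saving:,.0f}")

    RESULTS.mkdir(exist_ok=True)
    rollback_report(params).to_csv(RESULTS / "rollback.csv", index=False)
    (RESULTS / "rollback_summary.json").write_text(
        json.dumps(
            {
                "usual_cost": usual.expected_cost,
                "audit_cost": audit.expected_cost,
                "admin_cost_per_case": audit.admin_cost_per_case,
                "saving": saving,
            },
            indent=2,
        )
    )
    print(f"wrote {RESULTS / 'rollback.csv'} and rollback_summary.json")


if __name__ == "__main__":
    main()
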