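"""One-way sensitivity analyses on all ranged cost and rate parameters.

Varies each parameter across its plausible range (event rates and colon
share) or a symmetric ±30% band (the four DRG costs) with everything else
at base, ranks parameters by the swing they induce in the audit-arm
expected cost, and writes results/tornado.csv plus a tornado figure.
"""

from pathlib import Path

import pandas as pd

from audit_savings.model import expected_arm_cost
from audit_savings.parameters import default_parameters
from audit_savings.uncertainty import tornado, tornado_figure

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    params = default_parameters()
    entries = tornado(params, output="audit_cost")
    base = expected_arm_cost(params, "audit").expected_cost
    print(f"audit-arm base-case expected cost: ${base:,.0f}")
    print("one-way swings (audit-arm expected cost):")
    for e in entries:
        print(
            f"  {e.parameter:<20} ${min(e.output_low, e.output_high):>9,.0f} - "
            f"${max(e.output_low, e.output_high):>9,.0f}  (swing ${e.swing:,.0f})"
        )

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "input_low": e.input_low,
                "input_high": e.input_high,
                "output_low": e.output_low,
                "output_high": e.output_high,
                "swing": e.swing,
            }
            for e in entries
        ]
    ).to_csv(RESULTS / "tornado.csv", index=False)
    tornado_figure(entries, base, RESULTS / "tornado.png")
    print(f"wrote {RESULTS / 'tornado.csv'} and tornado.png")
    print(
        "the two uncomplicated surgery costs dominate: they are weighted by the "
        "85.1% of audited cases with no adverse event."
    )


if __name__ == "__main__":
    main()
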