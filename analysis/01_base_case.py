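#!/usr/bin/env python
"""Base case: 40-year cohort outcomes for all five arms, both perspectives.

Runs the published base case (with the packaged synthetic stand-ins for the
national mortality and revision-risk tables), writes one results table per
costing perspective under results/, and prints the headline comparison:
discounted QALYs, discounted costs, ICER versus standard of care, and
knee-replacement (TKR) / revision (TKRR) operations per 1,000 patients.
"""

import logging
from pathlib import Path

from oamarkov.analyses import relative_reduction, run_all, write_results_csv
from oamarkov.parameters import paper_baseline
from oamarkov.states import ARMS

logging.basicConfig(level=logging.WARNING)
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    for perspective in ("hospital", "societal"):
        df = run_all({arm: paper_baseline(perspective, arm) for arm in ARMS})
        write_results_csv(df, OUT / f"base_case_{perspective}.csv")
        print(f"\n=== Base case, {perspective} perspective ===")
        print(df.to_string(index=False,
                           float_format=lambda x: f"{x:,.2f}"))
        soc = df[df.arm == "SoC"].iloc[0]
        trt = df[df.arm != "SoC"].iloc[0]
        print(f"TKR reduction vs standard of care: "
              f"{relative_reduction(trt.tkr_per_1000, soc.tkr_per_1000):.1f}% "
              f"({trt.tkr_per_1000} vs {soc.tkr_per_1000} per 1,000)")
        print(f"TKRR reduction vs standard of care: "
              f"{relative_reduction(trt.tkrr_per_1000, soc.tkrr_per_1000):.1f}% "
              f"({trt.tkrr_per_1000} vs {soc.tkrr_per_1000} per 1,000)")
    print(f"\nTables written to {OUT}")


if __name__ == "__main__":
    main()
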