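#!/usr/bin/env python
"""One-way sensitivity: tornado tables for every arm and perspective.

Sweeps each bounded input between its published 95% CI (or +/-20% of base),
re-running the full cohort model each time, and ranks parameters by the
width of the discounted per-patient cost range.  Writes one ranked CSV per
arm/perspective and prints the top-10 cost drivers.
"""

import logging
from pathlib import Path

from oamarkov.analyses import one_way_sensitivity, write_tornado_csv
from oamarkov.parameters import paper_baseline
from oamarkov.states import ARMS

logging.basicConfig(level=logging.WARNING)
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    for perspective in ("hospital", "societal"):
        for arm in ARMS:
            table = one_way_sensitivity(paper_baseline(perspective, arm),
                                        arm, perspective)
            write_tornado_csv(table, OUT / f"tornado_{arm}_{perspective}.csv")
            print(f"\nTop 10 cost drivers — {arm}, {perspective}")
            for rank, e in table.ranked()[:10]:
                print(f"{rank:>2}  {e.parameter:<24} "
                      f"range {e.range:>12,.2f} EUR")
    print(f"\nTables written to {OUT}")


if __name__ == "__main__":
    main()
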