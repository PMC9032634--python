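#!/usr/bin/env python
"""SAMI Code of Practice comparator: P90 and exposure category per HEG.

Reads the fixture measurements written by 01_build_fixtures.py, computes the
empirical 90th percentile of each HEG's current campaign, classifies it
against the 2 mg/m3 OEL, and writes results/sami.csv.  The parametric
(normal / lognormal) P90 estimates are included for comparison: the three
estimators can disagree enough to move a HEG across a category boundary,
which is one motivation for replacing the point estimate with a posterior.
"""

from pathlib import Path

import pandas as pd

from hegbayes import DEFAULT_OEL, read_measurements, sami_assess

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_measurements(ROOT / "fixtures" / "measurements.csv")
    by_heg: dict = {}
    for r in records:
        if r.campaign == "current":
            by_heg.setdefault(r.heg_id, []).append(r)

    rows = []
    for heg in sorted(by_heg):
        row = {"heg_id": heg}
        for method in ("empirical", "normal", "lognormal"):
            result = sami_assess(by_heg[heg], oel=DEFAULT_OEL, method=method)
            row[f"p90_{method}"] = round(result.p90, 3)
            row[f"category_{method}"] = result.category
        rows.append(row)
    frame = pd.DataFrame(rows)
    out = ROOT / "sami.csv"
    frame.to_csv(out, index=False)
    print(frame.to_string(index=False))
    n_compliant = int((frame["category_empirical"] < 4).sum())
    print(
        f"\n{n_compliant}/9 HEGs below the OEL by the empirical P90 "
        f"(category < 4); wrote {out}"
    )


if __name__ == "__main__":
    main()
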