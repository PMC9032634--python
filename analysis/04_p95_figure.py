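#!/usr/bin/env python
"""P95 comparison figure: posterior median and 95% CrI per HEG and regime.

Reads results/study/posterior_summaries.csv (written by 03_fit_bayesian.py)
and draws the median +/- CrI of the posterior P95 for both prior regimes
against the OEL reference line, the visual summary of the compliance story:
every HEG's P95 sits above the 2 mg/m3 limit in both regimes, with the
non-informative intervals generally wider.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from hegbayes import DEFAULT_OEL

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    frame = pd.read_csv(ROOT / "study" / "posterior_summaries.csv")
    hegs = sorted(frame["heg_id"].unique())
    fig, ax = plt.subplots(figsize=(9, 5))
    style = {
        "non_informative": (-0.12, "tab:blue"),
        "informative": (0.12, "tab:orange"),
    }
    for regime, (offset, color) in style.items():
        sub = frame[frame["regime"] == regime].set_index("heg_id").loc[hegs]
        x = [i + offset for i in range(len(hegs))]
        ax.errorbar(
            x,
            sub["p95_median"],
            yerr=[
                sub["p95_median"] - sub["p95_cri_lower"],
                sub["p95_cri_upper"] - sub["p95_median"],
            ],
            fmt="o",
            capsize=3,
            color=color,
            label=regime.replace("_", "-"),
        )
    ax.axhline(DEFAULT_OEL, color="red", linestyle="--",
               label=f"OEL = {DEFAULT_OEL} mg/m3")
    ax.set_xticks(range(len(hegs)))
    ax.set_xticklabels(hegs, rotation=45, ha="right")
    ax.set_ylabel("posterior P95 (mg/m3), median and 95% CrI")
    ax.legend()
    fig.tight_layout()
    out = ROOT / "p95_comparison.png"
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
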