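#!/usr/bin/env python
"""Calibrate the high/low GFP threshold from the control wells.

Reads the well summaries written by step 01, pools the mean log10 GFP of
the retained NOR00 (positive) and WT (negative) control wells, and finds
the exact minimizer of the mean wrong-direction distance.  With the
generator's two-log-unit band gap the controls separate perfectly, so
the cost is zero and the threshold is the midpoint of the flat interval.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from yeastgates.calibration import ControlSet, optimize_threshold

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.parse_args()

    df = pd.read_csv(RESULTS / "well_summaries.tsv", sep="\t")
    df = df[df["retained"]]
    controls = ControlSet(
        tuple(df.loc[df["strain"] == "NOR00", "mean_log_gfp"]),
        tuple(df.loc[df["strain"] == "WT", "mean_log_gfp"]),
    )
    res = optimize_threshold(controls)
    payload = {
        "threshold": res.threshold,
        "cost": res.cost,
        "interval": list(res.minimizing_interval),
        "n_pos": res.n_pos,
        "n_neg": res.n_neg,
    }
    (RESULTS / "threshold.json").write_text(json.dumps(payload, indent=2))
    print(
        f"threshold {res.threshold:.3f} log10 a.u. "
        f"(~{10 ** res.threshold:.0f} a.u.), cost {res.cost:.4f}"
    )
    print(f"flat interval [{res.minimizing_interval[0]:.3f}, {res.minimizing_interval[1]:.3f}]")
    print(f"wrote {RESULTS / 'threshold.json'}")


if __name__ == "__main__":
    main()
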