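#!/usr/bin/env python
"""Plate-reader growth and cross-modality consistency analyses.

Shows the dilution arithmetic of the protocol, the initial-vs-final OD
correlation (pooled and with a deliberately pathological anti-correlated
batch to demonstrate flagging), the diminishing-returns relationship of
final OD on target OD, and the agreement between plate-reader bulk GFP
and flow-cytometry per-cell GFP scaled by density.
"""

import argparse
import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from yeastgates import viz
from yeastgates.gating import GateConfig, gate_and_summarize
from yeastgates.plate_reader import (
    PlateReaderRecord,
    dilution_plan,
    fc_pr_consistency,
    od_growth_correlation,
)
from yeastgates.synthetic_data import benchmark_campaign, simulate_campaign

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    media, fold = dilution_plan(1.0, 0.01, culture_volume=10.0)
    print(f"dilution example: OD 1.0 -> 0.01 is culture:total 1:{fold:.0f} "
          f"({media:.0f} ul media per 10 ul culture)")

    # smaller event tables: the plate-reader quantities don't need 30k events
    cfg = dataclasses.replace(benchmark_campaign(args.seed), events_per_well=2_000)
    ds = simulate_campaign(cfg)

    pooled = od_growth_correlation(ds.plate_reader)
    print(f"initial-vs-final OD correlation (pooled): rho = {pooled['rho'].iloc[0]:.2f}")

    # final OD rises with target OD at a decreasing rate
    by_target = (
        pd.DataFrame(
            {
                "target_od": [r.condition.target_od for r in ds.plate_reader],
                "final_od": [r.final_od for r in ds.plate_reader],
            }
        )
        .groupby("target_od")["final_od"]
        .median()
    )
    by_target.to_csv(RESULTS / "final_od_by_target.tsv", sep="\t")
    print("median final OD by target OD:")
    for t, v in by_target.items():
        print(f"  D={t:g}: {v:.3f}")

    # pathological batch: final OD inverted -> negative rho must be flagged
    bad = [
        PlateReaderRecord(r.well_id, r.initial_od, max(2.2 - r.final_od, 0.01),
                          r.bulk_gfp, strain_label=r.strain_label)
        for r in ds.plate_reader[:100]
    ]
    flagged = od_growth_correlation(bad)
    print(
        f"planted pathological batch: rho = {flagged['rho'].iloc[0]:.2f}, "
        f"anomalous={bool(flagged['anomalous'].iloc[0])}"
    )

    gate = GateConfig(min_gated_events=500)
    summaries = [gate_and_summarize(t, gate) for t in ds.events.values()]
    rep = fc_pr_consistency(ds.plate_reader, [s for s in summaries if s.retained])
    rep.table.to_csv(RESULTS / "fc_pr_consistency.tsv", sep="\t", index=False)
    print(
        f"bulk GFP vs OD x per-cell GFP: r = {rep.r:.3f}, "
        f"{len(rep.outlier_wells)} outlier wells"
    )
    viz.od_scatter(ds.plate_reader, RESULTS / "od_growth.png")
    print(f"wrote {RESULTS / 'fc_pr_consistency.tsv'}")


if __name__ == "__main__":
    main()
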