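#!/usr/bin/env python
"""Score replicate, strain and circuit correctness against the threshold.

Reads the well summaries (step 01) and the calibrated threshold (step
02), classifies every retained replicate, tabulates per-strain
proportion-correct with the >90% (green) / <50% (gray) shading, applies
the min-over-inputs circuit rule, and reports the effective Boolean
function of failing circuits.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from yeastgates.circuit_model import GrowthCondition, parse_strain_label
from yeastgates.correctness import score_circuits, score_strains, shade_counts, summarize_campaign
from yeastgates.gating import WellSummary

RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_wells() -> list[WellSummary]:
    df = pd.read_csv(RESULTS / "well_summaries.tsv", sep="\t")
    wells = []
    for r in df.itertuples():
        cond = GrowthCondition(r.temperature_C, r.overnight_hours, r.medium, r.target_od)
        wells.append(
            WellSummary(
                r.well_id, r.strain, r.n_raw, r.n_gated, r.mean_log_gfp,
                r.sd_log_gfp, bool(r.retained), condition=cond,
                plate_id=r.plate_id, strain=parse_strain_label(r.strain),
            )
        )
    return [w for w in wells if w.retained]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.parse_args()

    wells = load_wells()
    threshold = json.loads((RESULTS / "threshold.json").read_text())["threshold"]

    table_all = summarize_campaign(wells, threshold, "all-conditions")
    table_std = summarize_campaign(wells, threshold, "standard-conditions")
    table_all.to_csv(RESULTS / "strain_correctness_all.tsv", sep="\t", index=False)
    table_std.to_csv(RESULTS / "strain_correctness_standard.tsv", sep="\t", index=False)

    circuits = score_circuits(score_strains(wells, threshold))
    payload = {
        c.gate_name: {
            "p_correct": c.p_correct,
            "effective_function": c.effective_function,
        }
        for c in circuits
    }
    (RESULTS / "circuit_scores.json").write_text(json.dumps(payload, indent=2))

    counts = shade_counts(table_all)
    print(f"threshold {threshold:.3f} log10 a.u.")
    print(
        f"all conditions: {counts['green']} of {counts['total']} strains green "
        f"(>90% correct), {counts['gray']} gray (<50%)"
    )
    for c in circuits:
        note = f" -> behaves as {c.effective_function}" if c.effective_function != c.gate_name else ""
        print(f"  {c.gate_name:5s} circuit p_correct = {c.p_correct:.2f}{note}")
    print(f"wrote {RESULTS / 'strain_correctness_all.tsv'}")


if __name__ == "__main__":
    main()
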