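"""Replicate, strain and circuit correctness against the calibrated threshold.

A retained replicate (well) is correct when its mean log10 GFP falls on
the side of the threshold its strain's truth table dictates; a strain's
score is the proportion of its retained replicates that are correct,
and a circuit's score is the minimum over its four input strains — a
gate that fails even one input row is computing a different Boolean
function, and the "effective function" it does compute is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .circuit_model import GATE_NAMES, GATES, INPUT_PAIRS
from .gating import WellSummary

GREEN_MIN = 0.9  # shading: > 90% correct
GRAY_MAX = 0.5  # shading: < 50% correct

Shade = Literal["green", "none", "gray"]


@dataclass(frozen=True)
class StrainScore:
    strain_label: str
    n: int
    n_correct: int

    @property
    def p_correct(self) -> float:
        return self.n_correct / self.n if self.n else math.nan

    @property
    def shade(self) -> Shade:
        p = self.p_correct
        if math.isnan(p):
            return "none"
        if p > GREEN_MIN:
            return "green"
        if p < GRAY_MAX:
            return "gray"
        return "none"


@dataclass(frozen=True)
class CircuitScore:
    gate_name: str
    per_input: tuple[StrainScore, ...]  # ordered 00, 01, 10, 11
    complete: bool

    @property
    def p_correct(self) -> float:
        if not self.complete:
            return math.nan
        return min(s.p_correct for s in self.per_input)

    @property
    def effective_function(self) -> str | None:
        """Name of the Boolean function this circuit actually computes,
        judged per input by the majority replicate output: one of the six
        gates, ``CONST0``/``CONST1`` (e.g. a NAND whose 11 input fails
        high behaves as constant-high), or ``None`` when nothing standard
        matches or a score is undefined."""
        if not self.complete or any(math.isnan(s.p_correct) for s in self.per_input):
            return None
        gate = GATES[self.gate_name]
        observed = {}
        for pair, score in zip(INPUT_PAIRS, self.per_input):
            want = gate.truth_table[pair]
            observed[pair] = want if score.p_correct >= 0.5 else 1 - want
        for name, g in GATES.items():
            if all(g.truth_table[p] == observed[p] for p in INPUT_PAIRS):
                return name
        if len(set(observed.values())) == 1:
            return f"CONST{observed[INPUT_PAIRS[0]]}"
        return None


Statistic = Literal["mean_of_log", "log_of_mean"]


def classify_replicate(
    well: WellSummary, threshold: float, statistic: Statistic = "mean_of_log"
) -> bool:
    """Is this retained replicate's output on the expected side?

    The default well statistic is the mean of log10 GFP; the log of the
    arithmetic-mean GFP is available as ``statistic="log_of_mean"``.  A
    value exactly at the threshold classifies as high.
    """
    if not well.retained:
        raise ValueError(f"well {well.well_id} was not retained; filter upstream")
    if well.strain is None:
        raise ValueError(f"well {well.well_id} has no strain spec")
    value = well.mean_log_gfp if statistic == "mean_of_log" else well.log_mean_gfp
    is_high = value >= threshold
    return is_high == bool(well.strain.expected_output)


def score_strains(
    wells: Sequence[WellSummary],
    threshold: float,
    statistic: Statistic = "mean_of_log",
) -> dict[str, StrainScore]:
    """One score per strain present among the retained wells."""
    counts: dict[str, list[int]] = {}
    for w in wells:
        if not w.retained:
            continue
        n, k = counts.setdefault(w.strain_label, [0, 0])
        counts[w.strain_label][0] = n + 1
        counts[w.strain_label][1] = k + int(classify_replicate(w, threshold, statistic))
    return {
        label: StrainScore(label, n, k) for label, (n, k) in sorted(counts.items())
    }


def score_circuits(strain_scores: dict[str, StrainScore]) -> list[CircuitScore]:
    """Apply the min-over-inputs rule per gate.

    Gates with a missing or zero-replicate input strain are reported
    incomplete (NaN circuit score) rather than silently scored.
    """
    out = []
    for gate in GATE_NAMES:
        per_input = tuple(
            strain_scores.get(f"{gate}{a}{b}", StrainScore(f"{gate}{a}{b}", 0, 0))
            for a, b in INPUT_PAIRS
        )
        complete = all(s.n > 0 for s in per_input)
        out.append(CircuitScore(gate, per_input, complete))
    return out


def summarize_campaign(
    wells: Sequence[WellSummary],
    threshold: float,
    grouping: Literal["all-conditions", "standard-conditions"] = "all-conditions",
    statistic: Statistic = "mean_of_log",
) -> pd.DataFrame:
    """Strain-correctness table (one row per strain, with shading).

    ``standard-conditions`` restricts to wells grown at T=30 C, H=16 h
    in SC medium before scoring.
    """
    if grouping == "standard-conditions":
        wells = [w for w in wells if w.condition is not None and w.condition.is_standard]
    elif grouping != "all-conditions":
        raise ValueError(f"unknown grouping {grouping!r}")
    scores = score_strains(wells, threshold, statistic)
    return pd.DataFrame(
        {
            "strain": [s.strain_label for s in scores.values()],
            "n": [s.n for s in scores.values()],
            "n_correct": [s.n_correct for s in scores.values()],
            "p_correct": [s.p_correct for s in scores.values()],
            "shade": [s.shade for s in scores.values()],
        }
    )


def shade_counts(table: pd.DataFrame, experimental_only: bool = True) -> dict[str, int]:
    """Count green / gray / unshaded strains in a summary table.

    NOR00 counts as experimental (it is the NOR-gate 00 strain as well
    as the positive control); only WT is excluded.
    """
    if experimental_only:
        table = table[table["strain"] != "WT"]
    return {
        "green": int((table["shade"] == "green").sum()),
        "gray": int((table["shade"] == "gray").sum()),
        "none": int((table["shade"] == "none").sum()),
        "total": int(len(table)),
    }
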