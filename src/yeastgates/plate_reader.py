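"""Dilution planning and plate-reader OD / fluorescence analyses.

The protocol takes an OD reading after overnight recovery, dilutes each
culture to a target starting OD by adding growth medium, grows, and
reads OD and bulk fluorescence again alongside the flow-cytometry
measurement.  This module computes the dilution volumes, the
initial-vs-final OD growth correlations (overall and grouped), and a
consistency check between plate-reader bulk GFP and flow-cytometry
per-cell GFP scaled by culture density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circuit_model import GrowthCondition
from .gating import WellSummary


@dataclass(frozen=True)
class PlateReaderRecord:
    """Plate-reader measurements for one well."""

    well_id: str
    initial_od: float  # post-recovery, pre-dilution
    final_od: float  # at measurement time
    bulk_gfp: float  # a.u.
    condition: GrowthCondition | None = None
    strain_label: str = ""

    def __post_init__(self) -> None:
        if self.initial_od < 0 or self.final_od < 0:
            raise ValueError("OD readings must be non-negative")


def dilution_plan(
    measured_od: float, target_od: float, culture_volume: float
) -> tuple[float, float]:
    """Media volume (ul) and dilution fold to hit ``target_od``.

    With fold = measured/target, mixing 1 part culture to (fold - 1)
    parts media — i.e. culture:total of 1:fold — reproduces the target
    exactly: e.g. OD 1.0 to 0.01 is a 1:100 culture:total mix.
    Dilution cannot concentrate, so target must not exceed measured.
    """
    if measured_od <= 0:
        raise ValueError("measured OD must be positive")
    if culture_volume <= 0:
        raise ValueError("culture volume must be positive")
    if not 0 < target_od <= measured_od:
        raise ValueError(
            f"target OD {target_od} must be in (0, measured OD {measured_od}]"
        )
    fold = measured_od / target_od
    media_volume = culture_volume * (fold - 1.0)
    return media_volume, fold


#: Sentinel correlation for degenerate (constant) inputs.
UNDEFINED_CORRELATION = float("nan")


def od_growth_correlation(
    records: Sequence[PlateReaderRecord],
    group_by: str | None = None,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of initial vs final OD, optionally per group.

    ``group_by`` is ``None`` (pooled), ``"strain"``, or ``"hours"``
    (recovery/growth-hours setting of the condition).  Groups smaller
    than ``min_group_size`` and constant-vector groups get a NaN
    correlation and are flagged; negative correlations are flagged as
    anomalous growth.
    """
    def key(r: PlateReaderRecord) -> Hashable:
        if group_by is None:
            return "all"
        if group_by == "strain":
            return r.strain_label
        if group_by == "hours":
            return r.condition.overnight_hours if r.condition else math.nan
        raise ValueError(f"unknown group_by {group_by!r}")

    groups: dict[Hashable, list[PlateReaderRecord]] = {}
    for r in records:
        groups.setdefault(key(r), []).append(r)

    rows = []
    for g, rs in sorted(groups.items(), key=lambda kv: str(kv[0])):
        x = np.array([r.initial_od for r in rs])
        y = np.array([r.final_od for r in rs])
        if len(rs) < min_group_size or np.ptp(x) == 0 or np.ptp(y) == 0:
            rho = UNDEFINED_CORRELATION
        else:
            rho = float(stats.pearsonr(x, y).statistic)
        rows.append(
            {
                "group": g,
                "n": len(rs),
                "rho": rho,
                "too_small": len(rs) < min_group_size,
                "anomalous": bool(rho < 0) if not math.isnan(rho) else False,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ConsistencyReport:
    """Linear fit of bulk plate-reader GFP on final_od x per-cell GFP."""

    slope: float
    intercept: float
    r: float
    residual_sd: float
    table: pd.DataFrame  # per-well predictor, response, residual, outlier flag
    outlier_wells: list[str]


def fc_pr_consistency(
    records: Sequence[PlateReaderRecord],
    well_summaries: Sequence[WellSummary],
    outlier_sds: float = 3.0,
) -> ConsistencyReport:
    """Check plate-reader bulk GFP against FC per-cell GFP x density.

    Bulk fluorescence is additive over cells, so the predictor is
    final OD x 10^(mean log10 GFP) — the per-cell GFP on the linear
    a.u. scale.  Wells whose residual exceeds ``outlier_sds`` residual
    SDs are flagged as cross-modality inconsistencies.
    """
    summaries = {s.well_id: s for s in well_summaries if s.retained}
    xs, ys, wells = [], [], []
    for r in records:
        s = summaries.get(r.well_id)
        if s is None or math.isnan(s.mean_log_gfp):
            continue
        xs.append(r.final_od * 10.0 ** s.mean_log_gfp)
        ys.append(r.bulk_gfp)
        wells.append(r.well_id)
    if not wells:
        raise ValueError("no wells matched between plate reader and FC summaries")

    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValueError("constant predictor; consistency fit undefined")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    sd = float(np.std(resid, ddof=2)) if len(x) > 2 else 0.0
    flagged = np.abs(resid) > outlier_sds * sd if sd > 0 else np.zeros_like(resid, bool)
    table = pd.DataFrame(
        {
            "well_id": wells,
            "predictor": x,
            "bulk_gfp": y,
            "residual": resid,
            "outlier": flagged,
        }
    )
    return ConsistencyReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        residual_sd=sd,
        table=table,
        outlier_wells=[w for w, f in zip(wells, flagged) if f],
    )


def records_to_frame(records: Sequence[PlateReaderRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "well_id": [r.well_id for r in records],
            "strain": [r.strain_label for r in records],
            "initial_od": [r.initial_od for r in records],
            "final_od": [r.final_od for r in records],
            "bulk_gfp": [r.bulk_gfp for r in records],
        }
    )
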