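"""Scatter gating and per-well aggregation of flow-cytometry events.

Events are filtered on forward- (FSC_A) and side-scatter (SSC_A) area
channels to drop debris at the low end and saturating measurements at
the high end; each well is then reduced to the mean and SD of log10 GFP
over the gated events.  Wells with too few gated events are dropped from
downstream analysis, and whole plates can be excluded via a curated
list (with an optional control-based heuristic for flagging candidates).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .circuit_model import GrowthCondition, StrainSpec

#: Instrument ceiling for scatter channels, in arbitrary units.
SATURATION_LIMIT = 1_048_575


@dataclass
class EventTable:
    """Per-event measurements for one well.

    ``data`` holds one row per event with columns ``FSC_A``, ``SSC_A``
    and ``GFP``, all in instrument arbitrary units (non-negative).
    """

    data: pd.DataFrame
    well_id: str
    strain: StrainSpec | None = None
    condition: GrowthCondition | None = None
    plate_id: str | None = None

    CHANNELS = ("FSC_A", "SSC_A", "GFP")

    def __post_init__(self) -> None:
        missing = [c for c in self.CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing channels {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        well_id: str | None = None,
        channel_names: dict[str, str] | None = None,
        **meta,
    ) -> "EventTable":
        """Read an event table from CSV.

        ``channel_names`` maps the canonical names to the column names
        in the file (e.g. ``{"GFP": "BL1_A"}``) for instruments whose
        export uses different labels.
        """
        df = pd.read_csv(path)
        if channel_names:
            df = df.rename(columns={v: k for k, v in channel_names.items()})
        well = well_id if well_id is not None else Path(path).stem
        return cls(df[list(cls.CHANNELS)], well, **meta)


@dataclass(frozen=True)
class GateConfig:
    """Gating bounds and aggregation settings.

    The upper scatter cut defaults to 900,000 a.u. (saturation begins
    well below the 1,048,575 a.u. instrument ceiling); the lower cuts
    have no published values and default to a conservative 10,000 a.u.
    Wells with fewer than ``min_gated_events`` surviving events are not
    retained.  GFP values below ``gfp_floor`` are clamped before the
    log10 transform.
    """

    fsc_min: float = 10_000.0
    ssc_min: float = 10_000.0
    scatter_max: float = 900_000.0
    min_gated_events: int = 10_000
    gfp_floor: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.fsc_min < self.scatter_max):
            raise ValueError("need 0 <= fsc_min < scatter_max")
        if not (0 <= self.ssc_min < self.scatter_max):
            raise ValueError("need 0 <= ssc_min < scatter_max")
        if self.min_gated_events <= 0:
            raise ValueError("min_gated_events must be positive")
        if self.gfp_floor <= 0:
            raise ValueError("gfp_floor must be positive")


@dataclass
class WellSummary:
    """Gated per-well aggregates plus metadata."""

    well_id: str
    strain_label: str
    n_raw: int
    n_gated: int
    mean_log_gfp: float  # mean of log10 GFP, log10 a.u.; NaN when empty
    sd_log_gfp: float
    retained: bool
    log_mean_gfp: float = math.nan  # log10 of the arithmetic-mean GFP
    condition: GrowthCondition | None = None
    plate_id: str | None = None
    strain: StrainSpec | None = None


def apply_gate(events: EventTable, cfg: GateConfig) -> EventTable:
    """Retain events inside the scatter gate, preserving order.

    An event survives iff ``fsc_min <= FSC_A <= scatter_max`` and
    ``ssc_min <= SSC_A <= scatter_max``.  An empty input yields an empty
    output.
    """
    d = events.data
    keep = (
        (d["FSC_A"] >= cfg.fsc_min)
        & (d["FSC_A"] <= cfg.scatter_max)
        & (d["SSC_A"] >= cfg.ssc_min)
        & (d["SSC_A"] <= cfg.scatter_max)
    )
    return replace(events, data=d[keep].reset_index(drop=True))


def log_gfp(values: np.ndarray, gfp_floor: float) -> np.ndarray:
    """log10 GFP with sub-floor (including non-positive) values clamped."""
    return np.log10(np.maximum(np.asarray(values, dtype=float), gfp_floor))


def summarize_well(
    gated: EventTable, cfg: GateConfig, n_raw: int | None = None
) -> WellSummary:
    """Aggregate a gated well to mean/SD of log10 GFP.

    ``n_raw`` is the pre-gating event count; defaults to the table
    length when the table has not actually been gated.  An empty table
    produces NaN summaries and ``retained=False``.
    """
    n = len(gated)
    raw = n if n_raw is None else n_raw
    if n == 0:
        mean = sd = log_mean = math.nan
    else:
        raw_gfp = np.maximum(gated.data["GFP"].to_numpy(dtype=float), cfg.gfp_floor)
        lg = np.log10(raw_gfp)
        mean = float(np.mean(lg))
        sd = float(np.std(lg, ddof=1)) if n > 1 else 0.0
        log_mean = float(np.log10(np.mean(raw_gfp)))
    return WellSummary(
        well_id=gated.well_id,
        strain_label=gated.strain.label if gated.strain else "",
        n_raw=raw,
        n_gated=n,
        mean_log_gfp=mean,
        sd_log_gfp=sd,
        log_mean_gfp=log_mean,
        retained=n >= cfg.min_gated_events,
        condition=gated.condition,
        plate_id=gated.plate_id,
        strain=gated.strain,
    )


def gate_and_summarize(events: EventTable, cfg: GateConfig) -> WellSummary:
    """Convenience: gate a raw well and summarize it in one step."""
    return summarize_well(apply_gate(events, cfg), cfg, n_raw=len(events))


def apply_plate_exclusions(
    summaries: Sequence[WellSummary], excluded_plates: Iterable[str]
) -> list[WellSummary]:
    """Drop all wells on the excluded plates; warn on unknown plate ids."""
    excluded = set(excluded_plates)
    known = {s.plate_id for s in summaries}
    for plate in excluded - known:
        warnings.warn(f"excluded plate {plate!r} not present in data", stacklevel=2)
    return [s for s in summaries if s.plate_id not in excluded]


def flag_abnormal_plates(
    summaries: Sequence[WellSummary],
    positive_label: str = "NOR00",
    min_pos_median: float = 3.0,
) -> list[str]:
    """Optional heuristic for building an exclusion list (off by default).

    Flags plates whose median positive-control mean-log-GFP falls below
    ``min_pos_median`` log10 a.u. — i.e. plates where even the
    constitutively-high control failed to fluoresce, a symptom of failed
    recovery or a bad run.  Intended as a screening aid; the primary
    mechanism is an explicit curated exclusion list.
    """
    rows = [
        (s.plate_id, s.mean_log_gfp)
        for s in summaries
        if s.strain_label == positive_label and s.retained and s.plate_id
    ]
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["plate", "mean_log_gfp"])
    med = df.groupby("plate")["mean_log_gfp"].median()
    return sorted(med.index[med < min_pos_median])


def summaries_to_frame(summaries: Sequence[WellSummary]) -> pd.DataFrame:
    """Tabulate summaries (one row per well) for TSV export."""
    return pd.DataFrame(
        {
            "well_id": [s.well_id for s in summaries],
            "plate_id": [s.plate_id for s in summaries],
            "strain": [s.strain_label for s in summaries],
            "n_raw": [s.n_raw for s in summaries],
            "n_gated": [s.n_gated for s in summaries],
            "mean_log_gfp": [s.mean_log_gfp for s in summaries],
            "sd_log_gfp": [s.sd_log_gfp for s in summaries],
            "retained": [s.retained for s in summaries],
            "temperature_C": [
                s.condition.temperature_C if s.condition else np.nan for s in summaries
            ],
            "overnight_hours": [
                s.condition.overnight_hours if s.condition else np.nan
                for s in summaries
            ],
            "medium": [s.condition.medium if s.condition else "" for s in summaries],
            "target_od": [
                s.condition.target_od if s.condition else np.nan for s in summaries
            ],
        }
    )
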