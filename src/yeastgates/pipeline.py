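"""End-to-end campaign orchestration.

Runs simulate/ingest -> gate -> calibrate -> score -> scatter analysis
-> plate-reader analysis -> DNAseq verification, writing every table
plus a machine-readable summary.  Identical config + seed give
identical outputs; every output embeds the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import calibration, correctness, dnaseq, gating, plate_reader, scatter_analysis
from .gating import GateConfig, WellSummary
from .synthetic_data import SimulationConfig, SyntheticDataset, simulate_campaign

log = logging.getLogger("yeastgates")

#: Events pooled per control strain before clustering (memory guard).
_MAX_CLUSTER_EVENTS = 200_000


@dataclass(frozen=True)
class CampaignConfig:
    """Configuration for one pipeline run.

    Exactly one of ``simulation`` (generate synthetic data) or
    ``input_dir`` (a directory in the layout written by
    :func:`yeastgates.synthetic_data.write_dataset`) must be set.
    """

    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    gate: GateConfig = field(default_factory=GateConfig)
    excluded_plates: tuple[str, ...] = ()
    use_plate_heuristic: bool = False
    statistic: Literal["mean_of_log", "log_of_mean"] = "mean_of_log"
    seed: int = 0
    out_dir: str | None = None
    make_figures: bool = False

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("set exactly one of simulation / input_dir")

    def config_hash(self) -> str:
        payload = repr(self).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class CampaignReport:
    config: CampaignConfig
    dataset: SyntheticDataset | None
    summaries: list[WellSummary]
    threshold: calibration.ThresholdResult
    strain_scores: dict[str, correctness.StrainScore]
    circuit_scores: list[correctness.CircuitScore]
    table_all: pd.DataFrame
    table_standard: pd.DataFrame
    cluster_reports: dict[str, scatter_analysis.ClusterReport]
    gfp_comparison: scatter_analysis.GFPDensityComparison | None
    od_correlations: pd.DataFrame
    consistency: plate_reader.ConsistencyReport | None
    anomalies: dnaseq.AnomalyMatrix | None
    results_matrix: dnaseq.PresenceMatrix | None
    design_matrix: dnaseq.PresenceMatrix | None
    coverage: pd.Series | None
    summary: dict


def _load_dataset(input_dir: str) -> SyntheticDataset:
    """Ingest a dataset directory written by ``write_dataset``.

    Ground truth is not reconstructed (it is generator-internal); the
    returned dataset carries empty truth maps.
    """
    from .circuit_model import parse_strain_label
    from .synthetic_data import GroundTruth, campaign_strains

    root = Path(input_dir)
    layout = pd.read_csv(root / "layout.tsv", sep="\t")
    from .circuit_model import GrowthCondition

    events = {}
    for _, row in layout.iterrows():
        cond = GrowthCondition(
            row["temperature_C"], row["overnight_hours"], row["medium"], row["target_od"]
        )
        path = root / "events" / f"{row['well_id'].replace(':', '_')}.csv"
        events[row["well_id"]] = gating.EventTable.from_csv(
            path,
            well_id=row["well_id"],
            strain=parse_strain_label(row["strain"]),
            condition=cond,
            plate_id=row["plate_id"],
        )
    pr = pd.read_csv(root / "plate_reader.tsv", sep="\t")
    records = [
        plate_reader.PlateReaderRecord(
            r.well_id, r.initial_od, r.final_od, r.bulk_gfp, strain_label=r.strain
        )
        for r in pr.itertuples()
    ]
    library = dnaseq.GRNALibrary.from_fasta(root / "grna_library.fasta")
    reads = {}
    reads_dir = root / "reads"
    if reads_dir.is_dir():
        for f in sorted(reads_dir.glob("*.fasta")):
            reads[f.stem] = dnaseq.read_fasta_reads(f)
    return SyntheticDataset(
        config=SimulationConfig(),
        layout=layout,
        events=events,
        plate_reader=records,
        reads_by_strain=reads,
        library=library,
        strains=campaign_strains(),
        truth=GroundTruth({}, {}, {}, {}),
    )


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-14s %6.2f s", name, t1 - t0)
    return t1


def run_campaign(cfg: CampaignConfig) -> CampaignReport:
    """Execute the full pipeline; see module docstring for the stages."""
    t = time.perf_counter()

    if cfg.simulation is not None:
        sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        dataset = simulate_campaign(sim)
    else:
        dataset = _load_dataset(cfg.input_dir)
    t = _stage("ingest", t)

    summaries = [
        gating.gate_and_summarize(table, cfg.gate) for table in dataset.events.values()
    ]
    excluded = list(cfg.excluded_plates)
    if cfg.use_plate_heuristic:
        excluded += [
            p
            for p in gating.flag_abnormal_plates(summaries)
            if p not in excluded
        ]
    summaries = gating.apply_plate_exclusions(summaries, excluded)
    retained = [s for s in summaries if s.retained]
    t = _stage("gate", t)

    controls = calibration.ControlSet.from_summaries(retained)
    threshold = calibration.optimize_threshold(controls)
    t = _stage("calibrate", t)

    strain_scores = correctness.score_strains(retained, threshold.threshold, cfg.statistic)
    circuit_scores = correctness.score_circuits(strain_scores)
    table_all = correctness.summarize_campaign(
        retained, threshold.threshold, "all-conditions", cfg.statistic
    )
    table_standard = correctness.summarize_campaign(
        retained, threshold.threshold, "standard-conditions", cfg.statistic
    )
    t = _stage("score", t)

    cluster_reports: dict[str, scatter_analysis.ClusterReport] = {}
    gfp_cmp = None
    excluded_set = set(excluded)
    for label in ("WT", "NOR00"):
        tables = [
            tab
            for tab in dataset.events.values()
            if tab.strain is not None
            and tab.strain.label == label
            and tab.plate_id not in excluded_set
        ]
        if not tables:
            continue
        pooled = pd.concat([gating.apply_gate(tab, cfg.gate).data for tab in tables])
        if len(pooled) > _MAX_CLUSTER_EVENTS:
            rng = np.random.default_rng(cfg.seed)
            pooled = pooled.iloc[
                rng.choice(len(pooled), _MAX_CLUSTER_EVENTS, replace=False)
            ]
        pooled_table = gating.EventTable(
            pooled.reset_index(drop=True), well_id=f"pooled-{label}"
        )
        report = scatter_analysis.cluster_scatter(pooled_table, seed=cfg.seed)
        cluster_reports[label] = report
        if label == "NOR00":
            gfp_cmp = scatter_analysis.compare_cluster_gfp(pooled_table, report)
    t = _stage("scatter", t)

    od_corr = plate_reader.od_growth_correlation(dataset.plate_reader, group_by=None)
    try:
        consistency = plate_reader.fc_pr_consistency(dataset.plate_reader, retained)
    except ValueError:
        consistency = None
    t = _stage("platereader", t)

    design = results = anomalies = coverage = None
    if dataset.reads_by_strain:
        design = dnaseq.build_design_matrix(dataset.strains, dataset.library)
        results = dnaseq.build_results_matrix(dataset.reads_by_strain, dataset.library)
        anomalies = dnaseq.find_anomalies(design, results)
        coverage = dnaseq.coverage_estimate(
            dataset.reads_by_strain,
            dataset.config.genome_size if cfg.simulation else 12_000_000,
        )
    t = _stage("dnaseq", t)

    summary = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_wells": len(summaries),
        "n_retained": len(retained),
        "excluded_plates": excluded,
        "threshold_log10": threshold.threshold,
        "threshold_cost": threshold.cost,
        "threshold_interval": list(threshold.minimizing_interval),
        "n_pos_controls": threshold.n_pos,
        "n_neg_controls": threshold.n_neg,
        "strain_p_correct": {
            k: v.p_correct for k, v in strain_scores.items()
        },
        "circuit_p_correct": {
            c.gate_name: (None if not c.complete else c.p_correct)
            for c in circuit_scores
        },
        "effective_functions": {
            c.gate_name: c.effective_function for c in circuit_scores
        },
        "shade_counts_all": correctness.shade_counts(table_all),
        "shade_counts_standard": correctness.shade_counts(table_standard),
        "max_replicate_sd_log_gfp": float(
            max((s.sd_log_gfp for s in retained), default=float("nan"))
        ),
        "scatter": {
            label: {
                "r_cluster1": r.r_cluster1,
                "r_cluster2": r.r_cluster2,
                "r_pooled": r.r_pooled,
                "n_cluster1": r.n_cluster1,
                "n_cluster2": r.n_cluster2,
                "silhouette": r.silhouette,
                "bimodal": r.bimodal,
            }
            for label, r in cluster_reports.items()
        },
        "od_rho": float(od_corr["rho"].iloc[0]) if len(od_corr) else None,
        "fc_pr_r": consistency.r if consistency else None,
        "dnaseq_anomalies": anomalies.n_anomalies if anomalies else None,
    }

    report = CampaignReport(
        config=cfg,
        dataset=dataset,
        summaries=summaries,
        threshold=threshold,
        strain_scores=strain_scores,
        circuit_scores=circuit_scores,
        table_all=table_all,
        table_standard=table_standard,
        cluster_reports=cluster_reports,
        gfp_comparison=gfp_cmp,
        od_correlations=od_corr,
        consistency=consistency,
        anomalies=anomalies,
        results_matrix=results,
        design_matrix=design,
        coverage=coverage,
        summary=summary,
    )
    if cfg.out_dir:
        write_report(report, cfg.out_dir)
        t = _stage("write", t)
    return report


def _stamp(df: pd.DataFrame, cfg: CampaignConfig) -> pd.DataFrame:
    out = df.copy()
    out["config_hash"] = cfg.config_hash()
    out["seed"] = cfg.seed
    return out


def write_report(report: CampaignReport, out_dir: str | Path) -> None:
    """Write all tables (then figures, so headless table-only runs work)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    _stamp(gating.summaries_to_frame(report.summaries), cfg).to_csv(
        out / "well_summaries.tsv", sep="\t", index=False
    )
    _stamp(report.table_all, cfg).to_csv(
        out / "strain_correctness_all.tsv", sep="\t", index=False
    )
    _stamp(report.table_standard, cfg).to_csv(
        out / "strain_correctness_standard.tsv", sep="\t", index=False
    )
    for label, rep in report.cluster_reports.items():
        _stamp(rep.to_frame(), cfg).to_csv(
            out / f"scatter_clusters_{label}.tsv", sep="\t", index=False
        )
    _stamp(report.od_correlations, cfg).to_csv(
        out / "od_correlations.tsv", sep="\t", index=False
    )
    if report.consistency is not None:
        _stamp(report.consistency.table, cfg).to_csv(
            out / "fc_pr_consistency.tsv", sep="\t", index=False
        )
    if report.anomalies is not None:
        report.anomalies.table.to_csv(out / "dnaseq_anomalies.tsv", sep="\t")
        report.results_matrix.table.to_csv(out / "dnaseq_results.tsv", sep="\t")
        report.design_matrix.table.to_csv(out / "dnaseq_design.tsv", sep="\t")
    (out / "summary.json").write_text(json.dumps(report.summary, indent=2, sort_keys=True))
    if cfg.make_figures:
        from . import viz

        viz.histogram_grid(
            report.summaries, report.threshold.threshold, out / "strain_histograms.png"
        )
        if report.dataset is not None:
            viz.od_scatter(report.dataset.plate_reader, out / "od_growth.png")
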