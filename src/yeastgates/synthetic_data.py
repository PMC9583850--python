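"""Synthetic campaign generator.

Emulates the statistical structure of the study's measurements so every
downstream stage is testable without the archived data:

* per-well flow-cytometry event tables (~30,000 events) drawn from a
  two-cluster bivariate log10-normal scatter mixture plus a dim debris
  component, with all channels hard-clipped at the instrument ceiling
  (1,048,575 a.u.);
* per-well log10 GFP tightly clustered around a strain-and-input
  dependent high or low mode — failures are *whole-well*: with a
  per-strain probability the entire well expresses the wrong mode,
  which is what produces replicate-level bimodality in the summaries;
* plate-reader initial OD after overnight recovery, final OD with a
  diminishing-returns dependence on the target (post-dilution) OD, and
  bulk GFP proportional to final OD times mean per-cell fluorescence;
* fixed-length sequencing reads per strain with designed gRNA
  subsequences embedded (or withheld/planted, per injected anomalies).

All randomness flows from a single seed through named per-well and
per-strain substreams, so datasets are byte-identical under a fixed
seed and adding wells does not perturb existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit_model import (
    GrowthCondition,
    StrainSpec,
    control_strains,
    experimental_strains,
)
from .dnaseq import GRNALibrary
from .gating import SATURATION_LIMIT, EventTable
from .plate_reader import PlateReaderRecord, dilution_plan


@dataclass(frozen=True)
class ScatterCluster:
    """One bivariate log10-normal scatter component."""

    weight: float
    mean_log_fsc: float
    mean_log_ssc: float
    sd_log_fsc: float = 0.18
    sd_log_ssc: float = 0.18
    correlation: float = 0.92

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError("cluster weight must be in [0, 1]")
        if self.sd_log_fsc <= 0 or self.sd_log_ssc <= 0:
            raise ValueError("cluster SDs must be positive")
        if not -1 <= self.correlation <= 1:
            raise ValueError("correlation must be in [-1, 1]")


@dataclass(frozen=True)
class GrowthModel:
    """Maps target OD and growth hours to final OD.

    raw = target_od * 2^(hours / doubling_hours), saturating as
    final = od_max * raw / (raw + od_max): increasing in target OD with
    a diminishing rate of return, times multiplicative log-normal noise.
    """

    doubling_hours: float = 1.5
    od_max: float = 2.0
    growth_hours: float = 16.0
    noise_sd: float = 0.05  # SD of ln-scale multiplicative noise

    def final_od(self, target_od: float, rng: np.random.Generator) -> float:
        raw = target_od * 2.0 ** (self.growth_hours / self.doubling_hours)
        mean = self.od_max * raw / (raw + self.od_max)
        return float(mean * rng.lognormal(0.0, self.noise_sd))


# Two scatter lobes: cluster order here is unimportant; analysis relabels
# by center SSC/FSC ratio.  Offsets run across the within-cluster trend so
# pooling visibly attenuates the log-log correlation while leaving it
# positive.
DEFAULT_SCATTER = (
    ScatterCluster(weight=0.4, mean_log_fsc=5.20, mean_log_ssc=5.50),
    ScatterCluster(weight=0.6, mean_log_fsc=5.55, mean_log_ssc=5.20),
)

DEFAULT_CONDITIONS = (
    GrowthCondition(30, 16, "SC", 3e-4),
    GrowthCondition(30, 16, "SC", 1e-3),
    GrowthCondition(37, 16, "SC", 1e-4),
    GrowthCondition(30, 12, "rich", 1e-2),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the campaign structure: 93 sample wells per run
    (including 3 positive and 3 negative control wells), 30,000 FC
    events per well, low/high GFP modes two log-units apart (1.4 and
    3.4 log10 a.u.) so the controls' midpoint sits near 2.4, and
    whole-well failure off unless planted.
    """

    seed: int = 0
    n_runs: int = 4
    wells_per_run: int = 93
    n_pos_controls: int = 3
    n_neg_controls: int = 3
    events_per_well: int = 30_000
    scatter_clusters: tuple[ScatterCluster, ...] = DEFAULT_SCATTER
    debris_fraction: float = 0.05
    debris_mean_log: tuple[float, float] = (3.8, 3.6)
    debris_sd_log: float = 0.35
    saturation_limit: float = float(SATURATION_LIMIT)
    gfp_low: tuple[float, float] = (1.4, 0.15)  # per-cell log10 mean, SD
    gfp_high: tuple[float, float] = (3.4, 0.15)
    well_mode_sd: float = 0.10  # well-level jitter of the mode mean
    well_failure_rate: float | Mapping[str, float] = 0.0
    growth: GrowthModel = field(default_factory=GrowthModel)
    run_conditions: tuple[GrowthCondition, ...] = DEFAULT_CONDITIONS
    initial_od_mean: float = 1.0
    initial_od_sd: float = 0.2  # ln-scale
    vigor_sd: float = 0.3  # ln-scale per-well growth vigor, shared by
    # recovery and growth phases; couples initial and final OD
    pr_gain: float = 0.01
    pr_noise_sd: float = 0.05  # ln-scale noise on bulk GFP
    read_length: int = 100
    reads_per_strain: int = 200
    embed_per_grna: int = 5
    genome_size: int = 12_000_000
    dnaseq_anomalies: Mapping[str, Mapping[str, Sequence[str]]] = field(
        default_factory=dict
    )  # strain -> {"drop": [...], "add": [...]}

    def __post_init__(self) -> None:
        if not 0 <= self.debris_fraction <= 1:
            raise ValueError("debris_fraction must be in [0, 1]")
        if self.saturation_limit <= 0:
            raise ValueError("saturation_limit must be positive")
        total_w = sum(c.weight for c in self.scatter_clusters)
        if self.scatter_clusters and not np.isclose(total_w, 1.0):
            raise ValueError("scatter cluster weights must sum to 1")
        if self.gfp_low[1] <= 0 or self.gfp_high[1] <= 0:
            raise ValueError("GFP SDs must be positive")
        n_exp = self.wells_per_run - self.n_pos_controls - self.n_neg_controls
        if n_exp <= 0:
            raise ValueError("wells_per_run leaves no experimental wells")

    def failure_rate(self, strain: StrainSpec) -> float:
        if isinstance(self.well_failure_rate, Mapping):
            return float(self.well_failure_rate.get(strain.label, 0.0))
        # scalar rate applies to experimental strains only
        return 0.0 if strain.is_control else float(self.well_failure_rate)


# --- synthetic gRNA library and per-strain part lists -----------------------

#: Gate wiring (coding sequences + target sites, merged) of the synthetic
#: circuit designs; inputs add r7 (input 1) and r8 (input 2), every gate
#: carries the reporter gRNA r10.  r11/r12 are library members used by no
#: design.  These part lists are fixtures: the study's real gRNA library
#: is user-supplied input.
GATE_WIRING: dict[str, frozenset[str]] = {
    "AND": frozenset({"r1", "r3"}),
    "OR": frozenset({"r1", "r4"}),
    "NAND": frozenset({"r3", "r5"}),
    "NOR": frozenset({"r1", "r9"}),
    "XOR": frozenset({"r1", "r6", "r9"}),
    "XNOR": frozenset({"r4", "r6"}),
}

GRNA_NAMES = tuple(f"r{i}" for i in range(1, 13))

_LIBRARY_SEED = 20220616  # fixed: the library is an input, not campaign noise
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return b"".join(_BASES[rng.integers(0, 4, size=length)]).decode()


def default_library(grna_length: int = 20) -> GRNALibrary:
    """Deterministic synthetic gRNA library (names r1-r12)."""
    rng = np.random.default_rng(_LIBRARY_SEED)
    return GRNALibrary({name: _random_seq(rng, grna_length) for name in GRNA_NAMES})


def strain_grnas(strain: StrainSpec) -> frozenset[str]:
    """Designed gRNA part set of a strain (synthetic scheme)."""
    if strain.gate is None:  # WT carries no circuit parts
        return frozenset()
    parts = set(GATE_WIRING[strain.gate.name]) | {"r10"}
    a, b = strain.inputs
    if a:
        parts.add("r7")
    if b:
        parts.add("r8")
    return frozenset(parts)


def campaign_strains() -> list[StrainSpec]:
    """24 experimental strains + the WT control, with part lists.

    NOR00 serves double duty as the positive control and the NOR-gate
    input-00 strain, so it appears once (from the experimental list).
    """
    wt = control_strains()[1]
    return [s.with_grnas(strain_grnas(s)) for s in experimental_strains() + [wt]]


# --- dataset container ------------------------------------------------------

@dataclass
class GroundTruth:
    """Generator-side truth for downstream validation."""

    well_modes: dict[str, str]  # well_id -> "high" | "low"
    well_failed: dict[str, bool]  # well_id -> wrong-mode flag
    observed_grnas: dict[str, frozenset[str]]  # strain -> gRNAs actually in reads
    designed_grnas: dict[str, frozenset[str]]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    layout: pd.DataFrame  # run, plate_id, position, well_id, strain, condition cols
    events: dict[str, EventTable]  # well_id -> events
    plate_reader: list[PlateReaderRecord]
    reads_by_strain: dict[str, list[str]]
    library: GRNALibrary
    strains: list[StrainSpec]
    truth: GroundTruth

    @property
    def well_conditions(self) -> dict[str, GrowthCondition]:
        return {t.well_id: t.condition for t in self.events.values()}


# --- event simulation -------------------------------------------------------

def _bivariate_log10(
    rng: np.random.Generator,
    n: int,
    mean: tuple[float, float],
    sd: tuple[float, float],
    rho: float,
) -> np.ndarray:
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    return np.column_stack([mean[0] + sd[0] * z1, mean[1] + sd[1] * z2])


def simulate_well_events(
    strain: StrainSpec,
    mode: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    well_id: str = "well",
    condition: GrowthCondition | None = None,
    plate_id: str | None = None,
) -> EventTable:
    """Draw one well's FC events.

    ``mode`` ("high" or "low") selects the GFP component; the whole well
    shares one mode mean (base mode mean plus a per-well jitter), with
    per-cell spread on top.  Scatter comes from the debris + cluster
    mixture; every channel is clipped to [0, saturation_limit].
    """
    if mode not in ("high", "low"):
        raise ValueError("mode must be 'high' or 'low'")
    n = cfg.events_per_well
    n_debris = rng.binomial(n, cfg.debris_fraction) if cfg.debris_fraction > 0 else 0
    n_cells = n - n_debris

    parts = []
    if cfg.scatter_clusters and n_cells:
        weights = np.array([c.weight for c in cfg.scatter_clusters])
        counts = rng.multinomial(n_cells, weights / weights.sum())
        for c, k in zip(cfg.scatter_clusters, counts):
            if k:
                parts.append(
                    _bivariate_log10(
                        rng, k,
                        (c.mean_log_fsc, c.mean_log_ssc),
                        (c.sd_log_fsc, c.sd_log_ssc),
                        c.correlation,
                    )
                )
    if n_debris:
        parts.append(
            _bivariate_log10(
                rng, n_debris, cfg.debris_mean_log,
                (cfg.debris_sd_log, cfg.debris_sd_log), 0.3,
            )
        )
    log_scatter = np.vstack(parts) if parts else np.empty((0, 2))
    scatter = np.clip(10.0 ** log_scatter, 0.0, cfg.saturation_limit)

    mu, cell_sd = cfg.gfp_high if mode == "high" else cfg.gfp_low
    well_mu = mu + rng.normal(0.0, cfg.well_mode_sd)
    log_gfp_cells = rng.normal(well_mu, cell_sd, size=n_cells)
    log_gfp_debris = rng.normal(1.0, 0.3, size=n_debris)  # dim autofluorescence
    gfp = np.clip(
        10.0 ** np.concatenate([log_gfp_cells, log_gfp_debris]),
        0.0,
        cfg.saturation_limit,
    )

    data = pd.DataFrame(
        {"FSC_A": scatter[:, 0], "SSC_A": scatter[:, 1], "GFP": gfp}
    )
    return EventTable(
        data, well_id=well_id, strain=strain, condition=condition, plate_id=plate_id
    )


# --- campaign simulation ----------------------------------------------------

_POSITIONS = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


def _well_rng(cfg: SimulationConfig, run: int, well: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1, run, well))
    )


def _strain_reads_rng(cfg: SimulationConfig, idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(2, idx))
    )


def _run_assignment(
    cfg: SimulationConfig, exp: list[StrainSpec], run: int
) -> list[StrainSpec]:
    """Strains measured in one run: controls plus round-robin experimental.

    The rotation continues across runs so every strain is covered evenly
    even when a single run holds fewer than 24 experimental wells.
    """
    n_exp = cfg.wells_per_run - cfg.n_pos_controls - cfg.n_neg_controls
    pos, neg = control_strains()[0], control_strains()[1]
    pos = pos.with_grnas(strain_grnas(pos))
    assigned = [pos] * cfg.n_pos_controls + [neg] * cfg.n_neg_controls
    assigned += [exp[(run * n_exp + i) % len(exp)] for i in range(n_exp)]
    return assigned


def simulate_campaign(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset for one campaign.

    Each run is one 96-well plate under one growth condition; wells are
    placed at randomized plate positions.  Whole-well mode failures are
    drawn per well from the strain's failure rate.  Sequencing reads are
    generated once per strain, honoring injected DNAseq anomalies.
    """
    exp = [s.with_grnas(strain_grnas(s)) for s in experimental_strains()]
    strains = campaign_strains()

    layout_rows = []
    events: dict[str, EventTable] = {}
    pr_records: list[PlateReaderRecord] = []
    well_modes: dict[str, str] = {}
    well_failed: dict[str, bool] = {}

    for run in range(cfg.n_runs):
        condition = cfg.run_conditions[run % len(cfg.run_conditions)]
        plate_id = f"plate{run:02d}"
        layout_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0, run))
        )
        positions = layout_rng.permutation(_POSITIONS)[: cfg.wells_per_run]
        assigned = _run_assignment(cfg, exp, run)

        for widx, (pos, strain) in enumerate(zip(positions, assigned)):
            rng = _well_rng(cfg, run, widx)
            well_id = f"{plate_id}:{pos}"

            expected = "high" if strain.expected_output else "low"
            failed = bool(rng.random() < cfg.failure_rate(strain))
            mode = ("low" if expected == "high" else "high") if failed else expected
            table = simulate_well_events(
                strain, mode, cfg, rng,
                well_id=well_id, condition=condition, plate_id=plate_id,
            )
            events[well_id] = table
            well_modes[well_id] = mode
            well_failed[well_id] = failed

            vigor = rng.lognormal(0.0, cfg.vigor_sd)
            initial_od = float(
                cfg.initial_od_mean * vigor * rng.lognormal(0.0, cfg.initial_od_sd)
            )
            target = min(condition.target_od, initial_od)
            dilution_plan(initial_od, target, 10.0)  # protocol feasibility check
            final_od = cfg.growth.final_od(target, rng) * vigor
            mean_cell_gfp = float(table.data["GFP"].mean())
            bulk = (
                cfg.pr_gain * final_od * mean_cell_gfp
                * rng.lognormal(0.0, cfg.pr_noise_sd)
            )
            pr_records.append(
                PlateReaderRecord(
                    well_id, initial_od, final_od, float(bulk),
                    condition=condition, strain_label=strain.label,
                )
            )
            layout_rows.append(
                {
                    "run": run,
                    "plate_id": plate_id,
                    "position": pos,
                    "well_id": well_id,
                    "strain": strain.label,
                    "temperature_C": condition.temperature_C,
                    "overnight_hours": condition.overnight_hours,
                    "medium": condition.medium,
                    "target_od": condition.target_od,
                    "true_mode": mode,
                    "failed": failed,
                }
            )

    library = default_library()
    reads_by_strain: dict[str, list[str]] = {}
    observed: dict[str, frozenset[str]] = {}
    designed: dict[str, frozenset[str]] = {}
    for sidx, strain in enumerate(strains):
        rng = _strain_reads_rng(cfg, sidx)
        anomalies = cfg.dnaseq_anomalies.get(strain.label, {})
        present = (set(strain.grnas) - set(anomalies.get("drop", ()))) | set(
            anomalies.get("add", ())
        )
        designed[strain.label] = frozenset(strain.grnas)
        observed[strain.label] = frozenset(present)
        reads = [_random_seq(rng, cfg.read_length) for _ in range(cfg.reads_per_strain)]
        slot = 0
        for g in sorted(present):
            seq = library[g]
            for _ in range(cfg.embed_per_grna):
                read = reads[slot % len(reads)]
                start = int(rng.integers(0, cfg.read_length - len(seq) + 1))
                insert = seq
                if rng.random() < 0.5:  # either strand may be sequenced
                    from .dnaseq import reverse_complement

                    insert = reverse_complement(seq)
                reads[slot % len(reads)] = (
                    read[:start] + insert + read[start + len(seq):]
                )
                slot += 1
        reads_by_strain[strain.label] = reads

    return SyntheticDataset(
        config=cfg,
        layout=pd.DataFrame(layout_rows),
        events=events,
        plate_reader=pr_records,
        reads_by_strain=reads_by_strain,
        library=library,
        strains=strains,
        truth=GroundTruth(well_modes, well_failed, observed, designed),
    )


# --- benchmark scenario -----------------------------------------------------

#: Whole-well wrong-mode rates emulating the failure modes the replication
#: campaign observed: NAND11 barely half-correct, NOR11 split into two
#: replicate clusters, OR's single-positive inputs mostly failing low,
#: XOR01 mostly failing, XNOR11 partially failing.  Values are scenario
#: fixtures, fixed once.
BENCHMARK_FAILURE_RATES: dict[str, float] = {
    "NAND11": 0.58,
    "NOR11": 0.50,
    "OR01": 0.60,
    "OR10": 0.90,
    "XOR01": 0.70,
    "XNOR11": 0.33,
}

#: Injected build anomalies emulating the campaign's DNAseq findings: the
#: OR strains carrying AND-like parts instead of their own, and XOR
#: strains missing r1/r9 (and the r6 input signal).
BENCHMARK_DNASEQ_ANOMALIES: dict[str, dict[str, tuple[str, ...]]] = {
    "OR01": {"drop": ("r4",), "add": ("r3",)},
    "OR10": {"drop": ("r4",), "add": ("r3",)},
    "XOR00": {"drop": ("r1", "r9", "r6")},
    "XOR01": {"drop": ("r1", "r9")},
}


def benchmark_campaign(seed: int) -> SimulationConfig:
    """The standard synthetic replication scenario: 24 strains x 12 wells
    x 30,000 events (4 runs of 72 experimental + 6 control wells), with
    the benchmark failure rates and DNAseq anomalies planted."""
    return SimulationConfig(
        seed=seed,
        n_runs=4,
        wells_per_run=78,
        events_per_well=30_000,
        well_failure_rate=BENCHMARK_FAILURE_RATES,
        dnaseq_anomalies=BENCHMARK_DNASEQ_ANOMALIES,
    )


# --- plain-text export ------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the dataset as plain text: per-well event CSVs, layout and
    ground-truth TSVs, reads as FASTA, library as FASTA."""
    out = Path(out_dir)
    (out / "events").mkdir(parents=True, exist_ok=True)
    dataset.layout.to_csv(out / "layout.tsv", sep="\t", index=False)
    for well_id, table in dataset.events.items():
        table.to_csv(out / "events" / f"{well_id.replace(':', '_')}.csv")
    from .plate_reader import records_to_frame

    records_to_frame(dataset.plate_reader).to_csv(
        out / "plate_reader.tsv", sep="\t", index=False
    )
    dataset.library.to_fasta(out / "grna_library.fasta")
    (out / "reads").mkdir(exist_ok=True)
    for strain, reads in dataset.reads_by_strain.items():
        with open(out / "reads" / f"{strain}.fasta", "w") as fh:
            for i, r in enumerate(reads):
                fh.write(f">{strain}_read{i}\n{r}\n")
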