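import numpy as np
import pandas as pd
import pytest

from yeastgates.gating import EventTable, GateConfig
from yeastgates.pipeline import CampaignConfig, run_campaign
from yeastgates.synthetic_data import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_events(fsc, ssc, gfp=None, well_id="w", **meta) -> EventTable:
    fsc = np.asarray(fsc, dtype=float)
    if gfp is None:
        gfp = np.full_like(fsc, 100.0)
    return EventTable(
        pd.DataFrame(
            {"FSC_A": fsc, "SSC_A": np.asarray(ssc, float), "GFP": np.asarray(gfp, float)}
        ),
        well_id=well_id,
        **meta,
    )


#: A small campaign shared by integration-level tests: 2 runs x 30 wells
#: x 5,000 events, with a whole-well failure rate planted on two strains
#: and one injected DNAseq anomaly of each kind.
SMALL_SIM = SimulationConfig(
    seed=2024,
    n_runs=2,
    wells_per_run=30,
    events_per_well=5_000,
    well_failure_rate={"NAND11": 0.5, "NOR11": 0.5},
    dnaseq_anomalies={
        "OR01": {"drop": ["r4"], "add": ["r3"]},
        "XOR10": {"drop": ["r1", "r9"]},
    },
)

SMALL_GATE = GateConfig(min_gated_events=2_000)


@pytest.fixture(scope="session")
def small_report():
    cfg = CampaignConfig(simulation=SMALL_SIM, seed=SMALL_SIM.seed, gate=SMALL_GATE)
    return run_campaign(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_report):
    return small_report.dataset
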