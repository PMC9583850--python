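"""Generator contracts: determinism, clipping, mixtures, failures, growth."""

import numpy as np
import pandas as pd
import pytest

from conftest import SMALL_SIM
from yeastgates.circuit_model import parse_strain_label
from yeastgates.synthetic_data import (
    GrowthModel,
    ScatterCluster,
    SimulationConfig,
    campaign_strains,
    default_library,
    simulate_campaign,
    simulate_well_events,
    strain_grnas,
    write_dataset,
)

STRAIN = parse_strain_label("AND11")


def _rng(seed=5):
    return np.random.default_rng(seed)


class TestWellEvents:
    def test_row_count_matches_events_per_well(self):
        cfg = SimulationConfig(events_per_well=30_000)
        table = simulate_well_events(STRAIN, "high", cfg, _rng())
        assert len(table) == 30_000

    def test_degenerate_single_cluster_no_debris(self):
        cfg = SimulationConfig(
            events_per_well=2_000,
            debris_fraction=0.0,
            scatter_clusters=(ScatterCluster(1.0, 5.0, 5.0, 0.05, 0.05, 0.0),),
        )
        table = simulate_well_events(STRAIN, "low", cfg, _rng())
        lf = np.log10(table.data["FSC_A"])
        assert lf.std() < 0.06  # single tight cluster, no debris tail
        assert abs(lf.mean() - 5.0) < 0.01

    def test_channels_clipped_to_saturation(self):
        cfg = SimulationConfig(
            events_per_well=5_000,
            scatter_clusters=(ScatterCluster(1.0, 6.2, 6.2, 0.3, 0.3, 0.9),),
        )
        table = simulate_well_events(STRAIN, "high", cfg, _rng())
        assert (table.data.to_numpy() >= 0).all()
        assert (table.data.to_numpy() <= cfg.saturation_limit).all()
        assert (table.data["FSC_A"] == cfg.saturation_limit).any()

    def test_clip_fraction_matches_monte_carlo_oracle(self):
        cfg = SimulationConfig(
            events_per_well=50_000,
            debris_fraction=0.0,
            scatter_clusters=(ScatterCluster(1.0, 6.1, 5.0, 0.2, 0.2, 0.0),),
        )
        table = simulate_well_events(STRAIN, "high", cfg, _rng())
        observed = float((table.data["FSC_A"] == cfg.saturation_limit).mean())
        # oracle: direct Monte-Carlo clip fraction from independent draws
        oracle_draws = 10**6
        z = _rng(123).normal(6.1, 0.2, oracle_draws)
        p = float((10.0**z >= cfg.saturation_limit).mean())
        sd = np.sqrt(p * (1 - p) / cfg.events_per_well)
        assert abs(observed - p) <= 3 * sd

    def test_high_low_modes_two_logs_apart(self):
        cfg = SimulationConfig(events_per_well=5_000, debris_fraction=0.0)
        hi = simulate_well_events(STRAIN, "high", cfg, _rng(1))
        lo = simulate_well_events(STRAIN, "low", cfg, _rng(2))
        d = np.log10(hi.data["GFP"]).mean() - np.log10(lo.data["GFP"]).mean()
        assert d == pytest.approx(2.0, abs=0.5)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            simulate_well_events(STRAIN, "medium", SimulationConfig(), _rng())


class TestCampaign:
    def test_same_seed_identical_dataset(self):
        a = simulate_campaign(SMALL_SIM)
        b = simulate_campaign(SMALL_SIM)
        assert a.layout.equals(b.layout)
        for wid in a.events:
            assert a.events[wid].data.equals(b.events[wid].data)
        assert a.reads_by_strain == b.reads_by_strain
        assert [r.final_od for r in a.plate_reader] == [r.final_od for r in b.plate_reader]

    def test_adding_wells_leaves_existing_wells_unchanged(self):
        import dataclasses

        small = dataclasses.replace(SMALL_SIM, wells_per_run=20, n_runs=1)
        bigger = dataclasses.replace(SMALL_SIM, wells_per_run=21, n_runs=1)
        a = simulate_campaign(small)
        b = simulate_campaign(bigger)
        for wid in a.events:
            assert wid in b.events
            assert a.events[wid].data.equals(b.events[wid].data)

    def test_no_failures_means_expected_modes(self):
        import dataclasses

        cfg = dataclasses.replace(
            SMALL_SIM, well_failure_rate=0.0, n_runs=1, events_per_well=100
        )
        ds = simulate_campaign(cfg)
        for row in ds.layout.itertuples():
            expected = "high" if parse_strain_label(row.strain).expected_output else "low"
            assert row.true_mode == expected
            assert not row.failed

    def test_failure_rate_matches_binomial_oracle(self):
        # ~200 NOR11 wells at planted whole-well failure rate 0.5
        cfg = SimulationConfig(
            seed=77,
            n_runs=56,
            wells_per_run=93,
            events_per_well=20,
            well_failure_rate={"NOR11": 0.5},
        )
        ds = simulate_campaign(cfg)
        nor11 = ds.layout[ds.layout["strain"] == "NOR11"]
        n = len(nor11)
        assert n >= 190
        frac = nor11["failed"].mean()
        sd = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 3 * sd
        # all other strains never fail
        others = ds.layout[ds.layout["strain"] != "NOR11"]
        assert not others["failed"].any()

    def test_scalar_failure_rate_spares_controls(self):
        import dataclasses

        cfg = dataclasses.replace(
            SMALL_SIM, well_failure_rate=1.0, n_runs=1, events_per_well=50
        )
        ds = simulate_campaign(cfg)
        lay = ds.layout
        controls = lay[lay["strain"].isin(["WT", "NOR00"])]
        exp = lay[~lay["strain"].isin(["WT", "NOR00"])]
        assert not controls["failed"].any()
        assert exp["failed"].all()

    def test_final_od_median_nondecreasing_in_target(self):
        gm = GrowthModel()
        rng = _rng(9)
        meds = []
        for target in (1e-4, 3e-4, 1e-3, 1e-2, 1e-1):
            meds.append(np.median([gm.final_od(target, rng) for _ in range(300)]))
        assert all(a <= b + 1e-12 for a, b in zip(meds, meds[1:]))

    def test_initial_and_final_od_positively_coupled(self):
        ds = simulate_campaign(SMALL_SIM)
        same_cond = [r for r in ds.plate_reader if r.condition == ds.plate_reader[0].condition]
        x = np.array([r.initial_od for r in same_cond])
        y = np.array([r.final_od for r in same_cond])
        assert np.corrcoef(x, y)[0, 1] > 0.2

    def test_layout_positions_unique_per_plate(self):
        ds = simulate_campaign(SMALL_SIM)
        for _, plate in ds.layout.groupby("plate_id"):
            assert plate["position"].is_unique


class TestReads:
    def test_reads_contain_designed_grnas_exactly(self):
        ds = simulate_campaign(SMALL_SIM)
        lib = ds.library
        from yeastgates.dnaseq import search_grna

        for strain in ds.strains:
            reads = ds.reads_by_strain[strain.label]
            truth = ds.truth.observed_grnas[strain.label]
            for g in lib:
                assert search_grna(reads, lib[g]) == int(g in truth)

    def test_anomaly_injection_alters_truth(self):
        ds = simulate_campaign(SMALL_SIM)
        assert "r4" not in ds.truth.observed_grnas["OR01"]
        assert "r3" in ds.truth.observed_grnas["OR01"]
        assert "r4" in ds.truth.designed_grnas["OR01"]
        assert ds.truth.observed_grnas["XOR10"] == ds.truth.designed_grnas["XOR10"] - {
            "r1", "r9"
        }

    def test_library_deterministic_and_valid(self):
        a, b = default_library(), default_library()
        assert a.entries == b.entries
        assert all(len(s) == 20 for s in a.entries.values())

    def test_wt_has_no_parts_and_gates_share_reporter(self):
        strains = campaign_strains()
        by_label = {s.label: s for s in strains}
        assert by_label["WT"].grnas == frozenset()
        for s in strains:
            if s.label != "WT":
                assert "r10" in s.grnas
        # inputs add their signal gRNAs
        assert "r7" in strain_grnas(parse_strain_label("AND10"))
        assert "r8" not in strain_grnas(parse_strain_label("AND10"))


def test_write_dataset_round_trips_events(tmp_path):
    import dataclasses

    cfg = dataclasses.replace(SMALL_SIM, n_runs=1, wells_per_run=10, events_per_well=50)
    ds = simulate_campaign(cfg)
    write_dataset(ds, tmp_path)
    assert (tmp_path / "layout.tsv").exists()
    wid = next(iter(ds.events))
    path = tmp_path / "events" / f"{wid.replace(':', '_')}.csv"
    again = pd.read_csv(path)
    assert np.allclose(again.to_numpy(), ds.events[wid].data.to_numpy())
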