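"""Dilution arithmetic, OD growth correlations, FC/plate-reader consistency."""

import math

import numpy as np
import pytest

from yeastgates.circuit_model import parse_strain_label
from yeastgates.gating import WellSummary
from yeastgates.plate_reader import (
    PlateReaderRecord,
    dilution_plan,
    fc_pr_consistency,
    od_growth_correlation,
)


class TestDilutionPlan:
    def test_od_1_to_0p01_is_1_to_100(self):
        media, fold = dilution_plan(1.0, 0.01, 10.0)
        assert fold == pytest.approx(100.0)
        assert media == pytest.approx(990.0)  # 1 part culture : 100 parts total

    def test_identity_dilution(self):
        media, fold = dilution_plan(0.5, 0.5, 10.0)
        assert fold == 1.0 and media == 0.0

    def test_direct_arithmetic_example(self):
        media, fold = dilution_plan(0.8, 0.0003, 10.0)
        assert fold == pytest.approx(2666.67, rel=1e-5)
        assert media == pytest.approx(26_656.7, rel=1e-5)

    def test_cannot_concentrate(self):
        with pytest.raises(ValueError):
            dilution_plan(0.5, 0.6, 10.0)
        with pytest.raises(ValueError):
            dilution_plan(0.0, 0.01, 10.0)

    def test_round_trip_recovers_target(self, rng):
        for _ in range(50):
            measured = rng.uniform(0.1, 2.0)
            target = measured * rng.uniform(1e-4, 1.0)
            vol = rng.uniform(1, 100)
            media, fold = dilution_plan(measured, target, vol)
            post = measured * vol / (vol + media)
            assert post == pytest.approx(target, abs=1e-9)


def _rec(i, initial, final, gfp=0.0, strain=""):
    return PlateReaderRecord(f"w{i}", initial, final, gfp, strain_label=strain)


class TestODGrowthCorrelation:
    def test_exact_linear_growth(self):
        records = [_rec(i, od, 2 * od) for i, od in enumerate([0.1, 0.5, 1.0, 1.5])]
        out = od_growth_correlation(records)
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(0)
        rho = 0.4
        z = rng.standard_normal((500, 2))
        x = z[:, 0]
        y = rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1]
        records = [
            _rec(i, 1 + 0.2 * xi, 1 + 0.2 * yi) for i, (xi, yi) in enumerate(zip(x, y))
        ]
        est = od_growth_correlation(records)["rho"].iloc[0]
        assert est == pytest.approx(rho, abs=0.1)

    def test_anticorrelated_batch_flagged(self, rng):
        x = rng.uniform(0.5, 1.5, 100)
        y = 2.0 - x + rng.normal(0, 0.05, 100)
        out = od_growth_correlation([_rec(i, a, b) for i, (a, b) in enumerate(zip(x, y))])
        assert out["rho"].iloc[0] < 0
        assert bool(out["anomalous"].iloc[0])

    def test_small_and_constant_groups_get_sentinel(self):
        out = od_growth_correlation([_rec(0, 1.0, 1.0), _rec(1, 1.1, 1.2)])
        assert math.isnan(out["rho"].iloc[0])
        assert bool(out["too_small"].iloc[0])
        const = [_rec(i, 1.0, v) for i, v in enumerate([1.0, 1.1, 1.2])]
        assert math.isnan(od_growth_correlation(const)["rho"].iloc[0])

    def test_affine_rescaling_invariance(self, rng):
        x = rng.uniform(0.5, 1.5, 80)
        y = x + rng.normal(0, 0.2, 80)
        base = od_growth_correlation([_rec(i, a, b) for i, (a, b) in enumerate(zip(x, y))])
        scaled = od_growth_correlation(
            [_rec(i, 3 * a + 1, 0.5 * b + 2) for i, (a, b) in enumerate(zip(x, y))]
        )
        assert scaled["rho"].iloc[0] == pytest.approx(base["rho"].iloc[0], abs=1e-12)

    def test_identical_groups_equal_pooled(self, rng):
        x = rng.uniform(0.5, 1.5, 60)
        y = x + rng.normal(0, 0.2, 60)
        recs = [
            _rec(i, a, b, strain="OR01" if i % 2 else "AND11")
            for i, (a, b) in enumerate(zip(x, y))
        ]
        # duplicate the same (x, y) cloud into both groups
        recs2 = [
            _rec(100 + i, a, b, strain="AND11" if i % 2 else "OR01")
            for i, (a, b) in enumerate(zip(x, y))
        ]
        pooled = od_growth_correlation(recs + recs2)["rho"].iloc[0]
        grouped = od_growth_correlation(recs + recs2, group_by="strain")
        for rho in grouped["rho"]:
            assert rho == pytest.approx(pooled, abs=1e-12)


def _well(i, mean_log, strain="AND11"):
    return WellSummary(
        f"w{i}", strain, 30_000, 30_000, mean_log, 0.1, True,
        strain=parse_strain_label(strain),
    )


class TestFCPRConsistency:
    def test_exact_proportionality(self):
        wells = [_well(i, m) for i, m in enumerate([1.5, 2.0, 2.5, 3.0, 3.5])]
        records = [
            _rec(i, 1.0, 0.5 + 0.1 * i, gfp=0.01 * (0.5 + 0.1 * i) * 10 ** w.mean_log_gfp)
            for i, w in enumerate(wells)
        ]
        rep = fc_pr_consistency(records, wells)
        assert rep.r == pytest.approx(1.0)
        assert rep.intercept == pytest.approx(0.0, abs=1e-9)
        assert rep.outlier_wells == []

    def test_multiplicative_noise_keeps_high_r(self, rng):
        wells = [_well(i, rng.uniform(1.5, 3.5)) for i in range(200)]
        records = []
        for i, w in enumerate(wells):
            od = rng.uniform(0.3, 1.5)
            bulk = 0.01 * od * 10 ** w.mean_log_gfp * rng.lognormal(0, 0.05)
            records.append(_rec(i, 1.0, od, gfp=bulk))
        rep = fc_pr_consistency(records, wells)
        assert rep.r > 0.95

    def test_planted_inconsistency_flagged(self, rng):
        wells = [_well(i, rng.uniform(1.5, 3.5)) for i in range(100)]
        records = []
        for i, w in enumerate(wells):
            od = rng.uniform(0.3, 1.5)
            bulk = 0.01 * od * 10 ** w.mean_log_gfp * rng.lognormal(0, 0.02)
            if i == 57:  # this well's FC channel reads zero per-cell GFP
                bulk = 0.0
            records.append(_rec(i, 1.0, od, gfp=bulk))
        rep = fc_pr_consistency(records, wells)
        assert "w57" in rep.outlier_wells

    def test_no_matched_wells_is_error(self):
        with pytest.raises(ValueError, match="matched"):
            fc_pr_consistency([_rec(0, 1.0, 1.0)], [_well(99, 2.0)])
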