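"""Per-sample mLOY calling: medians, thresholds, QC, and truth recovery."""

import numpy as np
import pandas as pd
import pytest

from mloycf import calling, formulas
from mloycf.calling import CallingConfig, call_cohort, call_mloy_lrr, call_sample
from mloycf.simulate import SimulationConfig, simulate_cohort


def probe_frame(rows):
    """rows: (probe_id, chrom, position, lrr, baf, genotype)"""
    return pd.DataFrame(
        rows, columns=["probe_id", "chrom", "position", "lrr", "baf", "genotype"]
    ).astype({"position": np.int64})


def msy_frame(lrrs):
    return probe_frame(
        [(f"p{i}", "chrY", 3_000_000 + i, lrr, np.nan, "AA") for i, lrr in enumerate(lrrs)]
    )


def par1_het_frame(bafs):
    return probe_frame(
        [(f"h{i}", "chrX", 20_000 + i, 0.0, baf, "AB") for i, baf in enumerate(bafs)]
    )


class TestComputeMlrry:
    def test_odd_count_median(self, region_map):
        value, n, reason = calling.compute_mlrry(msy_frame([-0.1, -0.2, -0.3]), region_map, min_probes=3)
        assert (value, n, reason) == (-0.2, 3, None)

    def test_even_count_midpoint(self, region_map):
        value, n, _ = calling.compute_mlrry(msy_frame([-0.1, -0.3]), region_map, min_probes=2)
        assert value == pytest.approx(-0.2)

    def test_below_min_probes_is_absent_with_reason(self, region_map):
        value, n, reason = calling.compute_mlrry(msy_frame([-0.1] * 29), region_map, min_probes=30)
        assert value is None and n == 29 and reason == calling.FLAG_FEW_MSY

    def test_no_msy_coverage_flagged(self, region_map):
        table = probe_frame([("a", "chr1", 100, 0.0, 0.5, "AB")])
        value, n, reason = calling.compute_mlrry(table, region_map, min_probes=1)
        assert value is None and n == 0 and reason == calling.FLAG_NO_MSY

    def test_missing_lrr_excluded_from_median_and_count(self, region_map):
        value, n, _ = calling.compute_mlrry(msy_frame([-0.1, np.nan, -0.3]), region_map, min_probes=2)
        assert value == pytest.approx(-0.2) and n == 2


class TestMloyDecision:
    def test_inclusive_at_threshold(self):
        assert call_mloy_lrr(-0.15) is True
        assert call_mloy_lrr(-0.15 + 1e-12) is False
        assert call_mloy_lrr(-0.1499) is False
        assert call_mloy_lrr(0.0) is False

    def test_absent_mlrry_gives_no_call(self):
        assert call_mloy_lrr(None) is None

    def test_threshold_must_be_negative(self):
        with pytest.raises(ValueError):
            call_mloy_lrr(-0.2, threshold=0.0)


class TestEstimateBdev:
    def test_no_deviation(self, region_map):
        value, n, _ = calling.estimate_bdev(par1_het_frame([0.5, 0.5, 0.5]), region_map, min_het=3)
        assert value == 0.0 and n == 3

    def test_median_absolute_deviation(self, region_map):
        value, _, _ = calling.estimate_bdev(
            par1_het_frame([0.266, 0.734, 0.27, 0.73]), region_map, min_het=4
        )
        assert value == pytest.approx(0.232)

    def test_too_few_hets_absent(self, region_map):
        value, n, reason = calling.estimate_bdev(par1_het_frame([0.4] * 5), region_map, min_het=30)
        assert value is None and n == 5 and reason == calling.FLAG_FEW_HET

    def test_homozygotes_do_not_enter(self, region_map):
        table = pd.concat(
            [par1_het_frame([0.45, 0.55, 0.44]),
             probe_frame([("hom", "chrX", 30_000, 0.0, 0.99, "BB")])],
            ignore_index=True,
        )
        value, n, _ = calling.estimate_bdev(table, region_map, min_het=3)
        assert n == 3 and value == pytest.approx(0.05)


class TestComputeQC:
    def test_full_call_rate_and_rel_cov_fixed_point(self, region_map):
        table = pd.concat(
            [par1_het_frame([0.5] * 4), msy_frame([-0.1] * 4)], ignore_index=True
        )
        qc = calling.compute_qc(table, region_map)
        assert qc.call_rate == 1.0
        assert qc.rel_cov_par1 == pytest.approx(2.0)  # PAR1 median LRR = 0

    def test_white_noise_baf_has_small_autocorrelation(self, region_map, rng):
        for _ in range(5):
            baf = np.clip(0.5 + 0.05 * rng.standard_normal(10_000), 0, 1)
            table = probe_frame(
                [(f"a{i}", "chr1", 1_000 + i, 0.0, b, "AB") for i, b in enumerate(baf)]
            )
            qc = calling.compute_qc(table, region_map)
            assert abs(qc.baf_auto) < 0.05

    def test_too_few_autosomal_probes_gives_absent_baf_auto(self, region_map):
        qc = calling.compute_qc(probe_frame([("a", "chr1", 100, 0.0, 0.5, "AB")]), region_map)
        assert qc.baf_auto is None


class TestCallSample:
    def test_normal_male_noiseless(self):
        cohort, _ = simulate_cohort(
            SimulationConfig(cf=(0.0,), seed=1, sigma_lrr=0.0, sigma_baf=0.0,
                             n_autosomal_probes=50)
        )
        call = call_cohort(cohort)[0]
        assert call.mloy_lrr is False
        assert call.cf_mlrry == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_recovery_over_cf_grid(self):
        cfs = tuple(np.linspace(0.05, 0.95, 10))
        cohort, _ = simulate_cohort(
            SimulationConfig(cf=cfs, seed=2, sigma_lrr=0.0, sigma_baf=0.0,
                             n_autosomal_probes=0, n_par1_probes=0)
        )
        calls = call_cohort(cohort)
        for call, cf in zip(calls, cfs):
            assert call.mlrr_y == pytest.approx(0.45 * np.log2(1 - cf), abs=1e-12)
            assert call.cf_mlrry == pytest.approx(cf, abs=1e-9)

    def test_noiseless_female_reads_as_near_total_loss(self):
        cohort, _ = simulate_cohort(
            SimulationConfig(cf=(0.0,), sex="female", seed=3, sigma_lrr=0.0,
                             sigma_baf=0.0, cn_floor=0.005, n_autosomal_probes=50)
        )
        call = call_cohort(cohort)[0]
        assert call.cf_mlrry >= 0.99
        assert call.mloy_lrr is True

    def test_positive_mlrry_flagged_and_cf_absent(self, region_map):
        call = call_sample("S", msy_frame([0.02] * 35), region_map)
        assert call.cf_mlrry is None
        assert calling.FLAG_POSITIVE_MLRRY in call.flags
        assert call.mloy_lrr is False

    def test_call_invariant_to_probe_order(self, region_map, rng):
        cohort, _ = simulate_cohort(
            SimulationConfig(cf=(0.4,), seed=4, n_autosomal_probes=100)
        )
        table = cohort.drop(columns="sample_id")
        base = call_sample("S", table, region_map)
        shuffled = table.sample(frac=1, random_state=7).reset_index(drop=True)
        assert call_sample("S", shuffled, region_map) == base

    def test_qc_failures_flag_but_keep_measurements(self, region_map):
        # female-style sample: Y probes uncalled -> call rate below 0.97
        cohort, _ = simulate_cohort(
            SimulationConfig(cf=(0.0,), sex="female", seed=5, sigma_lrr=0.0,
                             sigma_baf=0.0, n_autosomal_probes=50)
        )
        call = call_cohort(cohort)[0]
        assert calling.FLAG_QC_CALL_RATE in call.flags
        assert call.qc_pass is False
        assert call.mlrr_y is not None  # measurement retained

    def test_cohort_path_matches_per_sample_path(self, region_map):
        cohort, _ = simulate_cohort(
            SimulationConfig(cf=(0.0, 0.3, 0.8), seed=6, n_autosomal_probes=80)
        )
        bulk = {c.sample_id: c for c in call_cohort(cohort, region_map)}
        for sid, grp in cohort.groupby("sample_id"):
            single = call_sample(sid, grp.drop(columns="sample_id").reset_index(drop=True), region_map)
            assert single == bulk[sid]


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("mloy_threshold: -0.2\nmin_msy_probes: 10\n")
        config = CallingConfig.from_yaml(path)
        assert config.mloy_threshold == -0.2 and config.min_msy_probes == 10
        assert config.scale == formulas.DEFAULT_SCALE

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            CallingConfig(mloy_threshold=0.1)
        with pytest.raises(ValueError):
            CallingConfig(min_msy_probes=0)
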