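"""Atlas tallies, region selection, regional volumes, hierarchical OLS."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fluencymap.cohort import AtlasVolume, LesionMap, lesion_prevalence
from fluencymap.roi import (
    RegionReport,
    fit_roi_model,
    region_voxel_report,
    regional_lesion_volume,
    regional_volume_table,
    select_regions,
)
from fluencymap.vlsm import apply_fdr, build_test_mask, voxelwise_ttest

from conftest import handmade_cohort, tiny_grid


def _atlas(grid, labels_spec):
    labels = np.zeros(grid.dims, dtype=np.int32)
    for lab, voxels in labels_spec.items():
        for v in voxels:
            labels[v] = lab
    names = {lab: f"region_{lab}" for lab in labels_spec}
    return AtlasVolume(grid=grid, labels=labels, region_table=names)


def _cohort_with_maps(rng, n=20):
    lesions = {
        f"s{i:02d}": [tuple(v) for v in rng.integers(0, 8, size=(rng.integers(5, 50), 3))]
        for i in range(n)
    }
    cohort = handmade_cohort(lesions)
    z = pd.Series(rng.normal(0, 1, n), index=cohort.subject_ids)
    mask = build_test_mask(lesion_prevalence(cohort), n, min_count=3)
    smap = apply_fdr(voxelwise_ttest(cohort, z, mask), q=0.3)
    return cohort, mask, smap


class TestRegionReport:
    def test_counts_match_bruteforce_tallies(self):
        rng = np.random.default_rng(40)
        cohort, mask, smap = _cohort_with_maps(rng)
        grid = cohort.grid
        # random two-region atlas
        labels = rng.integers(0, 3, size=grid.dims).astype(np.int32)
        atlas = AtlasVolume(grid=grid, labels=labels, region_table={1: "r1", 2: "r2"})
        report = region_voxel_report({"out": smap}, mask, atlas, cohort)
        for lab in (1, 2):
            region = labels == lab
            row = report.table.set_index("label").loc[lab]
            assert row["region_size_voxels"] == region.sum()
            assert row["tested_voxels"] == (region & mask.tested).sum()
            assert row["sig_out"] == (region & smap.significant).sum()
            expect_patients = sum(
                bool((m.voxels.astype(bool) & region).any()) for m in cohort.lesion_maps
            )
            assert row["patients_with_lesion"] == expect_patients
            if row["tested_voxels"]:
                assert np.isclose(
                    row["pct_out"], 100 * row["sig_out"] / row["tested_voxels"]
                )

    def test_empty_significance_all_zero(self):
        rng = np.random.default_rng(41)
        cohort, mask, smap = _cohort_with_maps(rng)
        strict = apply_fdr(smap, q=1e-12)
        atlas = _atlas(cohort.grid, {1: [(1, 1, 1), (2, 2, 2)]})
        report = region_voxel_report({"out": strict}, mask, atlas)
        assert (report.table["sig_out"] == 0).all()

    def test_whole_grid_region_tested_equals_mask(self):
        rng = np.random.default_rng(42)
        cohort, mask, smap = _cohort_with_maps(rng)
        labels = np.ones(cohort.grid.dims, dtype=np.int32)
        atlas = AtlasVolume(grid=cohort.grid, labels=labels, region_table={1: "all"})
        report = region_voxel_report({"out": smap}, mask, atlas)
        assert report.table.iloc[0]["tested_voxels"] == mask.n_tested


class TestSelectRegions:
    def _report(self, sig_counts):
        table = pd.DataFrame(
            {
                "label": list(range(1, len(sig_counts) + 1)),
                "region": [f"r{i}" for i in range(len(sig_counts))],
                "sig_out": sig_counts,
            }
        )
        return RegionReport(table=table, outcomes=("out",))

    def test_threshold_boundary(self):
        sel = select_regions(self._report([100, 99, 150]), min_sig=100)
        assert sel.selected["out"] == [1, 3]

    def test_empty_report_empty_selection(self):
        sel = select_regions(self._report([]), min_sig=100)
        assert sel.selected["out"] == []

    def test_monotone_in_min_sig(self):
        report = self._report([10, 60, 110, 250])
        loose = set(select_regions(report, min_sig=50).selected["out"])
        strict = set(select_regions(report, min_sig=150).selected["out"])
        assert strict <= loose


class TestRegionalVolume:
    def test_unit_conversion_1000_voxels_is_1ml(self):
        grid = tiny_grid(12)
        labels = np.zeros(grid.dims, dtype=np.int32)
        labels[:10, :10, :10] = 1
        atlas = AtlasVolume(grid=grid, labels=labels, region_table={1: "cube"})
        voxels = np.zeros(grid.dims, dtype=np.uint8)
        voxels[:10, :10, :10] = 1  # 1000 lesioned voxels of 1 mm^3
        lesion = LesionMap("s", grid, voxels)
        assert regional_lesion_volume(lesion, atlas, 1) == pytest.approx(1.0)

    def test_no_overlap_zero(self):
        grid = tiny_grid()
        atlas = _atlas(grid, {1: [(0, 0, 0)]})
        voxels = np.zeros(grid.dims, dtype=np.uint8)
        voxels[5, 5, 5] = 1
        assert regional_lesion_volume(LesionMap("s", grid, voxels), atlas, 1) == 0.0

    def test_unknown_region_rejected(self):
        grid = tiny_grid()
        atlas = _atlas(grid, {1: [(0, 0, 0)]})
        lesion = LesionMap("s", grid, np.zeros(grid.dims, dtype=np.uint8))
        with pytest.raises(KeyError):
            regional_lesion_volume(lesion, atlas, 9)

    def test_bruteforce_equality_and_additivity(self):
        rng = np.random.default_rng(43)
        grid = tiny_grid()
        labels = rng.integers(0, 4, size=grid.dims).astype(np.int32)
        atlas = AtlasVolume(
            grid=grid, labels=labels, region_table={1: "a", 2: "b", 3: "c"}
        )
        voxels = (rng.random(grid.dims) > 0.6).astype(np.uint8)
        lesion = LesionMap("s", grid, voxels)
        total_in_regions = 0.0
        for lab in (1, 2, 3):
            vol = regional_lesion_volume(lesion, atlas, lab)
            brute = (voxels.astype(bool) & (labels == lab)).sum() / 1000.0
            assert vol == pytest.approx(brute)
            total_in_regions += vol
        assert total_in_regions <= lesion.volume_ml + 1e-12


def _regression_data(rng, n=80, b_roi=-0.4):
    demo = pd.DataFrame(
        {
            "age": rng.normal(60, 12, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.integers(1, 8, n).astype(float),
        }
    )
    roi = pd.Series(rng.exponential(2.0, n))
    total = roi + pd.Series(rng.exponential(3.0, n))
    z = pd.Series(
        -0.01 * demo["age"] + 0.2 * demo["sex"] + 0.1 * demo["education"]
        + b_roi * roi + rng.normal(0, 1, n)
    )
    return z, demo, roi, total


class TestFitRoiModel:
    def test_constant_roi_volume_adds_nothing(self):
        rng = np.random.default_rng(44)
        z, demo, _, _ = _regression_data(rng)
        fit = fit_roi_model(z, demo, pd.Series(np.zeros(len(z))))
        assert fit.r2_full == fit.r2_base
        assert fit.delta_r2 == 0.0
        assert fit.p_delta == 1.0

    def test_partial_f_equals_coefficient_t_test(self):
        rng = np.random.default_rng(45)
        z, demo, roi, total = _regression_data(rng)
        fit = fit_roi_model(z, demo, roi, total)
        X_full = sm.add_constant(
            pd.DataFrame(
                {
                    "age": demo["age"],
                    "sex": demo["sex"],
                    "education": demo["education"],
                    "total_ml": total,
                    "roi_ml": roi,
                }
            )
        )
        ref = sm.OLS(z, X_full).fit()
        assert np.isclose(fit.p_delta, ref.pvalues["roi_ml"], atol=1e-10)
        assert np.isclose(fit.B, ref.params["roi_ml"], atol=1e-12)

    def test_invariants_delta_r2_and_ci(self):
        rng = np.random.default_rng(46)
        z, demo, roi, _ = _regression_data(rng)
        fit = fit_roi_model(z, demo, roi)
        assert 0.0 <= fit.r2_base <= fit.r2_full <= 1.0
        assert fit.ci95[0] <= fit.B <= fit.ci95[1]

    def test_collinear_roi_and_total_rejected(self):
        rng = np.random.default_rng(47)
        z, demo, roi, _ = _regression_data(rng)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_roi_model(z, demo, roi, total_volume_ml=2.0 * roi)

    def test_listwise_deletion_counts(self):
        rng = np.random.default_rng(48)
        z, demo, roi, _ = _regression_data(rng, n=40)
        z.iloc[:3] = np.nan
        fit = fit_roi_model(z, demo, roi)
        assert fit.n_used == 37

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(49)
        z, demo, roi, _ = _regression_data(rng, n=8)
        with pytest.raises(ValueError, match="complete cases"):
            fit_roi_model(z, demo, roi)

    def test_recovers_generative_coefficient(self):
        rng = np.random.default_rng(50)
        z, demo, roi, _ = _regression_data(rng, n=500, b_roi=-0.4)
        fit = fit_roi_model(z, demo, roi)
        assert fit.ci95[0] <= -0.4 <= fit.ci95[1]


def test_regional_volume_table_consistency(small_cohort):
    labels = sorted(small_cohort.atlas.region_table)
    table = regional_volume_table(small_cohort, small_cohort.atlas, labels)
    for m in small_cohort.lesion_maps:
        row = table.loc[m.subject_id]
        assert row["total_ml"] == pytest.approx(m.volume_ml)
        # toy atlas labels partition a subset of the brain: region sum <= total
        region_sum = sum(row[f"region_{lab}_ml"] for lab in labels)
        assert region_sum <= row["total_ml"] + 1e-12
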