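"""Mass-univariate engine: mask rule, t and BM statistics, FDR, overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fluencymap.cohort import CountMap, lesion_prevalence
from fluencymap.vlsm import (
    apply_fdr,
    brunner_munzel_stat,
    build_test_mask,
    fdr_threshold,
    overlap_map,
    voxelwise_brunner_munzel,
    voxelwise_ttest,
)

from conftest import handmade_cohort, tiny_grid


def _random_cohort(rng, n_subjects=24, missing=0):
    """Random lesions on an 8^3 grid plus adjusted-score stand-ins."""
    lesions = {
        f"s{i:02d}": [
            tuple(v) for v in rng.integers(0, 8, size=(rng.integers(5, 60), 3))
        ]
        for i in range(n_subjects)
    }
    cohort = handmade_cohort(lesions)
    z = pd.Series(rng.normal(0, 1, n_subjects), index=cohort.subject_ids)
    if missing:
        z.iloc[rng.choice(n_subjects, missing, replace=False)] = np.nan
    return cohort, z


class TestTestMask:
    def test_min_count_boundary(self):
        grid = tiny_grid()
        counts = np.zeros(grid.dims, dtype=int)
        counts[0, 0, 0] = 2  # below threshold: never tested
        counts[1, 1, 1] = 3  # at threshold: tested
        mask = build_test_mask(CountMap(grid, counts), n_subjects=10, min_count=3)
        assert not mask.tested[0, 0, 0]
        assert mask.tested[1, 1, 1]
        assert mask.min_count == 3

    def test_all_zero_prevalence_empty_mask(self):
        grid = tiny_grid()
        mask = build_test_mask(CountMap(grid, np.zeros(grid.dims, int)), 10)
        assert mask.is_empty

    def test_voxel_lesioned_in_everyone_excluded(self):
        grid = tiny_grid()
        counts = np.zeros(grid.dims, dtype=int)
        counts[2, 2, 2] = 10  # all subjects lesioned: no intact group
        mask = build_test_mask(CountMap(grid, counts), n_subjects=10)
        assert not mask.tested[2, 2, 2]


class TestVoxelwiseTTest:
    def _mask_and_map(self, cohort, z, **kw):
        mask = build_test_mask(lesion_prevalence(cohort), cohort.n_subjects, min_count=3)
        return mask, voxelwise_ttest(cohort, z, mask, **kw)

    def test_handmade_two_group_case(self):
        # lesioned subjects score {-2,-1}, intact {0,1} at a shared voxel
        cohort = handmade_cohort(
            {"a": [(1, 1, 1)], "b": [(1, 1, 1)], "c": [(1, 1, 1)], "d": [(5, 5, 5)]}
        )
        z = pd.Series({"a": -2.0, "b": -1.0, "c": -1.5, "d": 0.0})
        mask = build_test_mask(lesion_prevalence(cohort), 4, min_count=3)
        # voxel (1,1,1) has 3 lesioned, 1 intact -> intact group too small, flagged
        smap = voxelwise_ttest(cohort, z, mask)
        assert smap.degenerate[1, 1, 1]
        assert smap.p[1, 1, 1] == 1.0

    def test_matches_scipy_per_voxel_loop(self):
        rng = np.random.default_rng(12)
        cohort, z = _random_cohort(rng, n_subjects=30, missing=3)
        mask, smap = self._mask_and_map(cohort, z, tails="one")
        L = cohort.lesion_matrix().astype(bool)
        zv = z.to_numpy()
        use = np.isfinite(zv)
        checked = 0
        for flat_idx in np.flatnonzero(mask.tested.ravel()):
            idx = np.unravel_index(flat_idx, cohort.grid.dims)
            lesioned = L[:, flat_idx] & use
            intact = ~L[:, flat_idx] & use
            if lesioned.sum() < 2 or intact.sum() < 2:
                continue
            ref = stats.ttest_ind(zv[intact], zv[lesioned], equal_var=True)
            if np.isnan(ref.statistic):
                continue
            assert np.isclose(smap.statistic[idx], ref.statistic, atol=1e-10)
            one_tailed = stats.t.sf(ref.statistic, lesioned.sum() + intact.sum() - 2)
            assert np.isclose(smap.p[idx], one_tailed, atol=1e-10)
            checked += 1
        assert checked > 20

    def test_sign_conventions(self):
        # lesioned group BETTER -> negative t, never significant one-tailed
        lesions = {f"L{i}": [(1, 1, 1)] for i in range(5)}
        lesions.update({f"I{i}": [(6, 6, 6)] for i in range(5)})
        cohort = handmade_cohort(lesions)
        z = pd.Series(
            {**{f"L{i}": 1.0 + 0.1 * i for i in range(5)},
             **{f"I{i}": -1.0 - 0.1 * i for i in range(5)}}
        )
        mask = build_test_mask(lesion_prevalence(cohort), 10, min_count=3)
        smap = apply_fdr(voxelwise_ttest(cohort, z, mask), q=0.05)
        assert smap.statistic[1, 1, 1] < 0
        assert not smap.significant[1, 1, 1]
        # one-tailed inference can only ever flag lesion->worse voxels
        assert (smap.statistic[smap.significant] > 0).all()
        # flipped scores: lesioned worse -> positive t
        smap2 = voxelwise_ttest(cohort, -z, mask)
        assert smap2.statistic[1, 1, 1] > 0

    def test_identical_group_means(self):
        lesions = {f"L{i}": [(1, 1, 1)] for i in range(3)}
        lesions.update({f"I{i}": [(6, 6, 6)] for i in range(3)})
        cohort = handmade_cohort(lesions)
        z = pd.Series(
            {**{f"L{i}": float(i - 1) for i in range(3)},
             **{f"I{i}": float(i - 1) for i in range(3)}}
        )
        mask = build_test_mask(lesion_prevalence(cohort), 6, min_count=3)
        smap = voxelwise_ttest(cohort, z, mask)
        assert np.isclose(smap.statistic[1, 1, 1], 0.0)
        assert np.isclose(smap.p[1, 1, 1], 0.5)

    def test_zero_variance_voxel_flagged(self):
        lesions = {f"L{i}": [(1, 1, 1)] for i in range(3)}
        lesions.update({f"I{i}": [(6, 6, 6)] for i in range(3)})
        cohort = handmade_cohort(lesions)
        z = pd.Series({sid: 1.0 for sid in cohort.subject_ids})
        mask = build_test_mask(lesion_prevalence(cohort), 6, min_count=3)
        smap = voxelwise_ttest(cohort, z, mask)
        assert smap.degenerate[1, 1, 1]
        assert smap.p[1, 1, 1] == 1.0
        assert smap.statistic[1, 1, 1] == 0.0

    def test_shift_invariance_and_negation(self):
        rng = np.random.default_rng(13)
        cohort, z = _random_cohort(rng)
        mask, smap = self._mask_and_map(cohort, z)
        shifted = voxelwise_ttest(cohort, z + 7.5, mask)
        np.testing.assert_allclose(
            smap.statistic[mask.tested], shifted.statistic[mask.tested], atol=1e-10
        )
        negated = voxelwise_ttest(cohort, -z, mask)
        np.testing.assert_allclose(
            smap.statistic[mask.tested], -negated.statistic[mask.tested], atol=1e-10
        )


class TestBrunnerMunzel:
    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            x = rng.normal(0, 1, rng.integers(5, 20))
            y = rng.normal(0.5, 2, rng.integers(5, 20))
            s, df, p = brunner_munzel_stat(x, y)
            ref = stats.brunnermunzel(x, y, alternative="less", distribution="t")
            assert np.isclose(s, ref.statistic, atol=1e-8)
            assert np.isclose(p, ref.pvalue, atol=1e-8)

    def test_voxelwise_matches_scipy_loop(self):
        rng = np.random.default_rng(15)
        cohort, z = _random_cohort(rng, n_subjects=26, missing=2)
        mask = build_test_mask(lesion_prevalence(cohort), cohort.n_subjects, min_count=3)
        smap = voxelwise_brunner_munzel(cohort, z, mask)
        L = cohort.lesion_matrix().astype(bool)
        zv = z.to_numpy()
        use = np.isfinite(zv)
        checked = 0
        for flat_idx in np.flatnonzero(mask.tested.ravel()):
            idx = np.unravel_index(flat_idx, cohort.grid.dims)
            x = zv[L[:, flat_idx] & use]
            y = zv[~L[:, flat_idx] & use]
            if len(x) < 2 or len(y) < 2:
                continue
            ref = stats.brunnermunzel(x, y, alternative="less", distribution="t")
            assert np.isclose(smap.statistic[idx], ref.statistic, atol=1e-8)
            assert np.isclose(smap.p[idx], ref.pvalue, atol=1e-8)
            checked += 1
        assert checked > 20

    def test_identical_samples_statistic_zero(self):
        s, _, p = brunner_munzel_stat(np.ones(5), np.ones(5))
        assert s == 0.0 and p == 1.0

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(16)
        cohort, z = _random_cohort(rng, n_subjects=20)
        mask = build_test_mask(lesion_prevalence(cohort), 20, min_count=3)
        a = voxelwise_brunner_munzel(cohort, z, mask)
        b = voxelwise_brunner_munzel(cohort, np.exp(z / 2.0), mask)
        np.testing.assert_allclose(
            a.statistic[mask.tested], b.statistic[mask.tested], atol=1e-10
        )


class TestFdr:
    def test_all_tiny_p_all_significant(self):
        cutoff, sig = fdr_threshold(np.full(100, 0.001), q=0.05)
        assert sig.all()
        assert cutoff == 0.001

    def test_hand_computed_step_up(self):
        # sorted p: .01 <= 1*.05/4, .02 <= 2*.05/4, .9 > 3*.05/4, .95 > .05
        cutoff, sig = fdr_threshold(np.array([0.01, 0.02, 0.9, 0.95]), q=0.05)
        assert cutoff == 0.02
        assert sig.tolist() == [True, True, False, False]

    def test_no_survivor_gives_zero_cutoff(self):
        cutoff, sig = fdr_threshold(np.array([0.5, 0.8, 0.9]), q=0.05)
        assert cutoff == 0.0
        assert not sig.any()

    def test_matches_statsmodels_bh(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            p = rng.random(200) ** 2
            _, sig = fdr_threshold(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(sig, ref)

    def test_monotone_in_q(self):
        rng = np.random.default_rng(18)
        p = rng.random(500) ** 3
        _, sig1 = fdr_threshold(p, q=0.01)
        _, sig2 = fdr_threshold(p, q=0.05)
        assert (sig1 <= sig2).all()  # sig at stricter q is a subset

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold(np.array([0.1, 1.2]))
        with pytest.raises(ValueError):
            fdr_threshold(np.array([]))


class TestOverlapMap:
    def _sig_map(self, cohort, z, mask, q=0.3):
        return apply_fdr(voxelwise_ttest(cohort, z, mask), q=q)

    def test_category_algebra(self):
        rng = np.random.default_rng(19)
        cohort, z1 = _random_cohort(rng, n_subjects=24)
        z2 = pd.Series(rng.normal(0, 1, 24), index=cohort.subject_ids)
        mask = build_test_mask(lesion_prevalence(cohort), 24, min_count=3)
        a = self._sig_map(cohort, z1, mask)
        b = self._sig_map(cohort, z2, mask)
        om = overlap_map(a, b, names=("s", "p"))
        np.testing.assert_array_equal(om.category == 3, a.significant & b.significant)
        np.testing.assert_array_equal(om.category == 1, a.significant & ~b.significant)
        np.testing.assert_array_equal(om.category == 2, ~a.significant & b.significant)
        counts = om.counts()
        assert sum(counts.values()) == np.prod(cohort.grid.dims)

    def test_identical_maps_all_both(self):
        rng = np.random.default_rng(20)
        cohort, z = _random_cohort(rng, n_subjects=24)
        mask = build_test_mask(lesion_prevalence(cohort), 24, min_count=3)
        a = self._sig_map(cohort, z, mask)
        om = overlap_map(a, a)
        assert ((om.category == 3) == a.significant).all()
        assert not ((om.category == 1) | (om.category == 2)).any()

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(21)
        cohort, z = _random_cohort(rng, n_subjects=12)
        mask = build_test_mask(lesion_prevalence(cohort), 12, min_count=3)
        a = self._sig_map(cohort, z, mask)
        other = handmade_cohort(
            {f"s{i}": [(1, 1, 1)] if i < 4 else [(2, 2, 2)] for i in range(6)},
            grid=tiny_grid(6),
        )
        z2 = pd.Series(np.arange(6.0), index=other.subject_ids)
        mask2 = build_test_mask(lesion_prevalence(other), 6, min_count=3)
        b = self._sig_map(other, z2, mask2)
        with pytest.raises(Exception):
            overlap_map(a, b)


def test_significance_monotone_in_q():
    rng = np.random.default_rng(22)
    cohort, z = _random_cohort(rng, n_subjects=30)
    mask = build_test_mask(lesion_prevalence(cohort), 30, min_count=3)
    smap = voxelwise_ttest(cohort, z, mask)
    sig_small = apply_fdr(smap, q=0.02).significant
    sig_large = apply_fdr(smap, q=0.2).significant
    assert (sig_small <= sig_large).all()


def test_single_causal_region_sensitivity_and_specificity():
    """With one causal region and moderate lesions, VLSM finds most of the
    region while keeping out-of-region detections rare (seed-averaged)."""
    from fluencymap.behavior import PHONEMIC, SEMANTIC
    from fluencymap.pipeline import RunConfig, run_full_analysis
    from fluencymap.synthetic import SyntheticConfig, make_cohort

    config = SyntheticConfig(
        n_subjects=400,
        lesion_volume_range=(60, 300),
        truth_weights={SEMANTIC: {"left_temporal": 150.0}, PHONEMIC: {}},
    )
    sens, fp = [], []
    for seed in range(5):
        cohort = make_cohort(config, seed=seed)
        res = run_full_analysis(cohort, RunConfig(outcomes=(SEMANTIC,)))
        smap = res.stat_maps[SEMANTIC]
        causal = cohort.ground_truth.causal_mask(SEMANTIC)
        sens.append(smap.significant[causal & smap.tested].mean())
        fp.append(smap.significant[~causal & smap.tested].mean())
    assert np.mean(sens) >= 0.8
    assert np.mean(fp) <= 0.05
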