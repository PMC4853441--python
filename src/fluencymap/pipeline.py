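"""End-to-end study-replica pipeline.

Sequences the full analysis from one configuration: fluency scoring →
demographic z-adjustment → voxel-based lesion-symptom mapping per outcome
with FDR control → overlap map → dichotomized overlay/subtraction maps →
atlas region report and ≥min_sig region selection → hierarchical ROI
regressions with and without total-lesion-volume adjustment — and writes
every map (NIfTI), table (CSV) and a JSON run manifest recording each
parameter and software decision.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import behavior as bh
from . import roi as roi_mod
from . import subtraction as sub_mod
from . import vlsm
from .behavior import NormTable, PHONEMIC, SEMANTIC
from .cohort import Cohort, LesionMap, lesion_prevalence
from .util import percent_display, round_half_up

logger = logging.getLogger("fluencymap")

__all__ = ["RunConfig", "RunResult", "run_full_analysis", "describe_cohort", "classify_laterality"]


@dataclass
class RunConfig:
    """All analysis parameters for one pipeline run."""

    outcomes: tuple[str, ...] = (SEMANTIC, PHONEMIC)
    min_count: int = 3  # voxels lesioned in fewer patients are not tested
    q: float = 0.05
    statistic_kind: str = "t"  # "t" | "brunner_munzel"
    tails: str = "one"
    min_sig: int = 100  # region-selection threshold (significant voxels)
    adjust_total_volume: str = "both"  # "off" | "on" | "both"
    display_threshold: int = 3
    midline_band_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.statistic_kind not in ("t", "brunner_munzel"):
            raise ValueError(f"unknown statistic_kind {self.statistic_kind!r}")
        if self.tails not in ("one", "two"):
            raise ValueError(f"tails must be 'one' or 'two'")
        if self.adjust_total_volume not in ("off", "on", "both"):
            raise ValueError("adjust_total_volume must be off/on/both")
        if not (0 < self.q < 1):
            raise ValueError(f"q must be in (0, 1), got {self.q}")
        if self.min_count < 1 or self.min_sig < 1:
            raise ValueError("min_count and min_sig must be >= 1")

    def as_dict(self) -> dict:
        return {
            "outcomes": list(self.outcomes),
            "min_count": self.min_count,
            "q": self.q,
            "statistic_kind": self.statistic_kind,
            "tails": self.tails,
            "min_sig": self.min_sig,
            "adjust_total_volume": self.adjust_total_volume,
            "display_threshold": self.display_threshold,
            "midline_band_mm": self.midline_band_mm,
            "seed": self.seed,
        }


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    out_dir: Path | None
    prevalence: object
    z_scores: pd.DataFrame
    correlations: pd.DataFrame
    stat_maps: dict[str, vlsm.StatMap]
    overlap: vlsm.OverlapMap | None
    flags: pd.DataFrame
    overlays: dict[str, sub_mod.GroupOverlay]
    subtractions: dict[str, sub_mod.SubtractionMap]
    region_report: roi_mod.RegionReport | None
    roi_selection: roi_mod.RoiSelection | None
    roi_models: pd.DataFrame
    descriptives: dict[str, pd.DataFrame]
    manifest: dict


def classify_laterality(
    lesion: LesionMap,
    infratentorial_mask: np.ndarray | None = None,
    midline_band_mm: float = 0.0,
) -> str:
    """Assign a lesion to left / right / infratentorial / multiple.

    A lesion with most of its voxels inside the infratentorial mask is
    "infratentorial".  Otherwise the world x coordinates of lesioned
    voxels decide: all strictly left of the midline band → "left", all
    strictly right → "right", voxels on both sides → "multiple".  Voxels
    inside the band (|x| <= band) are ignored for the determination.
    """
    idx = np.argwhere(lesion.voxels > 0)
    if len(idx) == 0:
        return "none"
    if infratentorial_mask is not None:
        frac = lesion.voxels[infratentorial_mask].sum() / lesion.volume_voxels
        if frac > 0.5:
            return "infratentorial"
    x = lesion.grid.world_coordinates(idx)[:, 0]
    left = (x < -midline_band_mm).any()
    right = (x > midline_band_mm).any()
    if left and right:
        return "multiple"
    if left:
        return "left"
    if right:
        return "right"
    return "multiple"  # everything inside the band


LATERALITY_ORDER = ("left", "right", "infratentorial", "multiple")


def describe_cohort(
    cohort: Cohort,
    flags: pd.DataFrame,
    infratentorial_mask: np.ndarray | None = None,
    midline_band_mm: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Descriptive tables: cohort characteristics, impairment prevalence,
    and the laterality × impairment cross-table.

    ``flags`` is a subjects × outcomes boolean frame (NA allowed).
    Percentages are displayed half-up as integers; a group of size zero
    yields missing percentages rather than a division error.
    """
    frame = cohort.behavior_frame()
    n = cohort.n_subjects
    characteristics = pd.DataFrame(
        [
            {"characteristic": "n", "value": n, "detail": ""},
            {
                "characteristic": "age_mean_sd",
                "value": round(float(frame["age"].mean()), 1),
                "detail": f"sd {frame['age'].std():.1f}",
            },
            {
                "characteristic": "male_n_pct",
                "value": int(frame["sex"].sum()),
                "detail": f"{percent_display(frame['sex'].sum(), n)} %",
            },
            {
                "characteristic": "education_median_range",
                "value": float(frame["education"].median()),
                "detail": f"range {int(frame['education'].min())}-{int(frame['education'].max())}",
            },
        ]
    )

    rows = []
    for outcome in flags.columns:
        col = flags[outcome]
        defined = col.notna()
        n_def = int(defined.sum())
        n_imp = int(col[defined].astype(bool).sum())
        rows.append(
            {
                "outcome": outcome,
                "n_defined": n_def,
                "n_impaired": n_imp,
                "pct_impaired": percent_display(n_imp, n_def) if n_def else np.nan,
            }
        )
    prevalence_table = pd.DataFrame(rows)

    laterality = pd.Series(
        {
            m.subject_id: classify_laterality(m, infratentorial_mask, midline_band_mm)
            for m in cohort.lesion_maps
        },
        name="laterality",
    )
    lat_rows = []
    for outcome in flags.columns:
        col = flags[outcome]
        for status, wanted in (("impaired", True), ("normal", False)):
            grp = [
                sid
                for sid in cohort.subject_ids
                if pd.notna(col.get(sid, pd.NA)) and bool(col[sid]) == wanted
            ]
            total = len(grp)
            for loc in LATERALITY_ORDER:
                count = int(sum(laterality[sid] == loc for sid in grp))
                lat_rows.append(
                    {
                        "outcome": outcome,
                        "group": status,
                        "group_n": total,
                        "laterality": loc,
                        "n": count,
                        "pct": percent_display(count, total) if total else np.nan,
                    }
                )
    laterality_table = pd.DataFrame(lat_rows)
    return {
        "characteristics": characteristics,
        "impairment_prevalence": prevalence_table,
        "laterality": laterality_table,
        "laterality_per_subject": laterality.rename_axis("subject_id").reset_index(),
    }


def _adjusted_scores(cohort: Cohort, tests: list[str]) -> tuple[pd.DataFrame, dict]:
    frame = cohort.behavior_frame()
    scored = bh.fluency_scores(frame)
    z_cols = {}
    meta = {}
    for test in tests:
        res = bh.adjust_for_demographics(
            scored[test], scored["age"], scored["sex"], scored["education"], test=test
        )
        z_cols[test] = res.z
        meta[test] = {
            "n_used": res.n_used,
            "coefficients": res.coefficients,
            "residual_sd": res.residual_sd,
            "residual_sd_denominator": "n - p",
        }
    return pd.DataFrame(z_cols), meta


def run_full_analysis(
    cohort: Cohort,
    config: RunConfig | None = None,
    norms: NormTable | None = None,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Run the complete analysis on an assembled cohort.

    When ``out_dir`` is given, all maps, tables and a manifest sufficient
    to re-run the analysis identically are written there; any stage
    failure aborts with the stage name, leaving partial outputs plus an
    ``INCOMPLETE`` marker.
    """
    config = config or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "INCOMPLETE").write_text("run in progress or aborted\n")
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        result = _run_stages(cohort, config, norms, out, timings)
    except Exception as exc:  # annotate failures with the stage
        raise RuntimeError(f"pipeline failed at stage {_CURRENT_STAGE[0]!r}: {exc}") from exc
    if out is not None:
        (out / "INCOMPLETE").unlink(missing_ok=True)
    return result


_CURRENT_STAGE = ["setup"]


def _stage(name: str, timings: dict):
    _CURRENT_STAGE[0] = name
    timings[name] = time.perf_counter()
    logger.info("stage %s", name)


def _run_stages(cohort, config, norms, out, timings) -> RunResult:
    scored_frame = bh.fluency_scores(cohort.behavior_frame())
    extra_tests = [
        c
        for c in scored_frame.columns
        if c
        not in (
            "age",
            "sex",
            "education",
            bh.TRIAL_ANIMALS,
            bh.TRIAL_LETTER_N,
            bh.TRIAL_LETTER_A,
            SEMANTIC,
            PHONEMIC,
        )
    ]
    all_tests = list(config.outcomes) + extra_tests

    _stage("adjust_for_demographics", timings)
    z_scores, z_meta = _adjusted_scores(cohort, all_tests)

    _stage("correlation_table", timings)
    correlations = bh.correlation_table(z_scores, all_tests)

    _stage("dichotomize", timings)
    flags = pd.DataFrame(index=z_scores.index)
    if norms is not None:
        for test in config.outcomes:
            if test in norms:
                flags[test] = bh.dichotomize_series(scored_frame[test], norms, test)

    _stage("lesion_prevalence", timings)
    prevalence = lesion_prevalence(cohort, display_threshold=config.display_threshold)
    mask = vlsm.build_test_mask(prevalence, cohort.n_subjects, min_count=config.min_count)
    if mask.is_empty:
        logger.warning("test mask is empty: no voxel lesioned in >= %d subjects", config.min_count)

    _stage("vlsm", timings)
    stat_maps: dict[str, vlsm.StatMap] = {}
    for outcome in config.outcomes:
        z = z_scores[outcome]
        if config.statistic_kind == "t":
            smap = vlsm.voxelwise_ttest(cohort, z, mask, tails=config.tails, outcome=outcome)
        else:
            smap = vlsm.voxelwise_brunner_munzel(
                cohort, z, mask, tails=config.tails, outcome=outcome
            )
        stat_maps[outcome] = vlsm.apply_fdr(smap, q=config.q)

    _stage("overlap_map", timings)
    overlap = None
    if len(config.outcomes) >= 2:
        a, b = config.outcomes[:2]
        overlap = vlsm.overlap_map(stat_maps[a], stat_maps[b], names=(a, b))

    _stage("subtraction", timings)
    overlays: dict[str, sub_mod.GroupOverlay] = {}
    subtractions: dict[str, sub_mod.SubtractionMap] = {}
    for outcome in flags.columns:
        try:
            ov = sub_mod.group_overlays(cohort, flags[outcome], outcome=outcome)
        except ValueError as exc:
            logger.warning("skipping subtraction for %s: %s", outcome, exc)
            continue
        overlays[outcome] = ov
        subtractions[outcome] = sub_mod.subtraction_map(ov)

    _stage("region_report", timings)
    region_report = None
    selection = None
    roi_models = pd.DataFrame()
    if cohort.atlas is not None:
        region_report = roi_mod.region_voxel_report(stat_maps, mask, cohort.atlas, cohort)
        selection = roi_mod.select_regions(region_report, min_sig=config.min_sig)

        _stage("roi_regression", timings)
        union = selection.union()
        if union:
            volumes = roi_mod.regional_volume_table(cohort, cohort.atlas, union)
            demo = cohort.behavior_frame()[["age", "sex", "education"]]
            modes = {"off": [False], "on": [True], "both": [False, True]}[
                config.adjust_total_volume
            ]
            fits = []
            for adjust in modes:
                for outcome in config.outcomes:
                    for label in union:
                        fits.append(
                            roi_mod.fit_roi_model(
                                z_scores[outcome],
                                demo,
                                volumes[f"region_{label}_ml"],
                                volumes["total_ml"] if adjust else None,
                                outcome=outcome,
                                region=cohort.atlas.region_table[label],
                            )
                        )
            roi_models = roi_mod.roi_model_table(fits)

    _stage("descriptives", timings)
    infra = None
    if cohort.atlas is not None:
        from .synthetic import INFRATENTORIAL

        infra_mask = cohort.atlas.labels == INFRATENTORIAL
        infra = infra_mask if infra_mask.any() else None
    descriptives = describe_cohort(
        cohort, flags, infratentorial_mask=infra, midline_band_mm=config.midline_band_mm
    )

    _stage("write_outputs", timings)
    manifest = {
        "config": config.as_dict(),
        "n_subjects": cohort.n_subjects,
        "grid": cohort.grid.summary(),
        "n_tested_voxels": mask.n_tested,
        "z_adjustment": z_meta,
        "norm_cutoffs": norms.as_dict() if norms is not None else None,
        "fdr": {
            outcome: {
                "q": config.q,
                "realized_cutoff": sm.fdr_threshold,
                "n_significant": sm.n_significant,
            }
            for outcome, sm in stat_maps.items()
        },
        "statistic_kind": config.statistic_kind,
        "tails": config.tails,
        "missing_per_test": cohort.missingness(),
        "excluded_subjects": cohort.excluded_subjects,
    }
    result = RunResult(
        config=config,
        out_dir=out,
        prevalence=prevalence,
        z_scores=z_scores,
        correlations=correlations,
        stat_maps=stat_maps,
        overlap=overlap,
        flags=flags,
        overlays=overlays,
        subtractions=subtractions,
        region_report=region_report,
        roi_selection=selection,
        roi_models=roi_models,
        descriptives=descriptives,
        manifest=manifest,
    )
    if out is not None:
        _write_outputs(result, cohort, mask)
    return result


def _write_outputs(result: RunResult, cohort: Cohort, mask: vlsm.TestMask) -> None:
    out = result.out_dir
    aff = cohort.grid.affine
    nib.save(
        nib.Nifti1Image(result.prevalence.counts.astype(np.int16), aff),
        str(out / "lesion_prevalence.nii.gz"),
    )
    nib.save(
        nib.Nifti1Image(result.prevalence.displayed().astype(np.int16), aff),
        str(out / "lesion_prevalence_displayed.nii.gz"),
    )
    nib.save(
        nib.Nifti1Image(mask.tested.astype(np.uint8), aff), str(out / "test_mask.nii.gz")
    )
    result.z_scores.to_csv(out / "z_scores.csv")
    result.correlations.to_csv(out / "correlation_table.csv", index=False)
    result.flags.to_csv(out / "impairment_flags.csv")
    for outcome, smap in result.stat_maps.items():
        vlsm.save_stat_map(smap, out / f"vlsm_{outcome}")
    if result.overlap is not None:
        nib.save(
            nib.Nifti1Image(result.overlap.category.astype(np.int8), aff),
            str(out / "overlap_map.nii.gz"),
        )
    for outcome in result.subtractions:
        sub_mod.save_subtraction(
            result.overlays[outcome], result.subtractions[outcome], out / f"subtraction_{outcome}"
        )
    if result.region_report is not None:
        result.region_report.table.to_csv(out / "region_report.csv", index=False)
    if not result.roi_models.empty:
        result.roi_models[~result.roi_models["adjusted_for_total_volume"]].to_csv(
            out / "roi_models.csv", index=False
        )
        adj = result.roi_models[result.roi_models["adjusted_for_total_volume"]]
        if not adj.empty:
            adj.to_csv(out / "roi_models_total_adjusted.csv", index=False)
    for name, table in result.descriptives.items():
        table.to_csv(out / f"descriptives_{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
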