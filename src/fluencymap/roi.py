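"""Atlas-based region-of-interest quantification and regression.

The voxel-wise map is projected onto an integer-labeled atlas to count
tested and significant voxels per region; regions with at least 100
significant voxels for an outcome are selected.  For each selected region
the per-subject lesion volume inside it (ml) enters a hierarchical linear
regression on the adjusted behavioral z score:

    base:  z ~ age + sex + education            (+ total lesion volume)
    full:  base + regional lesion volume

reporting R² of both models, the partial-F p value for ΔR² (identical to
the added coefficient's two-sided t test), and the unstandardized
coefficient B — change in z per 1 ml of regional infarct — with its 95 %
CI.  Adding total lesion volume to the base model asks whether the region
predicts performance beyond overall lesion burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import AtlasVolume, Cohort, GridMismatchError, LesionMap
from .vlsm import StatMap, TestMask

__all__ = [
    "RegionReport",
    "RoiSelection",
    "RoiModelFit",
    "region_voxel_report",
    "select_regions",
    "regional_lesion_volume",
    "regional_volume_table",
    "fit_roi_model",
]


@dataclass(frozen=True)
class RegionReport:
    """Per-region voxel tallies for one or more outcomes.

    ``table`` columns: region label and name, region_size_voxels,
    tested_voxels, patients_with_lesion (any overlap, all subjects),
    patients_with_lesion_analyzed (subjects entering the given outcome's
    voxel test), and per outcome ``sig_<outcome>`` with
    ``pct_<outcome>`` = 100·significant/tested (0 when tested = 0).
    """

    table: pd.DataFrame
    outcomes: tuple[str, ...]


@dataclass(frozen=True)
class RoiSelection:
    """Atlas regions crossing the significant-voxel threshold per outcome."""

    selected: dict[str, list[int]]
    min_sig: int

    def union(self) -> list[int]:
        out: list[int] = []
        for labels in self.selected.values():
            for lab in labels:
                if lab not in out:
                    out.append(lab)
        return sorted(out)


@dataclass(frozen=True)
class RoiModelFit:
    outcome: str
    region: str
    n_used: int
    r2_base: float
    r2_full: float
    p_delta: float
    B: float
    ci95: tuple[float, float]
    adjusted_for_total_volume: bool

    @property
    def delta_r2(self) -> float:
        return self.r2_full - self.r2_base


def region_voxel_report(
    sig_maps: dict[str, StatMap],
    mask: TestMask,
    atlas: AtlasVolume,
    cohort: Cohort | None = None,
) -> RegionReport:
    """Exact voxel-label overlap tallies per atlas region.

    For every region: size, tested-voxel count, significant-voxel count and
    percent-of-tested per outcome, plus (when a cohort is given) the number
    of patients whose lesion overlaps the region by at least one voxel —
    both over all subjects and over subjects contributing a score to each
    outcome.
    """
    if not mask.grid.matches(atlas.grid):
        raise GridMismatchError("atlas grid does not match analysis grid")
    for name, smap in sig_maps.items():
        if not smap.grid.matches(atlas.grid):
            raise GridMismatchError(f"significance map {name!r} grid does not match atlas")
    labels = atlas.labels
    nbins = int(labels.max()) + 1
    size = np.bincount(labels.ravel(), minlength=nbins)
    tested = np.bincount(labels.ravel(), weights=mask.tested.ravel(), minlength=nbins)
    rows = []
    sig_counts = {
        name: np.bincount(labels.ravel(), weights=smap.significant.ravel(), minlength=nbins)
        for name, smap in sig_maps.items()
    }
    overlap_all: dict[int, int] = {}
    if cohort is not None:
        region_masks = {lab: (labels == lab).ravel() for lab in atlas.region_labels}
        L = cohort.lesion_matrix().astype(bool)
        for lab, rmask in region_masks.items():
            overlap_all[lab] = int((L[:, rmask].any(axis=1)).sum())
    for lab in atlas.region_labels:
        row = {
            "label": lab,
            "region": atlas.region_table[lab],
            "region_size_voxels": int(size[lab]) if lab < nbins else 0,
            "tested_voxels": int(tested[lab]) if lab < nbins else 0,
        }
        if cohort is not None:
            row["patients_with_lesion"] = overlap_all.get(lab, 0)
        for name in sig_maps:
            nsig = int(sig_counts[name][lab]) if lab < nbins else 0
            row[f"sig_{name}"] = nsig
            row[f"pct_{name}"] = (
                100.0 * nsig / row["tested_voxels"] if row["tested_voxels"] > 0 else 0.0
            )
        rows.append(row)
    return RegionReport(table=pd.DataFrame(rows), outcomes=tuple(sig_maps))


def select_regions(report: RegionReport, min_sig: int = 100) -> RoiSelection:
    """Regions with at least ``min_sig`` significant voxels, per outcome."""
    selected = {}
    for outcome in report.outcomes:
        col = f"sig_{outcome}"
        sel = report.table.loc[report.table[col] >= min_sig, "label"]
        selected[outcome] = [int(v) for v in sel]
    return RoiSelection(selected=selected, min_sig=min_sig)


def regional_lesion_volume(lesion: LesionMap, atlas: AtlasVolume, region: int) -> float:
    """Lesion volume inside one atlas region, in ml (1000 mm³ = 1 ml)."""
    rmask = atlas.region_mask(region)  # raises on unknown label
    n = int((lesion.voxels.astype(bool) & rmask).sum())
    return n * lesion.grid.voxel_volume_mm3 / 1000.0


def regional_volume_table(cohort: Cohort, atlas: AtlasVolume, regions: list[int]) -> pd.DataFrame:
    """Per-subject lesion volumes (ml): one column per region + total."""
    rows = []
    for m in cohort.lesion_maps:
        row = {"subject_id": m.subject_id, "total_ml": m.volume_ml}
        for lab in regions:
            row[f"region_{lab}_ml"] = regional_lesion_volume(m, atlas, lab)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def fit_roi_model(
    z: pd.Series,
    demographics: pd.DataFrame,
    roi_volume_ml: pd.Series,
    total_volume_ml: pd.Series | None = None,
    outcome: str = "score",
    region: str = "region",
    min_subjects: int = 10,
) -> RoiModelFit:
    """Hierarchical OLS: does regional lesion volume add explained variance?

    Base model regresses z on age, sex and education (plus total lesion
    volume when ``total_volume_ml`` is given); the full model adds the
    regional volume.  ΔR² is tested with the partial F test, which for a
    single added regressor equals the coefficient's two-sided t test.
    Listwise deletion within the fit; raises below ``min_subjects``
    complete cases or on a rank-deficient design (e.g. regional volume
    collinear with total volume).
    """
    data = pd.DataFrame(
        {
            "z": z,
            "age": demographics["age"],
            "sex": demographics["sex"],
            "education": demographics["education"],
            "roi_ml": roi_volume_ml,
        }
    )
    adjusted = total_volume_ml is not None
    if adjusted:
        data["total_ml"] = total_volume_ml
    data = data.dropna()
    n = len(data)
    if n < min_subjects:
        raise ValueError(
            f"{outcome}/{region}: only {n} complete cases, need >= {min_subjects}"
        )
    base_cols = ["age", "sex", "education"] + (["total_ml"] if adjusted else [])
    X_base = sm.add_constant(data[base_cols], has_constant="add")
    if np.ptp(data["roi_ml"].to_numpy(float)) == 0.0:
        # constant regional volume adds nothing: full model == base model
        fit_base = sm.OLS(data["z"], X_base).fit()
        r2 = float(fit_base.rsquared)
        return RoiModelFit(
            outcome=outcome, region=region, n_used=n,
            r2_base=r2, r2_full=r2, p_delta=1.0, B=0.0, ci95=(0.0, 0.0),
            adjusted_for_total_volume=adjusted,
        )
    X_full = sm.add_constant(data[base_cols + ["roi_ml"]], has_constant="add")
    if np.linalg.matrix_rank(X_full.to_numpy()) < X_full.shape[1]:
        raise ValueError(
            f"{outcome}/{region}: design is rank deficient "
            f"(regional volume collinear with other covariates?)"
        )
    fit_base = sm.OLS(data["z"], X_base).fit()
    fit_full = sm.OLS(data["z"], X_full).fit()
    # partial F for the one added regressor == squared t of its coefficient
    f_stat, p_delta, _ = fit_full.compare_f_test(fit_base)
    ci = fit_full.conf_int(alpha=0.05).loc["roi_ml"].to_numpy()
    return RoiModelFit(
        outcome=outcome,
        region=region,
        n_used=n,
        r2_base=float(fit_base.rsquared),
        r2_full=float(fit_full.rsquared),
        p_delta=float(p_delta),
        B=float(fit_full.params["roi_ml"]),
        ci95=(float(ci[0]), float(ci[1])),
        adjusted_for_total_volume=adjusted,
    )


def roi_model_table(fits: list[RoiModelFit]) -> pd.DataFrame:
    """Tidy frame mirroring the regression-results table layout."""
    rows = []
    for f in fits:
        rows.append(
            {
                "outcome": f.outcome,
                "region": f.region,
                "n": f.n_used,
                "r2_base": f.r2_base,
                "r2_full": f.r2_full,
                "delta_r2": f.delta_r2,
                "p_delta_r2": f.p_delta,
                "B_per_ml": f.B,
                "ci95_low": f.ci95[0],
                "ci95_high": f.ci95[1],
                "adjusted_for_total_volume": f.adjusted_for_total_volume,
            }
        )
    return pd.DataFrame(rows)
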