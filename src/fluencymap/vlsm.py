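"""Voxel-based lesion-symptom mapping (VLSM).

At every voxel lesioned in enough patients, subjects with a lesion there
are compared with subjects without on a demographically adjusted behavioral
z score, using either the pooled-variance two-sample t test or the
non-parametric Brunner–Munzel statistic.  Statistics are signed so that a
*positive* value means the lesioned group performs worse; inference is
one-tailed in that lesion→deficit direction by default (a lesion making
performance better is not a discovery), with a two-tailed mode available.
Multiple testing over the tested voxels is controlled with the
Benjamini–Hochberg false-discovery-rate step-up at q.

Group membership differs voxel by voxel, so the t statistic is computed
from lesion-matrix inner products rather than per-voxel calls; the result
is contractually identical to a per-voxel loop (tested against scipy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, CountMap, GridGeometry, GridMismatchError

__all__ = [
    "TestMask",
    "StatMap",
    "OverlapMap",
    "build_test_mask",
    "voxelwise_ttest",
    "voxelwise_brunner_munzel",
    "fdr_threshold",
    "apply_fdr",
    "overlap_map",
    "brunner_munzel_stat",
    "save_stat_map",
]


@dataclass(frozen=True)
class TestMask:
    """Boolean mask of voxels entering the mass-univariate analysis."""

    grid: GridGeometry
    tested: np.ndarray
    min_count: int

    def __post_init__(self) -> None:
        t = np.asarray(self.tested, dtype=bool)
        if t.shape != self.grid.dims:
            raise ValueError(f"mask shape {t.shape} != grid dims {self.grid.dims}")
        t.setflags(write=False)
        object.__setattr__(self, "tested", t)

    @property
    def n_tested(self) -> int:
        return int(self.tested.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_tested == 0


@dataclass(frozen=True)
class StatMap:
    """Voxel-wise statistic/p/significance volumes plus bookkeeping.

    Untested voxels carry NaN in ``statistic``, ``p`` and ``df`` and False
    in ``significant``.  ``fdr_threshold`` is the realized p cutoff (0.0
    when nothing survives, NaN before FDR is applied).
    """

    grid: GridGeometry
    statistic: np.ndarray
    p: np.ndarray
    df: np.ndarray
    tested: np.ndarray
    significant: np.ndarray
    statistic_kind: str  # "t" | "brunner_munzel"
    tails: str  # "one" | "two"
    outcome: str = ""
    q: float = float("nan")
    fdr_threshold: float = float("nan")
    degenerate: np.ndarray | None = None  # zero-variance voxels forced to p=1
    n_lesioned: np.ndarray | None = None
    n_intact: np.ndarray | None = None

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def tested_p(self) -> np.ndarray:
        """p values over tested voxels, 1D."""
        return self.p[self.tested]


@dataclass(frozen=True)
class OverlapMap:
    """Per-voxel conjunction of two significance maps.

    Categories: 0 = neither, 1 = first only, 2 = second only, 3 = both.
    """

    grid: GridGeometry
    category: np.ndarray
    names: tuple[str, str]

    NONE, A_ONLY, B_ONLY, BOTH = 0, 1, 2, 3

    def counts(self) -> dict[str, int]:
        c = self.category
        return {
            "none": int((c == self.NONE).sum()),
            f"{self.names[0]}_only": int((c == self.A_ONLY).sum()),
            f"{self.names[1]}_only": int((c == self.B_ONLY).sum()),
            "both": int((c == self.BOTH).sum()),
        }


def build_test_mask(prevalence: CountMap, n_subjects: int, min_count: int = 3) -> TestMask:
    """Voxels lesioned in at least ``min_count`` patients, and intact in at
    least one, are tested; all others are excluded from analysis.

    The upper bound (at least one intact subject) removes voxels lesioned in
    everybody, where the two-sample contrast is undefined.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    counts = prevalence.counts
    tested = (counts >= min_count) & (counts <= n_subjects - 1)
    return TestMask(grid=prevalence.grid, tested=tested, min_count=min_count)


def _aligned_z(cohort: Cohort, z: pd.Series) -> np.ndarray:
    missing = [sid for sid in cohort.subject_ids if sid not in z.index]
    if missing:
        raise ValueError(f"z scores missing for subjects {missing[:5]}")
    return z.reindex(cohort.subject_ids).to_numpy(dtype=float)


def voxelwise_ttest(
    cohort: Cohort,
    z: pd.Series,
    mask: TestMask,
    tails: str = "one",
    outcome: str = "",
    equal_var: bool = True,
) -> StatMap:
    """Pooled-variance two-sample t test at every tested voxel.

    Parameters
    ----------
    z : Series indexed by subject_id
        Adjusted behavioral scores; NaN entries are excluded voxel-wise
        (not listwise), so each voxel uses every subject with a score.
    tails : {"one", "two"}
        "one" (default) tests only the lesion→worse direction.
    equal_var : bool
        Pooled (Student) variance by default, matching the classic VLSM
        implementation; Welch available by flag.

    The statistic is ``mean(z intact) − mean(z lesioned)`` over its standard
    error: positive when the lesioned group performs worse.  Voxels where a
    group has < 2 usable subjects or pooled variance is zero are flagged
    degenerate and carry statistic 0, p 1.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if mask.is_empty:
        raise ValueError("test mask is empty; nothing to analyze")
    cohort.grid.require_match(mask.grid, what="test mask")
    zv = _aligned_z(cohort, z)
    use = np.isfinite(zv)
    L = cohort.lesion_matrix()[:, mask.tested.ravel()].astype(float)
    Lu = L[use]
    zu = zv[use]

    n1 = Lu.sum(axis=0)  # lesioned, per voxel
    n_use = float(use.sum())
    n0 = n_use - n1  # intact
    s1 = zu @ Lu
    s0 = zu.sum() - s1
    ss1 = (zu**2) @ Lu
    ss0 = (zu**2).sum() - ss1

    ok = (n1 >= 2) & (n0 >= 2)
    n1s = np.where(n1 > 0, n1, 1.0)
    n0s = np.where(n0 > 0, n0, 1.0)
    mean1 = s1 / n1s
    mean0 = s0 / n0s
    ssd1 = np.maximum(ss1 - s1**2 / n1s, 0.0)
    ssd0 = np.maximum(ss0 - s0**2 / n0s, 0.0)

    if equal_var:
        df = n1 + n0 - 2.0
        pooled = (ssd1 + ssd0) / np.where(df > 0, df, 1.0)
        se = np.sqrt(pooled * (1.0 / n1s + 1.0 / n0s))
    else:
        v1 = ssd1 / np.where(n1 > 1, n1 - 1.0, 1.0)
        v0 = ssd0 / np.where(n0 > 1, n0 - 1.0, 1.0)
        se = np.sqrt(v1 / n1s + v0 / n0s)
        num = (v1 / n1s + v0 / n0s) ** 2
        den = (v1 / n1s) ** 2 / np.where(n1 > 1, n1 - 1.0, 1.0) + (v0 / n0s) ** 2 / np.where(
            n0 > 1, n0 - 1.0, 1.0
        )
        df = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    degenerate = ok & ~(se > 0)
    valid = ok & (se > 0)
    tstat = np.zeros_like(se)
    tstat[valid] = (mean0[valid] - mean1[valid]) / se[valid]
    pvals = np.ones_like(se)
    if tails == "one":
        pvals[valid] = stats.t.sf(tstat[valid], df[valid])
    else:
        pvals[valid] = 2.0 * stats.t.sf(np.abs(tstat[valid]), df[valid])
    # voxels with an unusable group: statistic 0, p 1, flagged
    degenerate = degenerate | ~ok
    tstat[~ok] = 0.0
    pvals[~ok] = 1.0
    df = np.where(ok, df, 0.0)

    return _pack_stat_map(
        mask, tstat, pvals, df, degenerate, n1, n0, "t", tails, outcome
    )


def brunner_munzel_stat(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Brunner–Munzel rank statistic for two independent samples.

    Returns ``(statistic, df, p_one_tailed)`` where the statistic is
    positive when ``y`` tends to exceed ``x`` (stochastic dominance of the
    second sample) and the p value uses the t approximation with
    Welch–Satterthwaite-type degrees of freedom.  Midranks handle ties.
    Degenerate inputs (zero rank variance in both groups) return
    statistic 0, p 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        return 0.0, 0.0, 1.0
    combined = np.concatenate([x, y])
    rankc = stats.rankdata(combined)
    rcx, rcy = rankc[:nx], rankc[nx:]
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    mx, my = rcx.mean(), rcy.mean()
    sx = np.sum((rcx - rx - mx + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy = np.sum((rcy - ry - my + (ny + 1) / 2.0) ** 2) / (ny - 1)
    denom = (nx + ny) * np.sqrt(nx * sx + ny * sy)
    if denom <= 0:
        return 0.0, 0.0, 1.0
    stat = nx * ny * (my - mx) / denom
    df_num = (nx * sx + ny * sy) ** 2
    df_den = (nx * sx) ** 2 / (nx - 1) + (ny * sy) ** 2 / (ny - 1)
    df = df_num / df_den if df_den > 0 else 0.0
    p = float(stats.t.sf(stat, df)) if df > 0 else 1.0
    return float(stat), float(df), p


def voxelwise_brunner_munzel(
    cohort: Cohort,
    z: pd.Series,
    mask: TestMask,
    tails: str = "one",
    outcome: str = "",
) -> StatMap:
    """Brunner–Munzel statistic at every tested voxel.

    Sign convention matches :func:`voxelwise_ttest` (positive = lesioned
    worse).  The t approximation is unreliable below ~10 subjects per
    group; small groups are computed anyway and the caveat recorded here.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if mask.is_empty:
        raise ValueError("test mask is empty; nothing to analyze")
    cohort.grid.require_match(mask.grid, what="test mask")
    zv = _aligned_z(cohort, z)
    use = np.isfinite(zv)
    L = cohort.lesion_matrix()[:, mask.tested.ravel()].astype(bool)
    Lu = L[use]
    zu = zv[use]

    m = Lu.shape[1]
    statv = np.zeros(m)
    pv = np.ones(m)
    dfv = np.zeros(m)
    degen = np.zeros(m, dtype=bool)
    n1 = Lu.sum(axis=0).astype(float)
    n0 = float(len(zu)) - n1
    for j in range(m):
        lesioned = Lu[:, j]
        x = zu[lesioned]  # lesioned group
        yv = zu[~lesioned]  # intact group
        if len(x) < 2 or len(yv) < 2:
            degen[j] = True
            continue
        s, df, p1 = brunner_munzel_stat(x, yv)
        if df == 0.0 and s == 0.0 and p1 == 1.0 and (np.ptp(zu) > 0):
            degen[j] = True
        statv[j], dfv[j] = s, df
        pv[j] = p1 if tails == "one" else min(1.0, 2.0 * min(p1, 1.0 - p1))
    return _pack_stat_map(
        mask, statv, pv, dfv, degen, n1, n0, "brunner_munzel", tails, outcome
    )


def _pack_stat_map(mask, statv, pvals, dfv, degen, n1, n0, kind, tails, outcome) -> StatMap:
    dims = mask.grid.dims
    flat = mask.tested.ravel()

    def full(vec, fill=np.nan, dtype=float):
        out = np.full(flat.shape, fill, dtype=dtype)
        out[flat] = vec
        return out.reshape(dims)

    return StatMap(
        grid=mask.grid,
        statistic=full(statv),
        p=full(pvals),
        df=full(dfv),
        tested=mask.tested,
        significant=np.zeros(dims, dtype=bool),
        statistic_kind=kind,
        tails=tails,
        outcome=outcome,
        degenerate=full(degen, fill=False, dtype=bool),
        n_lesioned=full(n1),
        n_intact=full(n0),
    )


def fdr_threshold(p_values: np.ndarray, q: float = 0.05) -> tuple[float, np.ndarray]:
    """Benjamini–Hochberg step-up over a collection of p values.

    Returns ``(realized_cutoff, significant)``: the largest p(k) with
    p(k) <= k*q/m is the realized cutoff and everything at or below it is
    significant; when no k qualifies the cutoff is 0.0 and nothing is
    significant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    k = np.arange(1, m + 1)
    passing = order <= k * q / m
    if not passing.any():
        return 0.0, np.zeros(m, dtype=bool)
    cutoff = float(order[np.nonzero(passing)[0].max()])
    return cutoff, p <= cutoff


def apply_fdr(stat_map: StatMap, q: float = 0.05) -> StatMap:
    """Threshold a StatMap's tested p values at FDR level q."""
    cutoff, sig_flat = fdr_threshold(stat_map.tested_p(), q=q)
    significant = np.zeros(stat_map.grid.dims, dtype=bool)
    significant[stat_map.tested] = sig_flat
    return replace(stat_map, significant=significant, q=float(q), fdr_threshold=cutoff)


def overlap_map(sig_a: StatMap, sig_b: StatMap, names: tuple[str, str] | None = None) -> OverlapMap:
    """Conjunction of two significance maps on the same grid."""
    if not sig_a.grid.matches(sig_b.grid):
        raise GridMismatchError("overlap requires both maps on the same grid")
    if names is None:
        names = (sig_a.outcome or "A", sig_b.outcome or "B")
    a = sig_a.significant
    b = sig_b.significant
    category = np.zeros(sig_a.grid.dims, dtype=np.int8)
    category[a & ~b] = OverlapMap.A_ONLY
    category[~a & b] = OverlapMap.B_ONLY
    category[a & b] = OverlapMap.BOTH
    return OverlapMap(grid=sig_a.grid, category=category, names=names)


def save_stat_map(stat_map: StatMap, stem: str | Path) -> dict[str, Path]:
    """Write statistic/p/significance NIfTI volumes plus a JSON sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    aff = stat_map.grid.affine
    paths = {}
    for name, arr, dtype in (
        ("statistic", stat_map.statistic, np.float32),
        ("p", stat_map.p, np.float32),
        ("significant", stat_map.significant.astype(np.uint8), np.uint8),
    ):
        p = stem.with_name(stem.name + f"_{name}.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), str(p))
        paths[name] = p
    sidecar = stem.with_name(stem.name + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "outcome": stat_map.outcome,
                "statistic_kind": stat_map.statistic_kind,
                "tails": stat_map.tails,
                "q": None if np.isnan(stat_map.q) else stat_map.q,
                "fdr_threshold": None
                if np.isnan(stat_map.fdr_threshold)
                else stat_map.fdr_threshold,
                "n_tested_voxels": int(stat_map.tested.sum()),
                "n_significant_voxels": stat_map.n_significant,
            },
            indent=1,
        )
    )
    paths["sidecar"] = sidecar
    return paths
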