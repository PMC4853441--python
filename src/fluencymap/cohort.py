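"""Core data containers and input/output for lesion cohorts.

A cohort couples per-subject binary lesion maps, all on one common template
grid, with a behavior table (fluency counts plus demographics) and,
optionally, an integer-labeled anatomical atlas.  Everything downstream —
voxel-based lesion-symptom mapping, subtraction maps, region-of-interest
regression — consumes these containers.

Conventions
-----------
* Voxel indices are 0-based; world (mm) coordinates come from the affine.
* All cross-volume operations require *identical* grids: no on-the-fly
  resampling is performed, registration is a pre-processing concern.
* Lesion volumes are binarized on load: any strictly positive voxel is 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GridGeometry",
    "LesionMap",
    "BehaviorRecord",
    "AtlasVolume",
    "CountMap",
    "Cohort",
    "GridMismatchError",
    "CohortError",
    "load_lesion_map",
    "save_lesion_map",
    "load_atlas",
    "save_atlas",
    "read_behavior_table",
    "behavior_records_from_frame",
    "assemble_cohort",
    "lesion_prevalence",
    "write_cohort_manifest",
]

#: Default absolute per-element tolerance when comparing affines (mm).
AFFINE_TOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when two volumes do not share the same grid geometry."""


class CohortError(ValueError):
    """Raised when a cohort cannot be assembled or validated."""


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and affine of a 3D template grid.

    Parameters
    ----------
    dims : tuple of int
        Voxel counts along each axis; all >= 1.
    voxel_size : tuple of float
        Voxel edge length in mm along each axis; all > 0.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-mm map; must be invertible.
    space_label : str
        Free-text label of the space, e.g. ``"MNI-152 1 mm"`` or ``"toy"``.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray
    space_label: str = "unspecified"

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(
            self, "voxel_size", tuple(float(v) for v in self.voxel_size)
        )
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three counts >= 1, got {self.dims}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @classmethod
    def from_image(cls, img: nib.spatialimages.SpatialImage, space_label: str = "unspecified") -> "GridGeometry":
        if len(img.shape) != 3:
            raise ValueError(f"expected a 3D volume, got shape {img.shape}")
        zooms = img.header.get_zooms()[:3]
        return cls(tuple(img.shape), tuple(float(z) for z in zooms), np.asarray(img.affine), space_label)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        homo = np.c_[idx, np.ones(len(idx))]
        return (homo @ self.affine.T)[:, :3]

    def matches(self, other: "GridGeometry", affine_tol: float = AFFINE_TOL) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.affine, other.affine, rtol=0.0, atol=affine_tol)
        )

    def require_match(self, other: "GridGeometry", what: str = "volume", affine_tol: float = AFFINE_TOL) -> None:
        if not self.matches(other, affine_tol=affine_tol):
            raise GridMismatchError(
                f"{what} grid (dims={other.dims}, affine=\n{np.asarray(other.affine)})\n"
                f"does not match expected grid (dims={self.dims}, affine=\n{self.affine}) "
                f"within tolerance {affine_tol}"
            )

    def summary(self) -> dict:
        return {
            "dims": list(self.dims),
            "voxel_size_mm": list(self.voxel_size),
            "space_label": self.space_label,
        }


@dataclass(frozen=True)
class LesionMap:
    """One subject's binary lesion mask on the cohort grid."""

    subject_id: str
    grid: GridGeometry
    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.shape != self.grid.dims:
            raise ValueError(
                f"lesion array shape {vox.shape} != grid dims {self.grid.dims}"
            )
        uniq = np.unique(vox)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"lesion map must be binary, found values {uniq[:10]}")
        vox = vox.astype(np.uint8)
        vox.setflags(write=False)
        object.__setattr__(self, "voxels", vox)

    @property
    def volume_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_ml(self) -> float:
        # 1000 mm^3 = 1 ml
        return self.volume_voxels * self.grid.voxel_volume_mm3 / 1000.0


@dataclass
class BehaviorRecord:
    """Demographics and raw test scores for one subject.

    ``raw_scores`` maps test name to value; a missing test is either absent
    from the mapping or stored as NaN.  Education follows the 7-category
    Dutch (Verhage) scale, 1 = unfinished primary school, 7 = academic degree.
    """

    subject_id: str
    age: float
    sex: int
    education: int
    raw_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.education = int(self.education)
        self.sex = int(self.sex)
        if self.education not in range(1, 8):
            raise ValueError(
                f"subject {self.subject_id}: education must be 1..7, got {self.education}"
            )
        if self.sex not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: sex must be coded 0/1")
        for test, value in self.raw_scores.items():
            if value is None:
                self.raw_scores[test] = float("nan")

    def score(self, test: str) -> float:
        """Value for ``test``; NaN when missing."""
        value = self.raw_scores.get(test, float("nan"))
        return float("nan") if value is None else float(value)

    def has(self, test: str) -> bool:
        return np.isfinite(self.score(test))


@dataclass(frozen=True)
class AtlasVolume:
    """Integer-labeled parcellation on the cohort grid (0 = unlabeled)."""

    grid: GridGeometry
    labels: np.ndarray
    region_table: dict[int, str]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.shape != self.grid.dims:
            raise ValueError(f"atlas shape {lab.shape} != grid dims {self.grid.dims}")
        lab = lab.astype(np.int32)
        present = set(np.unique(lab).tolist()) - {0}
        missing = present - set(self.region_table)
        if missing:
            raise ValueError(f"atlas labels without region names: {sorted(missing)}")
        lab.setflags(write=False)
        object.__setattr__(self, "labels", lab)

    @property
    def region_labels(self) -> list[int]:
        return sorted(self.region_table)

    def region_mask(self, label: int) -> np.ndarray:
        if label not in self.region_table:
            raise KeyError(f"unknown atlas region label {label}")
        return self.labels == label


@dataclass(frozen=True)
class CountMap:
    """Per-voxel non-negative counts (e.g. lesion prevalence)."""

    grid: GridGeometry
    counts: np.ndarray
    display_threshold: int = 3

    def __post_init__(self) -> None:
        cnt = np.asarray(self.counts)
        if cnt.shape != self.grid.dims:
            raise ValueError(f"count array shape {cnt.shape} != grid dims {self.grid.dims}")
        if (cnt < 0).any():
            raise ValueError("counts must be non-negative")
        cnt = cnt.astype(np.int32)
        cnt.setflags(write=False)
        object.__setattr__(self, "counts", cnt)

    def displayed(self) -> np.ndarray:
        """Counts with voxels below the display threshold zeroed (figure analogue)."""
        out = self.counts.copy()
        out[out < self.display_threshold] = 0
        return out


@dataclass
class Cohort:
    """Aligned lesion maps, behavior records and optional atlas/ground truth."""

    grid: GridGeometry
    lesion_maps: list[LesionMap]
    behavior: list[BehaviorRecord]
    atlas: AtlasVolume | None = None
    ground_truth: object | None = None  # SyntheticTruth when simulated; never read by analyses
    excluded_subjects: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        map_ids = [m.subject_id for m in self.lesion_maps]
        beh_ids = [b.subject_id for b in self.behavior]
        if len(set(map_ids)) != len(map_ids):
            raise CohortError("duplicate subject_id among lesion maps")
        if len(set(beh_ids)) != len(beh_ids):
            raise CohortError("duplicate subject_id among behavior records")
        if set(map_ids) != set(beh_ids):
            raise CohortError(
                "lesion map and behavior subject sets differ: "
                f"maps-only={sorted(set(map_ids) - set(beh_ids))}, "
                f"behavior-only={sorted(set(beh_ids) - set(map_ids))}"
            )
        if len(map_ids) < 2:
            raise CohortError(f"a cohort needs >= 2 subjects, got {len(map_ids)}")
        for m in self.lesion_maps:
            self.grid.require_match(m.grid, what=f"lesion map {m.subject_id}")
        if self.atlas is not None:
            self.grid.require_match(self.atlas.grid, what="atlas")
        # keep behavior aligned with map order
        order = {sid: i for i, sid in enumerate(map_ids)}
        self.behavior = sorted(self.behavior, key=lambda b: order[b.subject_id])

    @property
    def n_subjects(self) -> int:
        return len(self.lesion_maps)

    @property
    def subject_ids(self) -> list[str]:
        return [m.subject_id for m in self.lesion_maps]

    def lesion_matrix(self) -> np.ndarray:
        """Subjects x voxels binary matrix (C-order flattened)."""
        return np.stack([m.voxels.ravel() for m in self.lesion_maps]).astype(np.uint8)

    def behavior_frame(self) -> pd.DataFrame:
        """Tidy per-subject frame: demographics plus one column per test."""
        tests: list[str] = []
        for rec in self.behavior:
            for t in rec.raw_scores:
                if t not in tests:
                    tests.append(t)
        rows = []
        for rec in self.behavior:
            row = {
                "subject_id": rec.subject_id,
                "age": rec.age,
                "sex": rec.sex,
                "education": rec.education,
            }
            for t in tests:
                row[t] = rec.score(t)
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject_id")

    def missingness(self) -> dict[str, int]:
        """Number of subjects missing each test."""
        frame = self.behavior_frame()
        tests = [c for c in frame.columns if c not in ("age", "sex", "education")]
        return {t: int(frame[t].isna().sum()) for t in tests}


# ---------------------------------------------------------------------------
# I/O


def load_lesion_map(
    path: str | Path,
    expected_grid: GridGeometry | None = None,
    subject_id: str | None = None,
    affine_tol: float = AFFINE_TOL,
) -> LesionMap:
    """Read a binary lesion mask from a NIfTI file.

    Any strictly positive voxel value is coerced to 1 (nominally binary
    segmentations can acquire fractional values through interpolation).
    When ``expected_grid`` is given, the file's grid must match it within
    ``affine_tol`` per affine element.
    """
    path = Path(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {img.shape}")
    grid = GridGeometry.from_image(
        img, space_label=expected_grid.space_label if expected_grid else "unspecified"
    )
    if expected_grid is not None:
        expected_grid.require_match(grid, what=str(path), affine_tol=affine_tol)
        grid = expected_grid
    data = np.asanyarray(img.dataobj)
    voxels = (np.nan_to_num(data, nan=0.0) > 0).astype(np.uint8)
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return LesionMap(subject_id=sid, grid=grid, voxels=voxels)


def save_lesion_map(lesion: LesionMap, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(lesion.voxels.astype(np.uint8), lesion.grid.affine)
    nib.save(img, str(path))
    return path


def load_atlas(
    volume_path: str | Path,
    region_table: Mapping[int, str] | str | Path,
    expected_grid: GridGeometry | None = None,
    affine_tol: float = AFFINE_TOL,
) -> AtlasVolume:
    """Read an integer-labeled atlas and its label -> region-name table.

    ``region_table`` is either a mapping or a path to a JSON / two-column
    CSV (``label,region``) file.
    """
    img = nib.load(str(volume_path))
    grid = GridGeometry.from_image(
        img, space_label=expected_grid.space_label if expected_grid else "unspecified"
    )
    if expected_grid is not None:
        expected_grid.require_match(grid, what=str(volume_path), affine_tol=affine_tol)
        grid = expected_grid
    labels = np.rint(np.asanyarray(img.dataobj)).astype(np.int32)
    if not isinstance(region_table, Mapping):
        p = Path(region_table)
        if p.suffix.lower() == ".json":
            raw = json.loads(p.read_text())
            table = {int(k): str(v) for k, v in raw.items()}
        else:
            frame = pd.read_csv(p)
            table = {int(r.iloc[0]): str(r.iloc[1]) for _, r in frame.iterrows()}
    else:
        table = {int(k): str(v) for k, v in region_table.items()}
    return AtlasVolume(grid=grid, labels=labels, region_table=table)


def save_atlas(atlas: AtlasVolume, volume_path: str | Path, table_path: str | Path | None = None) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.grid.affine), str(volume_path))
    if table_path is not None:
        Path(table_path).write_text(
            json.dumps({str(k): v for k, v in atlas.region_table.items()}, indent=1)
        )


_DEMOGRAPHIC_COLUMNS = ("subject_id", "age", "sex", "education")


def read_behavior_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[BehaviorRecord]:
    """Read a CSV/TSV behavior table into records.

    The table needs columns ``subject_id, age, sex, education``; every other
    column is treated as a test score.  ``column_map`` renames file columns
    to canonical names first (e.g. ``{"id": "subject_id"}``).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in _DEMOGRAPHIC_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: behavior table lacks required columns {missing}")
    return behavior_records_from_frame(frame)


def behavior_records_from_frame(frame: pd.DataFrame) -> list[BehaviorRecord]:
    test_columns = [c for c in frame.columns if c not in _DEMOGRAPHIC_COLUMNS]
    records = []
    for _, row in frame.iterrows():
        scores = {t: float(row[t]) if pd.notna(row[t]) else float("nan") for t in test_columns}
        records.append(
            BehaviorRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                sex=int(row["sex"]),
                education=int(row["education"]),
                raw_scores=scores,
            )
        )
    return records


def assemble_cohort(
    lesion_maps: Sequence[LesionMap],
    behavior: Sequence[BehaviorRecord] | pd.DataFrame,
    atlas: AtlasVolume | None = None,
    ground_truth: object | None = None,
) -> Cohort:
    """Match lesion maps and behavior records by subject id.

    Subjects present on only one side are excluded and listed in
    ``Cohort.excluded_subjects`` (id -> reason).  Raises if no subject has
    both a map and a record, or on duplicate ids.
    """
    if isinstance(behavior, pd.DataFrame):
        behavior = behavior_records_from_frame(behavior.reset_index())
    map_ids = [m.subject_id for m in lesion_maps]
    beh_ids = [b.subject_id for b in behavior]
    if len(set(map_ids)) != len(map_ids):
        dupes = sorted({i for i in map_ids if map_ids.count(i) > 1})
        raise CohortError(f"duplicate subject_id among lesion maps: {dupes}")
    if len(set(beh_ids)) != len(beh_ids):
        dupes = sorted({i for i in beh_ids if beh_ids.count(i) > 1})
        raise CohortError(f"duplicate subject_id among behavior records: {dupes}")
    matched = set(map_ids) & set(beh_ids)
    if not matched:
        raise CohortError("no subject has both a lesion map and a behavior record")
    excluded = {sid: "no behavior record" for sid in set(map_ids) - matched}
    excluded.update({sid: "no lesion map" for sid in set(beh_ids) - matched})
    maps = [m for m in lesion_maps if m.subject_id in matched]
    recs = [b for b in behavior if b.subject_id in matched]
    grid = maps[0].grid
    return Cohort(
        grid=grid,
        lesion_maps=maps,
        behavior=recs,
        atlas=atlas,
        ground_truth=ground_truth,
        excluded_subjects=excluded,
    )


def lesion_prevalence(cohort: Cohort, display_threshold: int = 3) -> CountMap:
    """Per-voxel count of subjects with a lesion there.

    ``display_threshold`` only affects :meth:`CountMap.displayed` (the
    prevalence-figure analogue, which projects voxels damaged in at least
    that many patients); all counts are retained exactly.
    """
    counts = np.zeros(cohort.grid.dims, dtype=np.int32)
    for m in cohort.lesion_maps:
        counts += m.voxels
    return CountMap(grid=cohort.grid, counts=counts, display_threshold=display_threshold)


def write_cohort_manifest(cohort: Cohort, path: str | Path, lesion_paths: Mapping[str, str] | None = None) -> Path:
    """JSON manifest: subjects, optional file paths, grid summary, missingness."""
    manifest = {
        "n_subjects": cohort.n_subjects,
        "subjects": cohort.subject_ids,
        "grid": cohort.grid.summary(),
        "excluded_subjects": cohort.excluded_subjects,
        "missing_per_test": cohort.missingness(),
    }
    if lesion_paths is not None:
        manifest["lesion_paths"] = dict(lesion_paths)
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=1))
    return path
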