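"""Synthetic lesion-cohort generator with ground truth.

No patient lesion or behavior data are redistributable, so every pipeline
stage is exercised on simulated cohorts built to mimic the structure of an
ischemic-stroke lesion-mapping study: a toy brain template with a labeled
atlas standing in for the MNI-152 template and the AAL parcellation;
spatially contiguous unilateral lesions grown by stochastic region growing,
with right-hemisphere predominance and an infratentorial compartment;
fluency and auxiliary test scores generated on the raw-count scale from
per-voxel ground-truth weight maps (raw-score loss per ml of overlapping
lesion) plus additive age/sex/education effects and Gaussian noise; and
per-test missingness.

The ground truth travels with the cohort but is never read by any analysis
stage — it exists so tests can score sensitivity, specificity and
coefficient recovery.

Scale conventions of the toy space: 32³ grid of 1 mm³ voxels, atlas
regions of a few thousand voxels (a few ml), lesions of 40–600 voxels
(0.04–0.6 ml).  Ground-truth weights are therefore quoted per ml on this
toy scale and are larger in magnitude than plausible per-ml effects on a
real 1 mm MNI grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import (
    PHONEMIC,
    SEMANTIC,
    TRIAL_ANIMALS,
    TRIAL_LETTER_A,
    TRIAL_LETTER_N,
    NormTable,
)
from .cohort import (
    AtlasVolume,
    BehaviorRecord,
    Cohort,
    GridGeometry,
    LesionMap,
    assemble_cohort,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "ToySpace",
    "make_toy_space",
    "simulate_lesions",
    "simulate_demographics",
    "simulate_behavior",
    "make_cohort",
    "default_norms",
]

# Atlas labels of the toy parcellation.
LEFT_MIDDLE_FRONTAL = 1
LEFT_INFERIOR_FRONTAL = 2
LEFT_TEMPORAL = 3
LEFT_PARIETAL = 4
RIGHT_FRONTAL = 5
RIGHT_TEMPORAL = 6
RIGHT_PARIETAL = 7
INFRATENTORIAL = 8

REGION_NAMES = {
    LEFT_MIDDLE_FRONTAL: "left_middle_frontal",
    LEFT_INFERIOR_FRONTAL: "left_inferior_frontal",
    LEFT_TEMPORAL: "left_temporal",
    LEFT_PARIETAL: "left_parietal",
    RIGHT_FRONTAL: "right_frontal",
    RIGHT_TEMPORAL: "right_temporal",
    RIGHT_PARIETAL: "right_parietal",
    INFRATENTORIAL: "infratentorial",
}
_NAME_TO_LABEL = {v: k for k, v in REGION_NAMES.items()}


@dataclass
class ExtraTest:
    """Auxiliary test generated from the fluency deficits (for correlation
    tables): score = baseline − c_semantic·semantic_loss − c_phonemic·
    phonemic_loss + demographic effects + noise."""

    baseline: float
    c_semantic: float
    c_phonemic: float
    noise_sd: float
    n_missing: int


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated cohort.

    Defaults mirror the emulated study where it states a value (n = 93;
    fluency means ~23.1 animals / 7.7 + 8.0 letter words; lesion location
    frequencies ~34 left / 40 right / 12 infratentorial of 93; per-test
    missingness 4/8/2/8 for the four auxiliary tests) and otherwise fix
    one field-realistic choice, documented in the methods note.
    """

    dims: tuple[int, int, int] = (32, 32, 32)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_subjects: int = 93

    # lesion model
    lesion_volume_range: tuple[int, int] = (60, 900)
    location_probs: dict[str, float] = field(
        default_factory=lambda: {"left": 0.40, "right": 0.47, "infratentorial": 0.13}
    )
    #: seed points concentrate around a per-hemisphere territory core
    #: (middle-cerebral-artery analogue); sd in voxels, None = uniform seeds
    territory_sigma: float | None = 5.0

    # ground-truth lesion weights: outcome -> {region name -> raw-score loss per ml}
    truth_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            SEMANTIC: {"left_temporal": 80.0, "left_inferior_frontal": 50.0},
            PHONEMIC: {"left_middle_frontal": 60.0, "left_inferior_frontal": 30.0},
        }
    )

    # raw-score generative model
    baselines: dict[str, float] = field(
        default_factory=lambda: {
            TRIAL_ANIMALS: 23.1,
            TRIAL_LETTER_N: 7.7,
            TRIAL_LETTER_A: 8.0,
        }
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            TRIAL_ANIMALS: 7.0,
            TRIAL_LETTER_N: 3.0,
            TRIAL_LETTER_A: 3.0,
        }
    )
    # additive demographic effects on the raw-count scale, centred at
    # age 60 / education category 5 so baselines stay interpretable
    demographic_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            TRIAL_ANIMALS: {"age": -0.10, "sex": 1.0, "education": 1.2},
            TRIAL_LETTER_N: {"age": -0.04, "sex": 0.3, "education": 0.6},
            TRIAL_LETTER_A: {"age": -0.04, "sex": 0.3, "education": 0.6},
        }
    )

    extra_tests: dict[str, ExtraTest] = field(
        default_factory=lambda: {
            "ravlt_total": ExtraTest(40.0, 0.8, 0.5, 8.0, 4),
            "rocf_delayed": ExtraTest(18.0, 0.3, 0.05, 5.0, 8),
            "boston_naming": ExtraTest(25.0, 0.5, 0.3, 3.0, 2),
            "token_test": ExtraTest(19.0, 0.4, 0.4, 2.0, 8),
        }
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        for t, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise sd for {t} must be >= 0")
        for outcome, weights in self.truth_weights.items():
            for region, w in weights.items():
                if not np.isfinite(w):
                    raise ValueError(f"weight {outcome}/{region} must be finite")
        total = sum(self.location_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"location probabilities must sum to 1, got {total}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative ground truth stored alongside a simulated cohort."""

    weight_volumes: dict[str, np.ndarray]  # outcome -> per-voxel loss per ml
    causal_regions: dict[str, list[str]]
    coefficients: dict[str, dict[str, float]]  # per trial: demographic betas used

    def causal_mask(self, outcome: str) -> np.ndarray:
        return self.weight_volumes[outcome] != 0


@dataclass(frozen=True)
class ToySpace:
    grid: GridGeometry
    brain_mask: np.ndarray
    atlas: AtlasVolume

    @property
    def infratentorial_mask(self) -> np.ndarray:
        return self.atlas.labels == INFRATENTORIAL


def make_toy_space(config: SyntheticConfig | None = None) -> ToySpace:
    """Deterministic toy template and atlas.

    An ellipsoidal supratentorial "brain" plus a small inferior-posterior
    infratentorial blob, carved into eight labeled regions (left/right ×
    frontal/temporal/parietal analogues, a dorsal left middle-frontal
    analogue and the infratentorial compartment).  The affine centres the
    grid so world x < 0 is the left hemisphere.
    """
    config = config or SyntheticConfig()
    dims = tuple(int(d) for d in config.dims)
    if any(d < 8 for d in dims):
        raise ValueError(f"toy space needs dims >= 8 per axis, got {dims}")
    vx, vy, vz = config.voxel_size
    affine = np.array(
        [
            [vx, 0, 0, -vx * (dims[0] - 1) / 2.0],
            [0, vy, 0, -vy * (dims[1] - 1) / 2.0],
            [0, 0, vz, -vz * (dims[2] - 1) / 2.0],
            [0, 0, 0, 1.0],
        ]
    )
    grid = GridGeometry(dims=dims, voxel_size=(vx, vy, vz), affine=affine, space_label="toy")
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    # world coordinates, scaled to a 32-voxel reference so geometry holds for any dims
    x = (ii - (dims[0] - 1) / 2.0) / dims[0] * 32.0
    y = (jj - (dims[1] - 1) / 2.0) / dims[1] * 32.0
    z = (kk - (dims[2] - 1) / 2.0) / dims[2] * 32.0

    supra = (x / 13.0) ** 2 + (y / 14.0) ** 2 + ((z - 2.0) / 10.0) ** 2 <= 1.0
    infra = (x / 6.0) ** 2 + ((y + 7.0) / 5.0) ** 2 + ((z + 10.0) / 4.5) ** 2 <= 1.0
    mask = supra | infra

    labels = np.zeros(dims, dtype=np.int32)
    left, right = x < 0, x > 0
    frontal = y >= 3
    temporal = (y < 3) & (z < -2)
    parietal = (y < 3) & (z >= -2)
    labels[supra & left & frontal & (z >= 3)] = LEFT_MIDDLE_FRONTAL
    labels[supra & left & frontal & (z < 3)] = LEFT_INFERIOR_FRONTAL
    labels[supra & left & temporal] = LEFT_TEMPORAL
    labels[supra & left & parietal] = LEFT_PARIETAL
    labels[supra & right & frontal] = RIGHT_FRONTAL
    labels[supra & right & temporal] = RIGHT_TEMPORAL
    labels[supra & right & parietal] = RIGHT_PARIETAL
    labels[infra & ~supra] = INFRATENTORIAL

    atlas = AtlasVolume(grid=grid, labels=labels, region_table=dict(REGION_NAMES))
    return ToySpace(grid=grid, brain_mask=mask, atlas=atlas)


def _neighbor_table(dims: tuple[int, int, int]) -> np.ndarray:
    """(n_voxels, 6) flat-index 6-neighbors, −1 outside the grid."""
    nx, ny, nz = dims
    idx = np.arange(nx * ny * nz).reshape(dims)
    out = np.full((nx * ny * nz, 6), -1, dtype=np.int64)
    out[idx[1:].ravel(), 0] = idx[:-1].ravel()
    out[idx[:-1].ravel(), 1] = idx[1:].ravel()
    out[idx[:, 1:].ravel(), 2] = idx[:, :-1].ravel()
    out[idx[:, :-1].ravel(), 3] = idx[:, 1:].ravel()
    out[idx[:, :, 1:].ravel(), 4] = idx[:, :, :-1].ravel()
    out[idx[:, :, :-1].ravel(), 5] = idx[:, :, 1:].ravel()
    return out


def _grow_lesion(
    compartment_flat: np.ndarray,
    neighbors: np.ndarray,
    target: int,
    rng: np.random.Generator,
    seed_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Stochastic region growing: add a random frontier voxel until target.

    Produces a single 6-connected component confined to the compartment;
    irregular, territory-like shapes rather than spheres.  ``seed_weights``
    biases where lesions start (vascular-territory analogue); growth itself
    is unweighted.
    """
    candidates = np.flatnonzero(compartment_flat)
    if seed_weights is not None:
        w = seed_weights[candidates]
        seed = int(rng.choice(candidates, p=w / w.sum()))
    else:
        seed = int(candidates[rng.integers(len(candidates))])
    in_lesion = np.zeros(compartment_flat.shape, dtype=bool)
    in_lesion[seed] = True
    frontier = [n for n in neighbors[seed] if n >= 0]
    volume = 1
    while volume < target and frontier:
        j = int(rng.integers(len(frontier)))
        cand = frontier[j]
        frontier[j] = frontier[-1]
        frontier.pop()
        if cand < 0 or in_lesion[cand] or not compartment_flat[cand]:
            continue
        in_lesion[cand] = True
        volume += 1
        frontier.extend(neighbors[cand])
    if volume < target:
        raise ValueError(
            f"compartment exhausted at {volume} voxels before reaching target {target}"
        )
    return in_lesion


def simulate_lesions(
    space: ToySpace,
    config: SyntheticConfig,
    rng: np.random.Generator | int,
) -> list[LesionMap]:
    """Grow one contiguous lesion per subject.

    Location (left / right hemisphere or infratentorial) is drawn per the
    configured prevalences; the lesion is confined to that compartment and
    its voxel volume drawn uniformly from ``lesion_volume_range``.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    lo, hi = config.lesion_volume_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid lesion volume range {config.lesion_volume_range}")
    dims = space.grid.dims
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    x = (ii - (dims[0] - 1) / 2.0) / dims[0] * 32.0
    y = (jj - (dims[1] - 1) / 2.0) / dims[1] * 32.0
    z = (kk - (dims[2] - 1) / 2.0) / dims[2] * 32.0
    infra = space.infratentorial_mask
    compartments = {
        "left": (space.brain_mask & (x < 0) & ~infra).ravel(),
        "right": (space.brain_mask & (x > 0) & ~infra).ravel(),
        "infratentorial": infra.ravel(),
    }
    # middle-cerebral-artery-like territory cores bias seed placement so
    # prevalence concentrates mid-hemisphere, as in real stroke cohorts
    seed_weights: dict[str, np.ndarray | None] = {"infratentorial": None}
    if config.territory_sigma is not None:
        s2 = 2.0 * config.territory_sigma**2
        for name, cx in (("left", -6.5), ("right", 6.5)):
            d2 = (x - cx) ** 2 + (y - 3.0) ** 2 + (z - 2.0) ** 2
            seed_weights[name] = np.exp(-d2 / s2).ravel()
    else:
        seed_weights.update({"left": None, "right": None})
    for name, comp in compartments.items():
        if comp.sum() < lo:
            raise ValueError(
                f"compartment {name!r} ({int(comp.sum())} voxels) cannot hold the "
                f"minimum lesion volume {lo}"
            )
    names = sorted(config.location_probs)
    probs = np.array([config.location_probs[n] for n in names])
    neighbors = _neighbor_table(space.grid.dims)
    maps = []
    for i in range(config.n_subjects):
        loc = names[int(rng.choice(len(names), p=probs))]
        comp = compartments[loc]
        target = int(rng.integers(lo, hi + 1))
        target = min(target, int(comp.sum()))
        voxels = _grow_lesion(comp, neighbors, target, rng, seed_weights[loc]).reshape(
            space.grid.dims
        )
        maps.append(
            LesionMap(subject_id=f"sub-{i + 1:03d}", grid=space.grid, voxels=voxels.astype(np.uint8))
        )
    return maps


def simulate_demographics(n: int, rng: np.random.Generator | int) -> pd.DataFrame:
    """Age ~ N(59.5, 14.9) clipped to [18, 90]; 57 % male; education 2–7
    with median 5 on the 7-category Dutch scale."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    age = np.clip(rng.normal(59.5, 14.9, size=n), 18.0, 90.0).round(1)
    sex = (rng.random(n) < 0.57).astype(int)
    edu = rng.choice(
        np.arange(1, 8), size=n, p=[0.0, 0.05, 0.15, 0.20, 0.35, 0.15, 0.10]
    )
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education": edu,
        }
    ).set_index("subject_id")


def build_truth(space: ToySpace, config: SyntheticConfig) -> SyntheticTruth:
    """Per-voxel weight volumes from the configured region weights."""
    weight_volumes = {}
    causal = {}
    for outcome, weights in config.truth_weights.items():
        vol = np.zeros(space.grid.dims, dtype=float)
        for region_name, w in weights.items():
            label = _NAME_TO_LABEL[region_name]
            vol[space.atlas.labels == label] = w
        weight_volumes[outcome] = vol
        causal[outcome] = sorted(weights)
    return SyntheticTruth(
        weight_volumes=weight_volumes,
        causal_regions=causal,
        coefficients={t: dict(b) for t, b in config.demographic_effects.items()},
    )


def simulate_behavior(
    lesions: list[LesionMap],
    truth: SyntheticTruth,
    demographics: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Raw test scores from lesion load, demographics and noise.

    Per subject and trial::

        raw = baseline − lesion loss + β_age·(age−60) + β_sex·sex
              + β_edu·(education−5) + Normal(0, sd)

    where the lesion loss is the inner product of the ground-truth weight
    volume (loss per ml) with the subject's lesioned-voxel volume in ml.
    The phonemic loss is split evenly between the two letter trials.
    Counts are rounded and clipped at 0.  Auxiliary tests are generated
    from the two fluency losses plus noise, then per-test missingness is
    applied as an exact number of randomly blanked subjects.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n = len(lesions)
    voxel_ml = lesions[0].grid.voxel_volume_mm3 / 1000.0
    L = np.stack([m.voxels.ravel() for m in lesions]).astype(float)
    losses = {
        outcome: L @ truth.weight_volumes[outcome].ravel() * voxel_ml
        for outcome in truth.weight_volumes
    }
    ids = [m.subject_id for m in lesions]
    demo = demographics.loc[ids]
    age_c = demo["age"].to_numpy(float) - 60.0
    sex = demo["sex"].to_numpy(float)
    edu_c = demo["education"].to_numpy(float) - 5.0

    trial_loss = {
        TRIAL_ANIMALS: losses.get(SEMANTIC, np.zeros(n)),
        TRIAL_LETTER_N: losses.get(PHONEMIC, np.zeros(n)) / 2.0,
        TRIAL_LETTER_A: losses.get(PHONEMIC, np.zeros(n)) / 2.0,
    }
    table = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
    table["age"] = demo["age"]
    table["sex"] = demo["sex"]
    table["education"] = demo["education"]
    for trial in (TRIAL_ANIMALS, TRIAL_LETTER_N, TRIAL_LETTER_A):
        eff = config.demographic_effects[trial]
        raw = (
            config.baselines[trial]
            - trial_loss[trial]
            + eff["age"] * age_c
            + eff["sex"] * sex
            + eff["education"] * edu_c
            + rng.normal(0.0, config.noise_sd[trial], size=n)
        )
        table[trial] = np.clip(np.rint(raw), 0, None)
    for name, spec in config.extra_tests.items():
        raw = (
            spec.baseline
            - spec.c_semantic * losses.get(SEMANTIC, np.zeros(n))
            - spec.c_phonemic * losses.get(PHONEMIC, np.zeros(n))
            + rng.normal(0.0, spec.noise_sd, size=n)
        )
        col = np.clip(np.rint(raw), 0, None)
        if spec.n_missing > 0:
            blank = rng.choice(n, size=min(spec.n_missing, n), replace=False)
            col = col.astype(float)
            col[blank] = np.nan
        table[name] = col
    return table


def make_cohort(
    config: SyntheticConfig | None = None,
    seed: int | np.random.Generator = 0,
    space: ToySpace | None = None,
) -> Cohort:
    """One-call generator: toy space, lesions, demographics, behavior.

    Fully deterministic under a fixed seed.  The returned cohort carries
    the atlas and the :class:`SyntheticTruth` block; analyses never read
    the truth.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    if space is None:
        space = make_toy_space(config)
    truth = build_truth(space, config)
    lesions = simulate_lesions(space, config, rng)
    demographics = simulate_demographics(config.n_subjects, rng)
    behavior = simulate_behavior(lesions, truth, demographics, config, rng)
    cohort = assemble_cohort(
        lesions, behavior, atlas=space.atlas, ground_truth=truth
    )
    return cohort


def default_norms() -> NormTable:
    """Normative 5th-percentile cutoffs for the synthetic battery.

    Fixed at the healthy (lesion-free) generative distribution's 5th
    percentile, rounded to whole counts: a healthy-looking score is rarely
    below these, so cohort impairment rates above ~5 % reflect lesions.
    """
    return NormTable(
        {
            SEMANTIC: 10.0,
            PHONEMIC: 8.0,
            "boston_naming": 19.0,
            "token_test": 15.0,
        }
    )
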