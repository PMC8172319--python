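"""Synthetic VBM-like cohorts with known, injectable structure.

This module emulates the *outputs* of a VBM pipeline (segmented, template-
aligned, smoothed GM/WM tissue-density maps) so the whole workflow — records,
folds, training, evaluation, saliency — can be exercised and verified without
any imaging download.  It makes no attempt to model segmentation itself,
scanner/site effects or cortical folding; see docs/methods.md for what that
does and does not imply.

A cohort is defined by a :class:`CohortSpec` and an :class:`AtlasVolume`.
Per subject, baseline densities (GM 0.6, WM 0.5 inside the brain) receive the
configured regional effects (an age slope and/or group offsets confined to
chosen atlas ROIs), are Gaussian-smoothed, perturbed with i.i.d. noise,
clipped to [0, 1], and background voxels are set to exactly -1.

Reproducibility: each subject has its own RNG stream derived from
``(seed, subject index)``, so a cohort is bit-identical however it is
(re)generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .volume_io import (BACKGROUND, DEFAULT_AFFINE, PhenotypeRecord,
                        TissueVolumePair, write_nifti, write_phenotypes_csv)

__all__ = [
    "AtlasVolume", "EffectSpec", "CohortSpec", "CapacityError",
    "generate_atlas", "generate_cohort", "write_cohort", "benchmark_cohort",
    "null_cohort",
]

GM_BASELINE = 0.6
WM_BASELINE = 0.5


class CapacityError(ValueError):
    """More ROIs requested than the brain has voxels."""


@dataclass
class AtlasVolume:
    """Integer parcellation: 0 = background, k >= 1 = ROI id."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"ROI ids without names: {sorted(missing)}")
        empty = [k for k in self.names if k not in present]
        if empty:
            raise ValueError(f"named ROI ids with no voxels: {sorted(empty)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.names)

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def roi_mask(self, roi_ids) -> np.ndarray:
        return np.isin(self.labels, np.asarray(list(roi_ids)))


@dataclass(frozen=True)
class EffectSpec:
    """A regional ground-truth effect to inject.

    ``target`` chooses the phenotype driving the effect; ``magnitude`` is a
    density change per year of age (centred on the cohort mean age) or a
    group offset added for the positive class (female / disorder).
    """

    target: str
    roi_ids: tuple[int, ...]
    magnitude: float
    tissue: str = "GM"

    def __post_init__(self):
        if self.target not in ("age", "gender", "diagnosis"):
            raise ValueError(f"unknown effect target {self.target!r}")
        if self.tissue not in ("GM", "WM", "both"):
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if not np.isfinite(self.magnitude):
            raise ValueError("effect magnitude must be finite")
        object.__setattr__(self, "roi_ids", tuple(int(r) for r in self.roi_ids))


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults emulate the demographic envelope of the paediatric datasets this
    package targets: ages uniform on 6-20 years, roughly balanced genders,
    and a sizeable minority carrying a diagnosis.  ``gender_balance`` /
    ``diagnosis_balance`` are the probabilities of the positive class
    (female / disorder).
    """

    n_subjects: int
    shape: tuple[int, int, int] = (121, 145, 121)
    age_range: tuple[float, float] = (6.0, 20.0)
    gender_balance: float = 0.5
    diagnosis_balance: float = 0.4
    effects: tuple[EffectSpec, ...] = ()
    smoothing_sigma: float = 1.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 < self.gender_balance < 1.0:
            raise ValueError("gender_balance must be in (0, 1)")
        if not 0.0 <= self.diagnosis_balance < 1.0:
            raise ValueError("diagnosis_balance must be in [0, 1)")
        if self.age_range[0] <= 0 or self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be an increasing positive interval")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "effects", tuple(self.effects))

    def validate_against(self, atlas: AtlasVolume) -> None:
        if tuple(atlas.shape) != self.shape:
            raise ValueError(f"atlas shape {atlas.shape} != cohort shape {self.shape}")
        known = set(atlas.names)
        for eff in self.effects:
            bad = set(eff.roi_ids) - known
            if bad:
                raise ValueError(f"effect on unknown ROI ids {sorted(bad)}")


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    # brain = axis-aligned ellipsoid with semi-axes 40% of each grid extent
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centre = [(s - 1) / 2.0 for s in shape]
    semi = [0.4 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0


def generate_atlas(shape: tuple[int, int, int], n_rois: int, seed: int = 0) -> AtlasVolume:
    """Ellipsoidal brain partitioned into ``n_rois`` contiguous blob ROIs.

    ROIs are the Voronoi cells of ``n_rois`` random in-brain seed voxels
    (nearest-seed assignment), which yields compact contiguous parcels.
    Deterministic given ``seed``.
    """
    shape = tuple(int(s) for s in shape)
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if any(s < 8 for s in shape):
        raise ValueError("every grid dimension must be >= 8 voxels")
    mask = _ellipsoid_mask(shape)
    coords = np.argwhere(mask)
    if n_rois > len(coords):
        raise CapacityError(f"{n_rois} ROIs requested but the brain has only "
                            f"{len(coords)} voxels")
    rng = np.random.default_rng(seed)
    seed_voxels = coords[rng.choice(len(coords), size=n_rois, replace=False)]
    _, nearest = cKDTree(seed_voxels).query(coords)
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(coords.T)] = nearest + 1
    names = {k: f"ROI_{k:03d}" for k in range(1, n_rois + 1)}
    return AtlasVolume(labels, names)


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate_cohort(spec: CohortSpec, atlas: AtlasVolume
                    ) -> tuple[list[TissueVolumePair], list[PhenotypeRecord]]:
    """Draw phenotypes and synthesize masked GM/WM volumes for every subject.

    Ages are uniform on ``age_range``; gender and diagnosis are Bernoulli
    draws at the configured balances.  Age effects are centred on the
    midpoint of ``age_range`` so the cohort-mean density stays at baseline.
    An empty effect list yields a pure-noise null cohort.
    """
    spec.validate_against(atlas)
    brain = atlas.brain_mask()
    lo, hi = spec.age_range
    mid_age = 0.5 * (lo + hi)
    disorder = "ADHD"

    pairs: list[TissueVolumePair] = []
    phenotypes: list[PhenotypeRecord] = []
    for i in range(spec.n_subjects):
        rng = _subject_rng(spec.seed, i)
        age = float(rng.uniform(lo, hi))
        gender = int(rng.random() < spec.gender_balance)
        diagnosis = int(rng.random() < spec.diagnosis_balance)
        record = PhenotypeRecord(subject_id=f"sub-{i:04d}", age=age, gender=gender,
                                 diagnosis=diagnosis, disorder_name=disorder)

        gm = np.where(brain, GM_BASELINE, 0.0)
        wm = np.where(brain, WM_BASELINE, 0.0)
        for eff in spec.effects:
            if eff.target == "age":
                delta = eff.magnitude * (age - mid_age)
            else:
                value = gender if eff.target == "gender" else diagnosis
                delta = eff.magnitude * value
            if delta == 0.0:
                continue
            region = atlas.roi_mask(eff.roi_ids)
            if eff.tissue in ("GM", "both"):
                gm[region] += delta
            if eff.tissue in ("WM", "both"):
                wm[region] += delta
        if spec.smoothing_sigma > 0:
            gm = gaussian_filter(gm, spec.smoothing_sigma)
            wm = gaussian_filter(wm, spec.smoothing_sigma)
        if spec.noise_sd > 0:
            gm = gm + rng.normal(0.0, spec.noise_sd, size=spec.shape)
            wm = wm + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        gm = np.where(brain, np.clip(gm, 0.0, 1.0), BACKGROUND).astype(np.float32)
        wm = np.where(brain, np.clip(wm, 0.0, 1.0), BACKGROUND).astype(np.float32)
        pairs.append(TissueVolumePair(record.subject_id, gm, wm))
        phenotypes.append(record)
    return pairs, phenotypes


# ---------------------------------------------------------------------------
# canonical study cohorts (used by the end-to-end recovery checks)

AGE_EFFECT_ROI = 2
GENDER_EFFECT_ROI = 5
AGE_SLOPE = -0.02   # density change per year, GM
GENDER_OFFSET = 0.04  # density offset for the positive (female) class, GM
BENCHMARK_N_ROIS = 8


def benchmark_cohort(seed: int, n_subjects: int = 400,
                     shape: tuple[int, int, int] = (32, 32, 32)
                     ) -> tuple[list[TissueVolumePair], list[PhenotypeRecord], AtlasVolume]:
    """The recovery study: an age slope in one ROI, a gender offset in another.

    A 32^3 grid with an 8-ROI atlas; the injected effects are the ground
    truth that training must detect and saliency must localise.  The atlas
    seed is fixed so the ROI geometry is the study design, not a random
    variable; subject draws vary with ``seed``.
    """
    atlas = generate_atlas(shape, BENCHMARK_N_ROIS, seed=0)
    spec = CohortSpec(
        n_subjects=n_subjects,
        shape=shape,
        effects=(
            EffectSpec("age", (AGE_EFFECT_ROI,), AGE_SLOPE, tissue="GM"),
            EffectSpec("gender", (GENDER_EFFECT_ROI,), GENDER_OFFSET, tissue="GM"),
        ),
        seed=seed,
    )
    pairs, phenotypes = generate_cohort(spec, atlas)
    return pairs, phenotypes, atlas


def null_cohort(seed: int, n_subjects: int = 150,
                shape: tuple[int, int, int] = (32, 32, 32)
                ) -> tuple[list[TissueVolumePair], list[PhenotypeRecord], AtlasVolume]:
    """Effect-free cohort: identical pipeline, no injected signal."""
    atlas = generate_atlas(shape, BENCHMARK_N_ROIS, seed=0)
    spec = CohortSpec(n_subjects=n_subjects, shape=shape, effects=(), seed=seed)
    pairs, phenotypes = generate_cohort(spec, atlas)
    return pairs, phenotypes, atlas


# ---------------------------------------------------------------------------
# on-disk cohort layout


def write_cohort(pairs: list[TissueVolumePair], phenotypes: list[PhenotypeRecord],
                 atlas: AtlasVolume, outdir: str | Path, seed: int | None = None,
                 affine: np.ndarray = DEFAULT_AFFINE) -> Path:
    """Write per-subject GM/WM NIfTI files, the phenotype CSV, the atlas
    (integer NIfTI + JSON name map) and a manifest; returns the directory."""
    outdir = Path(outdir)
    (outdir / "volumes").mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        write_nifti(pair.gm, outdir / "volumes" / f"{pair.subject_id}_gm.nii.gz", affine)
        write_nifti(pair.wm, outdir / "volumes" / f"{pair.subject_id}_wm.nii.gz", affine)
    write_phenotypes_csv(phenotypes, outdir / "phenotypes.csv")
    write_nifti(atlas.labels.astype(np.int32), outdir / "atlas.nii.gz", affine)
    (outdir / "atlas_names.json").write_text(
        json.dumps({str(k): v for k, v in atlas.names.items()}, indent=2))
    manifest = {"n_subjects": len(pairs), "shape": list(pairs[0].shape) if pairs else None,
                "seed": seed}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
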