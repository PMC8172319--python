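"""SmoothGrad attribution, fold aggregation, atlas intersection, ROI ranking.

SmoothGrad for one example and one task: average, over ``n_samples``
Gaussian-perturbed copies of the input, the absolute gradient of that task's
output with respect to the input, with the other two heads excluded from the
gradient target.  The noise standard deviation is
``noise_level * (max - min)`` of the *in-brain* input values (the SmoothGrad
range convention; background marker voxels do not inflate the range).  The
two tissue channels are collapsed voxelwise (mean by default) and background
voxels are zeroed in the map.

Aggregation follows the per-fold protocol: average the per-example maps of
each fold's test set, min-max normalize each fold map over in-brain voxels,
then average the normalized maps across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nn import MultitaskCNN3D, TASKS
from .synth import AtlasVolume
from .volume_io import SampleTensor, write_nifti

__all__ = [
    "AttentionMap", "smoothgrad", "aggregate_maps", "rank_rois",
    "export_overlay", "resample_atlas_nearest",
]

DEFAULT_N_SAMPLES = 5
DEFAULT_NOISE_LEVEL = 0.20


@dataclass
class AttentionMap:
    """Nonnegative voxel grid of gradient magnitude for one task."""

    values: np.ndarray
    task: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("attention map must be 3-D")
        if np.any(self.values < 0):
            raise ValueError("attention values must be nonnegative")


def _collapse(channels_last: np.ndarray, how: str) -> np.ndarray:
    if how == "mean":
        return channels_last.mean(axis=-1)
    if how == "max":
        return channels_last.max(axis=-1)
    raise ValueError(f"unknown channel collapse {how!r}")


def smoothgrad(model: MultitaskCNN3D, sample: SampleTensor, task: str,
               n_samples: int = DEFAULT_N_SAMPLES,
               noise_level: float = DEFAULT_NOISE_LEVEL,
               seed: int = 0, channel_collapse: str = "mean") -> AttentionMap:
    """SmoothGrad map of one task's output for one example.

    ``noise_level=0, n_samples=1`` degenerates to the plain absolute
    gradient.  Deterministic given ``seed``.
    """
    if task not in TASKS:
        raise KeyError(f"unknown task {task!r}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    x = np.asarray(sample.values, dtype=np.float32)
    brain = np.any(x != -1.0, axis=-1)
    in_brain = x[brain]
    value_range = float(in_brain.max() - in_brain.min()) if in_brain.size else 0.0
    sd = noise_level * value_range
    rng = np.random.default_rng(seed)

    acc = np.zeros(x.shape[:3], dtype=np.float64)
    for i in range(n_samples):
        xi = x if sd == 0 else x + rng.normal(0.0, sd, size=x.shape).astype(np.float32)
        grad = model.input_gradient(xi, task)
        if not np.isfinite(grad).all():
            raise FloatingPointError(f"non-finite gradient at perturbation {i}")
        acc += _collapse(np.abs(grad), channel_collapse)
    values = (acc / n_samples).astype(np.float32)
    values[~brain] = 0.0
    return AttentionMap(values, task, provenance={
        "n_samples": n_samples, "noise_level": noise_level,
        "channel_collapse": channel_collapse, "seed": seed,
        "subject_id": sample.phenotype.subject_id})


def _minmax_normalize(values: np.ndarray, brain: np.ndarray) -> np.ndarray:
    out = np.zeros_like(values, dtype=np.float32)
    inside = values[brain]
    if inside.size == 0:
        return out
    lo, hi = float(inside.min()), float(inside.max())
    if hi == lo:
        warnings.warn("flat attention map; normalization degenerate", stacklevel=2)
        return out
    out[brain] = (values[brain] - lo) / (hi - lo)
    return out


def aggregate_maps(maps_by_fold: Mapping[int, Sequence[AttentionMap]],
                   brain_mask: np.ndarray | None = None) -> AttentionMap:
    """Mean over each fold's example maps, min-max normalize per fold over
    in-brain voxels, then mean across folds."""
    if not maps_by_fold:
        raise ValueError("no fold maps")
    shapes = {m.values.shape for maps in maps_by_fold.values() for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent map shapes across folds: {shapes}")
    tasks = {m.task for maps in maps_by_fold.values() for m in maps}
    task = tasks.pop() if len(tasks) == 1 else "mixed"
    shape = shapes.pop()
    if brain_mask is None:
        # fall back to "any voxel with nonzero attention anywhere"
        brain_mask = np.zeros(shape, dtype=bool)
        for maps in maps_by_fold.values():
            for m in maps:
                brain_mask |= m.values > 0
    normalized = []
    for fold in sorted(maps_by_fold):
        maps = maps_by_fold[fold]
        if not maps:
            raise ValueError(f"fold {fold} has no example maps")
        fold_mean = np.mean([m.values for m in maps], axis=0)
        normalized.append(_minmax_normalize(fold_mean, brain_mask))
    values = np.mean(normalized, axis=0).astype(np.float32)
    return AttentionMap(values, task, provenance={
        "folds": sorted(maps_by_fold),
        "n_examples": {int(f): len(maps_by_fold[f]) for f in maps_by_fold},
        "normalization": "minmax_in_brain"})


def rank_rois(attention: AttentionMap, atlas: AtlasVolume, top_k: int = 10,
              statistic: str = "mean") -> pd.DataFrame:
    """Top-k ROIs by attention statistic (mean by default, so ROI size does
    not dominate; ``sum`` available).  Ties break toward the lower ROI id.

    Returns columns (task, roi_id, roi_name, statistic, value, rank).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if atlas.shape != attention.values.shape:
        raise ValueError(f"atlas shape {atlas.shape} != map shape {attention.values.shape}")
    if statistic not in ("mean", "sum"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rows = []
    labels = atlas.labels
    for roi_id in atlas.roi_ids:
        sel = labels == roi_id
        if not sel.any():
            warnings.warn(f"ROI {roi_id} has no voxels; skipped", stacklevel=2)
            continue
        vals = attention.values[sel]
        value = float(vals.mean() if statistic == "mean" else vals.sum())
        rows.append((roi_id, atlas.names[roi_id], value))
    # sort by value desc, then roi_id asc (tie rule)
    rows.sort(key=lambda r: (-r[2], r[0]))
    rows = rows[:top_k]
    return pd.DataFrame({
        "task": attention.task,
        "roi_id": [r[0] for r in rows],
        "roi_name": [r[1] for r in rows],
        "statistic": statistic,
        "value": [r[2] for r in rows],
        "rank": np.arange(1, len(rows) + 1),
    })


def export_overlay(attention: AttentionMap, reference_affine: np.ndarray,
                   path: str | Path, reference_shape: tuple | None = None) -> Path:
    """Write the map as a NIfTI overlay in the reference space, scaled to
    [0, 1] (viewers expect a bounded color range); background stays 0."""
    if reference_shape is not None and tuple(reference_shape) != attention.values.shape:
        raise ValueError(f"reference shape {reference_shape} != map shape "
                         f"{attention.values.shape}")
    values = attention.values
    vmax = float(values.max())
    if vmax > 0:
        values = values / vmax
    write_nifti(values.astype(np.float32), path, np.asarray(reference_affine))
    return Path(path)


def resample_atlas_nearest(atlas: AtlasVolume, target_shape: tuple[int, int, int]
                           ) -> AtlasVolume:
    """Nearest-neighbour resampling of an atlas onto another grid.

    A stand-in for proper affine-aware resampling: it assumes the two grids
    cover the same field of view and only differ in sampling density.
    """
    src = atlas.labels
    idx = [np.clip(np.round(np.linspace(0, s - 1, t)).astype(int), 0, s - 1)
           for s, t in zip(src.shape, target_shape)]
    labels = src[np.ix_(*idx)]
    present = set(np.unique(labels)) - {0}
    names = {k: v for k, v in atlas.names.items() if k in present}
    return AtlasVolume(labels, names)
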