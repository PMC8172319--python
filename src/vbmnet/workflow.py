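"""Model/results facade over the full cross-validated workflow.

:class:`MultitaskBrainCNN` holds a cohort (stacked two-channel samples, an
optional atlas) plus the architecture/optimizer configuration;
:meth:`MultitaskBrainCNN.fit` runs the stratified k-fold protocol — per-fold
training with per-task checkpoints, validation-based operating points, test
metrics — and returns a :class:`MultitaskCVResults` carrying per-fold and
aggregate reports, cross-fold model selection, SmoothGrad aggregation and
ROI ranking.

Typical use::

    pairs, phenotypes, atlas = synth.benchmark_cohort(seed=1)
    model = MultitaskBrainCNN.from_cohort(pairs, phenotypes, atlas,
                                          model_config=ModelConfig.small(),
                                          train_config=TrainConfig(max_epochs=40,
                                                                   patience=8))
    results = model.fit(k=3, seed=1)
    print(results.summary())
    table = results.rank_rois("age", top_k=3)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import saliency as sal
from .folds import FoldSplit, make_folds
from .nn import LossWeights, ModelConfig, MultitaskCNN3D, TASKS, build_model
from .synth import AtlasVolume
from .train import (BestAcrossFolds, TaskCheckpointSet, TrainConfig,
                    TrainingHistory, select_best_across_folds, train_fold)
from .volume_io import (PhenotypeRecord, SampleTensor, TissueVolumePair,
                        stack_channels)

__all__ = ["MultitaskBrainCNN", "MultitaskCVResults", "FoldReport"]

ENCODING_HEADER = ("label encoding: gender 1=female, 0=male; "
                   "diagnosis 1=disorder, 0=healthy control")

CLASSIFICATION_TASKS = ("gender", "diagnosis")


@dataclass
class FoldReport:
    """Test-set metrics of one cross-validation round."""

    round_index: int
    age: ev.RegressionReport
    gender: ev.ClassificationReport
    diagnosis: ev.ClassificationReport
    baseline_age_mae: float
    history: TrainingHistory

    def row(self) -> dict:
        d = {"fold": self.round_index,
             "age_mae": self.age.mae, "age_r": self.age.pearson_r,
             "age_p": self.age.p_value, "age_r2": self.age.r2,
             "baseline_age_mae": self.baseline_age_mae}
        for task in CLASSIFICATION_TASKS:
            rep: ev.ClassificationReport = getattr(self, task)
            d.update({f"{task}_precision": rep.precision, f"{task}_recall": rep.recall,
                      f"{task}_f1": rep.f1, f"{task}_auc": rep.auc,
                      f"{task}_threshold": rep.threshold})
        return d


class MultitaskBrainCNN:
    """Multitask 3D CNN estimator for one cohort.

    Parameters
    ----------
    samples
        Mapping subject id -> :class:`SampleTensor` (already masked/stacked).
    atlas
        Optional :class:`AtlasVolume` on the same grid (needed for ROI
        ranking).
    model_config, train_config, loss_weights
        Architecture and optimization settings; defaults follow the method's
        published values.
    """

    def __init__(self, samples: Mapping[str, SampleTensor],
                 atlas: AtlasVolume | None = None,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None,
                 loss_weights: LossWeights | None = None):
        if not samples:
            raise ValueError("empty cohort")
        self.samples = dict(samples)
        self.atlas = atlas
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.loss_weights = loss_weights or LossWeights()
        shapes = {s.spatial_shape for s in self.samples.values()}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent sample shapes: {shapes}")
        self.input_shape = shapes.pop()

    @classmethod
    def from_cohort(cls, pairs: Sequence[TissueVolumePair],
                    phenotypes: Sequence[PhenotypeRecord],
                    atlas: AtlasVolume | None = None, **kwargs) -> "MultitaskBrainCNN":
        """Build from tissue pairs + phenotype records (stacks channels)."""
        if len(pairs) != len(phenotypes):
            raise ValueError("pairs and phenotypes differ in length")
        samples = {ph.subject_id: stack_channels(pair, ph)
                   for pair, ph in zip(pairs, phenotypes)}
        return cls(samples, atlas=atlas, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self, k: int = 10, seed: int = 0,
            folds: Sequence[FoldSplit] | None = None,
            precomputed: Mapping[int, TaskCheckpointSet] | None = None
            ) -> "MultitaskCVResults":
        """Run the full stratified k-fold protocol.

        ``folds`` overrides the generated splits; ``precomputed`` supplies
        already-trained checkpoint sets by round index (resume support) —
        those rounds skip training but are still evaluated.
        """
        strata = {sid: s.phenotype.diagnosis for sid, s in self.samples.items()}
        if folds is None:
            folds = make_folds(strata, k=k, seed=seed)
        checkpoint_sets: list[TaskCheckpointSet] = []
        reports: list[FoldReport] = []
        histories: list[TrainingHistory] = []
        for split in folds:
            pre = (precomputed or {}).get(split.round_index)
            if pre is not None:
                checkpoints, history = pre, TrainingHistory(stop_reason="precomputed")
            else:
                cfg = self.train_config
                fold_cfg = TrainConfig(**{**cfg.to_dict(), "seed": seed + cfg.seed})
                checkpoints, history = train_fold(
                    self.samples, split, self.model_config, fold_cfg,
                    self.loss_weights)
            checkpoint_sets.append(checkpoints)
            histories.append(history)
            reports.append(self._evaluate_fold(split, checkpoints, history))
        return MultitaskCVResults(model=self, folds=list(folds),
                                  checkpoint_sets=checkpoint_sets,
                                  fold_reports=reports, seed=seed)

    # -- prediction helpers --------------------------------------------------

    def _network_with_state(self, state) -> MultitaskCNN3D:
        net = build_model(self.model_config, self.input_shape)
        net.set_state(state)
        return net

    def predict_state(self, state, subject_ids: Sequence[str],
                      samples: Mapping[str, SampleTensor] | None = None,
                      chunk: int = 64) -> dict[str, np.ndarray]:
        """Forward a set of subjects through a stored model state."""
        samples = self.samples if samples is None else samples
        net = self._network_with_state(state)
        x = np.stack([samples[sid].values for sid in subject_ids])
        outs = {t: [] for t in TASKS}
        for start in range(0, len(x), chunk):
            out = net.forward(x[start:start + chunk], training=False)
            for t in TASKS:
                outs[t].append(out[t])
        return {t: np.concatenate(v) for t, v in outs.items()}

    def _evaluate_fold(self, split: FoldSplit, checkpoints: TaskCheckpointSet,
                       history: TrainingHistory) -> FoldReport:
        ph = {sid: self.samples[sid].phenotype for sid in self.samples}
        test_ids = list(split.test_ids)
        val_ids = list(split.val_ids)
        age_true = np.array([ph[s].age for s in test_ids])
        train_mean_age = float(np.mean([ph[s].age for s in split.train_ids]))
        baseline_mae = float(np.mean(np.abs(age_true - train_mean_age)))

        age_pred = self.predict_state(checkpoints.states["age"], test_ids)["age"]
        age_report = ev.regression_metrics(age_true, age_pred)

        cls_reports = {}
        for task in CLASSIFICATION_TASKS:
            val_out = self.predict_state(checkpoints.states[task], val_ids)[task]
            val_labels = np.array([getattr(ph[s], task) for s in val_ids])
            test_out = self.predict_state(checkpoints.states[task], test_ids)[task]
            test_labels = np.array([getattr(ph[s], task) for s in test_ids])
            threshold = ev.select_operating_point(val_labels, val_out)
            cls_reports[task] = ev.classification_metrics(test_labels, test_out, threshold)
        return FoldReport(round_index=split.round_index, age=age_report,
                          gender=cls_reports["gender"],
                          diagnosis=cls_reports["diagnosis"],
                          baseline_age_mae=baseline_mae, history=history)


@dataclass
class MultitaskCVResults:
    """Fitted results: per-fold reports, selection, saliency, summaries."""

    model: MultitaskBrainCNN
    folds: list[FoldSplit]
    checkpoint_sets: list[TaskCheckpointSet]
    fold_reports: list[FoldReport]
    seed: int
    _saliency_cache: dict = field(default_factory=dict, repr=False)

    # -- tables --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.row() for r in self.fold_reports])

    def summary(self) -> "Summary":
        """Per-fold metrics plus mean +/- SD aggregate rows."""
        df = self.to_frame()
        agg = df.drop(columns=["fold"]).agg(["mean", "std"])
        agg.insert(0, "fold", ["mean", "sd"])
        table = pd.concat([df, agg], ignore_index=True)
        return Summary(table, n_folds=len(self.folds), seed=self.seed)

    # -- model selection ------------------------------------------------------

    def best(self, task: str) -> BestAcrossFolds:
        return select_best_across_folds(self.checkpoint_sets, task)

    def best_threshold(self, task: str) -> float:
        """Operating point of the best fold's checkpoint (selected on its
        validation data)."""
        best = self.best(task)
        report = self.fold_reports[best.fold_index]
        return getattr(report, task).threshold

    def cross_evaluate(self, samples: Mapping[str, SampleTensor], task: str):
        """Apply the best checkpoint for ``task`` to another full cohort."""
        ids = list(samples)
        best = self.best(task)
        out = self.model.predict_state(best.state, ids, samples=samples)[task]
        ph = [samples[s].phenotype for s in ids]
        if task == "age":
            return ev.regression_metrics([p.age for p in ph], out)
        labels = [getattr(p, task) for p in ph]
        return ev.classification_metrics(labels, out, self.best_threshold(task))

    # -- attribution ----------------------------------------------------------

    def saliency(self, task: str, n_samples: int = sal.DEFAULT_N_SAMPLES,
                 noise_level: float = sal.DEFAULT_NOISE_LEVEL,
                 max_examples_per_fold: int | None = None,
                 seed: int | None = None) -> sal.AttentionMap:
        """Aggregate SmoothGrad maps over every fold's test set using that
        fold's best checkpoint for ``task``."""
        seed = self.seed if seed is None else seed
        key = (task, n_samples, noise_level, max_examples_per_fold, seed)
        if key in self._saliency_cache:
            return self._saliency_cache[key]
        maps_by_fold: dict[int, list[sal.AttentionMap]] = {}
        for split, checkpoints in zip(self.folds, self.checkpoint_sets):
            net = self.model._network_with_state(checkpoints.states[task])
            test_ids = list(split.test_ids)
            if max_examples_per_fold is not None:
                test_ids = test_ids[:max_examples_per_fold]
            fold_maps = []
            for j, sid in enumerate(test_ids):
                fold_maps.append(sal.smoothgrad(
                    net, self.model.samples[sid], task,
                    n_samples=n_samples, noise_level=noise_level,
                    seed=seed * 100003 + split.round_index * 1009 + j))
            maps_by_fold[split.round_index] = fold_maps
        brain = self.model.atlas.brain_mask() if self.model.atlas is not None else None
        agg = sal.aggregate_maps(maps_by_fold, brain_mask=brain)
        self._saliency_cache[key] = agg
        return agg

    def rank_rois(self, task: str, top_k: int = 10, **saliency_kwargs) -> pd.DataFrame:
        if self.model.atlas is None:
            raise ValueError("ROI ranking needs an atlas")
        attention = self.saliency(task, **saliency_kwargs)
        return sal.rank_rois(attention, self.model.atlas, top_k=top_k)

    # -- diagnostics -----------------------------------------------------------

    def confound_check(self, mode: str = "count") -> dict:
        ids = list(self.model.samples)
        samples = [self.model.samples[s] for s in ids]
        phenotypes = [s.phenotype for s in samples]
        return ev.confound_check(samples, phenotypes, mode=mode)


class Summary:
    """Printable cross-validation summary (statsmodels-style)."""

    def __init__(self, table: pd.DataFrame, n_folds: int, seed: int):
        self.table = table
        self.n_folds = n_folds
        self.seed = seed

    def __str__(self) -> str:
        lines = [
            "Multitask 3D CNN cross-validation summary",
            f"folds: {self.n_folds}   seed: {self.seed}",
            ENCODING_HEADER,
            "",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def _repr_html_(self):  # notebook display
        return self.table.to_html(index=False)
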