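"""Canonical scaled-down recovery studies on synthetic cohorts.

These define the package's reference experiment: a 32^3 cohort of 400
subjects with a known age slope (-0.02 density/yr, GM, one ROI) and gender
offset (+0.04, GM, another ROI), fitted with the 2-block configuration under
a k=3 stratified protocol.  ``recovery_study`` reports whether the fitted
model (a) beats the predict-the-mean age baseline, (b) classifies gender
well, and (c) localises each injected ROI via SmoothGrad ranking.
``null_study`` runs the identical pipeline on an effect-free cohort, where
all of that must *fail* (metrics at chance).

The training schedule here (learning rate 5e-3, batch 16, up to 26 epochs,
dropout 0.1) is the package's small-problem preset; see docs/methods.md for
why it differs from the full-scale defaults.
"""

from __future__ import annotations

from . import synth
from .nn import ModelConfig
from .train import TrainConfig
from .workflow import MultitaskBrainCNN, MultitaskCVResults

__all__ = ["small_model_config", "small_train_config", "fit_benchmark",
           "recovery_study", "null_study"]

SALIENCY_EXAMPLES_PER_FOLD = 16


def small_model_config() -> ModelConfig:
    """2 blocks, filters (4, 8), dense 32; light dropout for the small grid."""
    return ModelConfig(filters_per_block=(4, 8), dense_units=32, dropout_rate=0.1)


def small_train_config(max_epochs: int = 26) -> TrainConfig:
    return TrainConfig(learning_rate=5e-3, batch_size=16,
                       max_epochs=max_epochs, patience=min(8, max_epochs - 1))


def fit_benchmark(pairs, phenotypes, atlas, seed: int,
                  max_epochs: int = 26, k: int = 3) -> MultitaskCVResults:
    model = MultitaskBrainCNN.from_cohort(
        pairs, phenotypes, atlas,
        model_config=small_model_config(),
        train_config=small_train_config(max_epochs))
    return model.fit(k=k, seed=seed)


def recovery_study(seed: int, n_subjects: int = 400, max_epochs: int = 26) -> dict:
    """Fit the injected-effect cohort and measure signal recovery.

    Returns per-seed quantities: the best-age checkpoint's test MAE and its
    ratio to the predict-the-mean baseline, the best-gender checkpoint's test
    AUC, and the SmoothGrad rank of each injected ROI for its task.
    """
    pairs, phenotypes, atlas = synth.benchmark_cohort(seed, n_subjects=n_subjects)
    results = fit_benchmark(pairs, phenotypes, atlas, seed, max_epochs=max_epochs)

    age_fold = results.fold_reports[results.best("age").fold_index]
    gender_fold = results.fold_reports[results.best("gender").fold_index]

    def roi_rank(task, roi_id):
        table = results.rank_rois(
            task, top_k=synth.BENCHMARK_N_ROIS,
            max_examples_per_fold=SALIENCY_EXAMPLES_PER_FOLD)
        hit = table[table["roi_id"] == roi_id]
        return int(hit["rank"].iloc[0]) if len(hit) else synth.BENCHMARK_N_ROIS + 1

    return {
        "age_test_mae": age_fold.age.mae,
        "baseline_age_mae": age_fold.baseline_age_mae,
        "age_mae_ratio": age_fold.age.mae / age_fold.baseline_age_mae,
        "age_test_r2": age_fold.age.r2,
        "gender_test_auc": gender_fold.gender.auc,
        "age_roi_rank": roi_rank("age", synth.AGE_EFFECT_ROI),
        "gender_roi_rank": roi_rank("gender", synth.GENDER_EFFECT_ROI),
        "results": results,
    }


def null_study(seed: int, n_subjects: int = 150, max_epochs: int = 8) -> dict:
    """Fit an effect-free cohort: everything should sit at chance level."""
    pairs, phenotypes, atlas = synth.null_cohort(seed, n_subjects=n_subjects)
    results = fit_benchmark(pairs, phenotypes, atlas, seed, max_epochs=max_epochs)
    gender_fold = results.fold_reports[results.best("gender").fold_index]
    age_fold = results.fold_reports[results.best("age").fold_index]
    # density-sum volume: the synthetic generator emulates modulated
    # (Jacobian-scaled) maps on a fixed template mask, so the voxel count is
    # constant by construction and only the summed density carries volume
    confound = results.confound_check(mode="sum")
    return {
        "gender_test_auc": gender_fold.gender.auc,
        "age_test_r2": age_fold.age.r2,
        "confound_gender_auc": confound["gender_auc"],
        "confound_age_r": confound["age_r"],
        "results": results,
    }
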