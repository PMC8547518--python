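"""Reference synthetic-study conditions used for validation runs.

These functions freeze the desk-scale study design on which the package
validates itself end to end: a 20-region cohort of 40 subjects with a
1.0-standard-deviation mean shift injected into five regions (the "effect"
study), the matching null study with no injected effect, and the label-flip
permutation calibration on small null cohorts. Training uses the desk-scale
recipe (Adam at 1e-2, 150 epochs, no weight decay) rather than the
full-scale defaults, which are tuned for cohorts of ~1000 subjects and 108
regions; see the methods note for the rationale.
"""

from __future__ import annotations

import numpy as np

from . import evaluate, explain
from .io import sampleset_from_cohort_subject
from .model import ModelConfig, model_forward, train_model
from .network import MorphNetwork, build_network
from .synthetic import EffectSpec, SyntheticCohort, simulate_cohort

__all__ = [
    "desk_config",
    "cohort_networks",
    "effect_study",
    "null_study_accuracy",
    "permutation_calibration",
]

#: regions carrying the group effect in the reference effect study
EFFECT_REGIONS = frozenset({2, 5, 9, 13, 17})
#: 1.0 x the regional standard deviation (base_sd = 0.1)
EFFECT_SHIFT = 0.1
N_PER_GROUP = 20
N_REGIONS = 20
VOXELS_PER_REGION = 200
N_POINTS = 128


def desk_config(seed: int, **overrides) -> ModelConfig:
    """Training recipe for 40-subject synthetic cohorts."""
    params = dict(learning_rate=1e-2, weight_decay=0.0, max_epochs=150,
                  seed=int(seed) & 0x7FFFFFFF)
    params.update(overrides)
    return ModelConfig(**params)


def cohort_networks(cohort: SyntheticCohort,
                    n_points: int = N_POINTS) -> list[MorphNetwork]:
    return [build_network(sampleset_from_cohort_subject(s), n_points=n_points)
            for s in cohort.subjects]


def effect_study(seed: int) -> dict[str, float]:
    """One full effect-cohort run: CV accuracy plus top-8 biomarker recovery.

    Returns cv_accuracy (5-fold stratified), recovery (fraction of the five
    effect regions among the top-8 attention source regions of the fused
    all-correct group map) and auc.
    """
    effect = EffectSpec(effect_regions=EFFECT_REGIONS, mean_shift=EFFECT_SHIFT,
                        seed=seed)
    cohort = simulate_cohort(N_PER_GROUP, N_PER_GROUP, N_REGIONS, effect,
                             voxels_per_region=VOXELS_PER_REGION, seed=seed)
    networks = cohort_networks(cohort)
    y = cohort.labels
    cfg = desk_config(seed)
    cv = evaluate.stratified_cross_validate(networks, y, cfg, k_folds=5,
                                            seed=seed)
    model = train_model(networks, y, cfg)
    records = [model_forward(net, model) for net in networks]
    fused = [explain.fuse_layer_maps(r, networks[0].region_labels)
             for r in records]
    code = {(1, 1): "TP", (1, 0): "FN", (0, 0): "TN", (0, 1): "FP"}
    outcomes = [code[(int(t), int(r.probability >= 0.5))]
                for t, r in zip(y, records)]
    group = explain.group_mean_map(fused, outcomes=outcomes,
                                   subject_filter="all_correct")
    report = explain.threshold_entries(group)
    recovery = explain.biomarker_recovery_score(report, cohort.ground_truth,
                                                k=8)
    return {"cv_accuracy": float(cv.mean_accuracy),
            "auc": float(cv.auc),
            "recovery": float(recovery)}


def null_study_accuracy(seed: int) -> float:
    """5-fold CV accuracy on a cohort with no injected effect (chance level)."""
    effect = EffectSpec(effect_regions=frozenset(), seed=seed)
    cohort = simulate_cohort(N_PER_GROUP, N_PER_GROUP, N_REGIONS, effect,
                             voxels_per_region=VOXELS_PER_REGION, seed=seed)
    networks = cohort_networks(cohort)
    cv = evaluate.stratified_cross_validate(networks, cohort.labels,
                                            desk_config(seed), k_folds=5,
                                            seed=seed)
    return float(cv.mean_accuracy)


def permutation_calibration(seed: int, n_reps: int = 20,
                            n_perm: int = 99) -> list[float]:
    """P-values of the label-flip test across independent null cohorts.

    Small cohorts (10 regions, 10+10 subjects) with reduced-epoch (fast)
    training keep the 2000 cross-validated fits tractable; under the null
    the p-values should rarely fall below 0.05.
    """
    p_values = []
    for rep in range(n_reps):
        rep_seed = (int(seed) + 104729 * rep) & 0x7FFFFFFF
        effect = EffectSpec(effect_regions=frozenset(), seed=rep_seed)
        cohort = simulate_cohort(10, 10, 10, effect, voxels_per_region=100,
                                 seed=rep_seed)
        networks = cohort_networks(cohort, n_points=64)
        cfg = desk_config(rep_seed, d_embed=16, batch_size=16, max_epochs=10)
        result = evaluate.permutation_test(
            networks, cohort.labels, cfg, n_perm=n_perm, flip_fraction=0.2,
            seed=rep_seed, k_folds=3, fast=True)
        p_values.append(result.p_value)
    return p_values
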