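"""Canonical end-to-end experiment recipes.

These functions tie the generator, the models and the evaluation kit into
the study designs the package is validated on: recovering known spatial
sources from simulated event-related data with a 64-unit tanh RBM, probing
whether network depth helps classification of a nonlinearly separable
cohort, and checking that the 2D constraint-satisfaction map organizes a
cohort by class and by disease severity once the data pass through a deep
network.  Tests, example scripts and the acceptance script all call these
so the study conditions live in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import simulate as sim
from .data import preprocess
from .dbn import DBNModel, FinetuneConfig, feedforward, finetune_softmax, pretrain_stack
from .embedding import class_separation, embed, severity_axis_correlation
from .evaluate import crossval_fscores, match_components
from .rbm import TrainConfig, flip_negative_features, project_timecourses, train_rbm

#: Reference RBM settings for source recovery on simulated event-related
#: data: 64 tanh hidden units, L1 decay 0.1, learning rate 0.08, batch 5.
RECOVERY_HIDDEN = 64
RECOVERY_CONFIG = dict(epsilon=0.08, lambda_l1=0.1, batch_size=5)

#: The 50-50-100 architecture and its training schedule used for the
#: structural-cohort experiments.  Upper layers are pre-trained longer, at a
#: higher rate and without L1 (logistic-logistic RBMs see much weaker
#: gradients than the Gaussian-visible first layer, and decay would pin
#: their weights at zero).  Fine-tuning uses plain mini-batch descent.
COHORT_ARCH = (50, 50, 100)
COHORT_PRETRAIN_EPS = (0.01, 0.1, 0.1)
COHORT_PRETRAIN_L1 = (0.01, 0.0, 0.0)
COHORT_PRETRAIN_EPOCHS = (15, 40, 40)
COHORT_FINETUNE_RATES = (0.05, 0.1, 0.1)
COHORT_FINETUNE_HEAD_RATE = 0.2
COHORT_FINETUNE_EPOCHS = 200


@dataclass(frozen=True)
class RecoveryResult:
    mean_sm_corr: float
    mean_tc_corr: float
    overlap: float
    spread: float


def source_recovery(
    seed: int,
    spread: float = 1.0,
    n_subjects: int = 20,
    grid_side: int = 64,
    n_sources: int = 27,
    n_epochs: int = 30,
    n_hidden: int = RECOVERY_HIDDEN,
) -> RecoveryResult:
    """Simulate a study, train the reference RBM on the preprocessed data,
    and score matched spatial-map and time-course recovery.

    The data of all subjects are concatenated along the volume axis; the
    preprocessing chain (mask below mean, mean-image removal, per-voxel
    z-scoring) runs on the concatenation.  Estimated maps are the rows of W
    restricted to the mask; estimated time courses are the linear
    projections of the data onto the features (no hidden nonlinearity).
    """
    study = sim.simulate_study(n_subjects=n_subjects, grid_side=grid_side,
                               n_sources=n_sources, spread=spread, seed=seed)
    dm = preprocess(study.concatenated())
    cfg = TrainConfig(n_epochs=n_epochs, seed=seed, **RECOVERY_CONFIG)
    params, _ = train_rbm(dm.values, n_hidden, cfg)
    params, _ = flip_negative_features(params)
    result = match_components(
        params.W, study.sources.maps[:, dm.mask],
        project_timecourses(dm.values, params), study.concatenated_tcs(),
    )
    return RecoveryResult(mean_sm_corr=result.mean_sm_corr,
                          mean_tc_corr=result.mean_tc_corr,
                          overlap=sim.compute_overlap(study.sources),
                          spread=spread)


def _cohort_stack(X: np.ndarray, seed: int) -> DBNModel:
    cfgs = [
        TrainConfig(epsilon=e, lambda_l1=l, n_epochs=n, batch_size=10, seed=seed + i)
        for i, (e, l, n) in enumerate(zip(
            COHORT_PRETRAIN_EPS, COHORT_PRETRAIN_L1, COHORT_PRETRAIN_EPOCHS))
    ]
    return pretrain_stack(X, list(COHORT_ARCH), cfgs)


def _finetune(stack: DBNModel, X, y, depth: int, seed: int) -> DBNModel:
    sub = DBNModel(layers=stack.layers[:depth])
    cfg = FinetuneConfig(n_epochs=COHORT_FINETUNE_EPOCHS, seed=seed,
                         learning_rates=COHORT_FINETUNE_RATES[:depth],
                         head_learning_rate=COHORT_FINETUNE_HEAD_RATE)
    return finetune_softmax(sub, X, y, cfg)


def depth_trend(
    seed: int,
    n_per_class: int = 100,
    signal: float = 0.6,
    noise_sd: float = 1.0,
    depths: tuple = (1, 3),
) -> dict[int, float]:
    """kNN F-score (10-fold, class-balanced) on fine-tuned activations of
    DBNs of different depths, on a cohort whose label is the XOR of two
    regional intensity offsets (no linear readout of raw voxels works)."""
    cohort = sim.generate_xor_cohort(n_per_class=n_per_class, signal=signal,
                                     noise_sd=noise_sd, seed=seed)
    dm = preprocess(cohort.volumes)
    X, y = dm.values, cohort.labels
    stack = _cohort_stack(X, seed)
    scores = {}
    for depth in depths:
        model = _finetune(stack, X, y, depth, seed)
        acts = feedforward(model, X)
        scores[depth] = crossval_fscores(acts, y, k=10, seed=seed).mean_f["knn"]
    return scores


@dataclass(frozen=True)
class EmbeddingAnalogResult:
    separation_raw: float
    separation_depth3: float
    severity_rho: float


def embedding_analogs(
    seed: int,
    n_per_class: int = 100,
    effect_size: float = 0.4,
    k: int = 20,
    max_iters: int = 200,
) -> EmbeddingAnalogResult:
    """Fig-style map experiments on one synthetic structural cohort:
    class separation of the 2D map built from raw voxels vs from depth-3
    fine-tuned activations, and the rank correlation of patient severity
    with position along the patient limb of the depth-3 map."""
    cohort = sim.generate_structural_cohort(
        n_controls=n_per_class, n_patients=n_per_class,
        effect_size=effect_size, seed=seed)
    dm = preprocess(cohort.volumes)
    X, y = dm.values, cohort.labels
    stack = _cohort_stack(X, seed)
    model = _finetune(stack, X, y, 3, seed)
    acts = feedforward(model, X)
    map_raw = embed(X, k=k, max_iters=max_iters)
    map_d3 = embed(acts, k=k, max_iters=max_iters)
    return EmbeddingAnalogResult(
        separation_raw=class_separation(map_raw.coords, y),
        separation_depth3=class_separation(map_d3.coords, y),
        severity_rho=severity_axis_correlation(map_d3.coords, y, cohort.severity),
    )
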