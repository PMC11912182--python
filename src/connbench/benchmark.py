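"""Desk-scale study conditions: the standard end-to-end recovery experiment.

This module fixes the scaled-down synthetic study used by the test-suite and
the acceptance script: a 20-site cohort at 70% of the reference site table
(~590 participants), 64 ROIs (2016 connectivity edges), 202 structural
features, 50 planted edges and 20 planted structural features at a
standardized effect size d = 1.5.  Feature selection keeps 300 edges and 80
structural features per split; neural models train for up to 60 epochs with
checkpoint selection every 10 (see docs/methods.md for the sizing rationale).

Everything here is ordinary library code — the same experiment can be run at
other sizes through the public APIs.
"""

from __future__ import annotations

import copy

import numpy as np

from . import evaluation as E
from . import interpretation as I
from . import synthdata as S
from .cohort import CohortData

__all__ = [
    "study_config",
    "study_cohort",
    "run_cv_study",
    "null_accuracy",
    "nested_max_vote_study",
    "fcn_saliency_recall",
    "run_full_study",
]

STUDY_MODE = "s+f"
STUDY_FEATURES = E.FeatureParams(k_fmri=300, k_smri=80, rfe_step=0.1)
STUDY_EPOCHS = {"max_epochs": 60, "eval_every": 10}


def study_config(seed: int, effect_size_d: float = 1.5) -> S.GenerationConfig:
    return S.GenerationConfig(
        n_rois=64,
        site_table=S.abide_like_site_table(0.7),
        n_informative_edges=50,
        n_informative_struct=20,
        effect_size_d=effect_size_d,
        n_cortical=10,
        n_noncortical=16,
        seed=seed,
    )


def study_cohort(seed: int, effect_size_d: float = 1.5):
    records, truth = S.generate_cohort(study_config(seed, effect_size_d))
    return CohortData.from_records(records), truth


def _overrides(architecture: str) -> dict:
    return {} if architecture == "svm" else dict(STUDY_EPOCHS)


def run_cv_study(
    architecture: str,
    data: CohortData,
    seed: int,
    return_models: bool = False,
) -> E.CVResult:
    plan = E.make_stratified_folds(data.y, data.sites, k=5, seed=seed)
    return E.run_cv(
        architecture,
        STUDY_MODE,
        plan,
        data,
        feature_params=STUDY_FEATURES,
        model_overrides=_overrides(architecture),
        model_seed=seed,
        return_models=return_models,
    )


def null_accuracy(data: CohortData, seed: int, architecture: str = "svm") -> float:
    """Pooled CV accuracy after globally permuting the class labels.

    The whole pipeline (stratification, standardization, RFE, tuning) is
    re-run on the permuted labels.
    """
    rng = np.random.default_rng(seed + 1)
    null_data = copy.copy(data)
    null_data.y = rng.permutation(data.y)
    plan = E.make_stratified_folds(null_data.y, null_data.sites, k=5, seed=seed)
    res = E.run_cv(
        architecture,
        STUDY_MODE,
        plan,
        null_data,
        feature_params=STUDY_FEATURES,
        model_overrides=_overrides(architecture),
        model_seed=seed,
    )
    return res.pooled_accuracy


def nested_max_vote_study(
    data: CohortData, seeds, architecture: str = "svm"
) -> dict:
    """Max voting vs. its own five inner voters, across fold-plan seeds."""
    max_vote_acc, mean_inner_acc = [], []
    for s in seeds:
        plan = E.make_stratified_folds(data.y, data.sites, k=5, seed=s)
        res = E.run_nested_cv(
            architecture,
            STUDY_MODE,
            plan,
            data,
            feature_params=STUDY_FEATURES,
            model_overrides=_overrides(architecture),
            model_seed=s,
        )
        max_vote_acc.append(res.pooled_accuracy)
        mean_inner_acc.append(float(res.per_inner_model_accuracy.mean()))
    wins = int(sum(mv >= mi for mv, mi in zip(max_vote_acc, mean_inner_acc)))
    return {
        "max_vote_acc": max_vote_acc,
        "mean_inner_acc": mean_inner_acc,
        "wins": wins,
        "n_seeds": len(list(seeds)),
    }


def fcn_saliency_recall(
    data: CohortData,
    truth: S.GroundTruth,
    cv_result: E.CVResult,
    seed: int,
    top_k: int = 50,
    n_noisy: int = 10,
) -> float:
    """Fraction of the FCN's top-k connectivity saliencies that are planted edges.

    Uses the five CV-trained FCN models: every participant's SmoothGrad map
    (from the model of the fold where they were a test sample) is lifted into
    the full feature space; connectivity features are ranked by the cohort-mean
    saliency.
    """
    full_ids = list(data.edge_ids) + list(data.struct_ids)
    cfg = I.SmoothGradConfig(n_noisy=n_noisy, seed=seed)
    total = np.zeros(len(full_ids))
    count = 0
    for fm in cv_result.fold_models:
        rng_range = I._training_range(fm.features, fm.train_idx)
        for node in fm.test_idx:
            c = I.SmoothGradConfig(
                n_noisy=cfg.n_noisy,
                noise_scale=cfg.noise_scale,
                seed=cfg.seed + 1009 * int(node),
            )
            sal = I.smoothgrad(fm.model, fm.features.X[int(node)], c, rng_range)
            total += I.embed_saliency(sal, fm.features.feature_ids, full_ids)
            count += 1
    mean_sal = total / count
    n_edges = len(data.edge_ids)
    top = I.top_features(mean_sal[:n_edges], list(data.edge_ids), k=top_k)
    planted = {data.edge_ids[i] for i in truth.planted_edge_ids}
    return sum(t in planted for t in top) / top_k


def run_full_study(seed: int, architectures=("svm", "fcn", "ae_fcn", "gcn", "ev_gcn")) -> dict:
    """The complete desk-scale experiment; returns plain numbers only."""
    data, truth = study_cohort(seed)
    out: dict = {
        "n": data.n,
        "cv_accuracy": {},
        "cv_auc": {},
    }
    fcn_result = None
    for arch in architectures:
        res = run_cv_study(arch, data, seed, return_models=(arch == "fcn"))
        out["cv_accuracy"][arch] = res.pooled_accuracy
        out["cv_auc"][arch] = res.pooled_auc
        if arch == "fcn":
            fcn_result = res
    out["null_accuracy"] = null_accuracy(data, seed)
    out["nested_svm"] = nested_max_vote_study(data, range(seed, seed + 5))
    if fcn_result is not None:
        out["fcn_top50_recall"] = fcn_saliency_recall(data, truth, fcn_result, seed)
    return out
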