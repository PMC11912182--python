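"""Cross-validated evaluation pipelines.

Two pipelines share one fixed, site-and-label-stratified 5-fold plan:

* **5-fold cross-validation** (individual models, and EMMA across them): per
  fold, one group is the test set, the next group the validation set for
  hyper-parameter tuning, the remaining three train the model.  Pooling the
  per-fold test predictions scores every participant exactly once.
* **5x5 nested cross-validation** (max voting): per outer fold the remaining
  four groups are re-stratified into five inner folds; hyper-parameters are
  chosen by the best *average* inner-validation accuracy, and the five inner
  models then vote on the outer test set (25 trained models per architecture).

Standardization and RFE feature selection are re-fitted on the training rows
of every (inner) split — never on validation or test rows.  Transductive graph
models see all node features and the full population graph, but their loss and
model selection only ever read training/validation-node labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from . import features as F
from . import models as M
from .cohort import CohortData
from .ensembles import max_vote
from .graphs import build_site_graph, scaled_laplacian

__all__ = [
    "FoldPlan",
    "make_stratified_folds",
    "FeatureParams",
    "run_cv",
    "run_nested_cv",
    "accuracy",
    "roc_auc",
    "paired_t_test",
    "chi_squared_best",
    "CVResult",
    "NestedCVResult",
]


# ---------------------------------------------------------------------------
# stratified fold plan
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    fold: np.ndarray  # fold index per sample, 0..k-1
    k: int
    seed: int

    def __post_init__(self):
        if not np.isin(self.fold, np.arange(self.k)).all():
            raise ValueError("every sample must sit in exactly one of the k folds")

    def test_indices(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.fold == f)

    def composition(self, labels, sites):
        """Per-fold (site, label) cell counts — the stratification report."""
        import pandas as pd

        return pd.crosstab(
            [np.asarray(sites), np.asarray(labels)], self.fold
        )


def make_stratified_folds(labels, sites, k: int = 5, seed: int = 0) -> FoldPlan:
    """Deterministic k-fold plan balancing every (site, label) cell within +-1.

    Members of each cell are shuffled by the seed and dealt cyclically over the
    folds ordered by current size (smallest first), so both the per-cell counts
    and the overall fold sizes stay within one of each other.
    """
    labels = np.asarray(labels)
    sites = np.asarray(sites)
    n = labels.size
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    fold = np.full(n, -1, dtype=int)
    sizes = np.zeros(k, dtype=int)
    cells = {}
    for i in range(n):
        cells.setdefault((str(sites[i]), str(labels[i])), []).append(i)
    # larger cells first; key breaks ties deterministically
    for key in sorted(cells, key=lambda c: (-len(cells[c]), c)):
        members = np.array(cells[key])
        rng.shuffle(members)
        order = np.lexsort((np.arange(k), sizes))  # by size, then fold index
        for j, idx in enumerate(members):
            f = order[j % k]
            fold[idx] = f
            sizes[f] += 1
    return FoldPlan(fold=fold, k=k, seed=seed)


# ---------------------------------------------------------------------------
# per-split feature preparation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureParams:
    """Feature-selection settings (full-scale defaults: 4000 fMRI / 800 sMRI)."""

    k_fmri: int = 4000
    k_smri: int = 800
    rfe_step: float = 0.1


@dataclass
class FoldFeatures:
    """Standardized, train-only-selected design matrix for one split."""

    X: np.ndarray  # n_cohort x d (all rows transformed; fit on train rows only)
    feature_ids: list[str]
    modality: list[str]
    masks: dict[str, np.ndarray]  # per-modality selected mask over the raw block


def prepare_fold_features(
    data: CohortData, mode: str, train_idx: np.ndarray, params: FeatureParams
) -> FoldFeatures:
    train_idx = np.asarray(train_idx, dtype=int)
    y_tr = data.y[train_idx]
    parts: dict[str, F.FeatureMatrix] = {}
    masks: dict[str, np.ndarray] = {}

    def block(raw, ids, k, modality):
        std = F.fit_standardizer(raw[train_idx])
        Xs = F.apply_standardizer(std, raw)
        if k is not None and k < raw.shape[1]:
            ranking = F.rfe_rank(Xs[train_idx], y_tr, step=params.rfe_step)
            mask = F.select_top_k(ranking, k)
        else:
            mask = np.ones(raw.shape[1], dtype=bool)
        sel_ids = [fid for fid, m in zip(ids, mask) if m]
        parts[modality] = F.FeatureMatrix(
            values=Xs[:, mask], feature_ids=sel_ids, modality=[modality] * int(mask.sum())
        )
        masks[modality] = mask

    tokens = set(mode.split("+"))
    if "f" in tokens:
        block(data.edge_X, data.edge_ids, params.k_fmri, "fmri")
    if "s" in tokens:
        block(data.struct_X, data.struct_ids, params.k_smri, "smri")
    if "p" in tokens:
        block(data.pheno, list(F.PHENO_FIELDS), None, "pheno")
    fm = F.assemble_feature_set(mode, parts)
    return FoldFeatures(X=fm.values, feature_ids=fm.feature_ids, modality=fm.modality, masks=masks)


# ---------------------------------------------------------------------------
# metrics and statistical comparisons
# ---------------------------------------------------------------------------


def accuracy(preds, labels) -> float:
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must be aligned")
    return float((preds == labels).mean())


def roc_auc(scores, labels) -> float:
    """AUC = P(random positive outranks random negative), ties counting 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired (dependent) t-test on per-fold metrics.

    Identical vectors have an undefined t statistic; by convention the test
    then reports (0.0, 1.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need at least two aligned pairs")
    if np.allclose(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def chi_squared_best(pred_a, pred_b, labels) -> tuple[float, float]:
    """Pearson chi-squared on the 2x2 correct/incorrect table of two models."""
    pred_a, pred_b, labels = (np.asarray(v) for v in (pred_a, pred_b, labels))
    ca = pred_a == labels
    cb = pred_b == labels
    table = np.array(
        [
            [(ca & cb).sum(), (ca & ~cb).sum()],
            [(~ca & cb).sum(), (~ca & ~cb).sum()],
        ]
    )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# 5-fold cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldModel:
    """A trained model plus the split context needed to reuse it later."""

    fold: int
    model: object
    features: FoldFeatures
    test_idx: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray


@dataclass
class CVResult:
    architecture: str
    mode: str
    preds: np.ndarray  # pooled: each sample predicted when its fold was the test fold
    scores: np.ndarray  # pooled autism-class scores
    fold: np.ndarray
    y: np.ndarray
    per_fold_val_acc: list[float]
    per_fold_test_acc: list[float]
    selected: list[dict]
    fold_models: list[FoldModel] = field(default_factory=list)

    @property
    def pooled_accuracy(self) -> float:
        return accuracy(self.preds, self.y)

    @property
    def pooled_auc(self) -> float:
        return roc_auc(self.scores, self.y)


def _split_cv(plan: FoldPlan, f: int):
    test = np.flatnonzero(plan.fold == f)
    val = np.flatnonzero(plan.fold == (f + 1) % plan.k)
    train = np.flatnonzero((plan.fold != f) & (plan.fold != (f + 1) % plan.k))
    if np.intersect1d(train, test).size or np.intersect1d(val, test).size:
        raise RuntimeError("train/validation rows intersect the test fold")
    return train, val, test


def _train_split(
    architecture: str,
    data: CohortData,
    ff: FoldFeatures,
    train: np.ndarray,
    val: np.ndarray,
    spec: M.ModelSpec,
    extra_nodes: dict[str, np.ndarray] | None = None,
):
    """Train one model on a prepared split; returns the fitted classifier."""
    X = ff.X
    if architecture == "svm":
        return M.train_svm(X[train], data.y[train], spec, X[val], data.y[val])
    if architecture in ("fcn", "ae_fcn"):
        trainer = M.train_fcn if architecture == "fcn" else M.train_ae_fcn
        extra = (
            {name: X[idx] for name, idx in extra_nodes.items()} if extra_nodes else None
        )
        return trainer(X[train], data.y[train], spec, X[val], data.y[val], extra_eval=extra)
    masks = {"train": train, "val": val, "test": np.array([], dtype=int)}
    if architecture == "gcn":
        L = scaled_laplacian(build_site_graph(data.sites))
        return M.train_gcn(X, L, data.y, masks, spec, extra_eval=extra_nodes)
    if architecture == "ev_gcn":
        return M.train_ev_gcn(
            X, data.sex_site_onehot(), data.y, masks, spec, extra_eval=extra_nodes
        )
    raise ValueError(f"unknown architecture {architecture!r}")


def _scores_for(architecture: str, model, ff: FoldFeatures, idx: np.ndarray) -> np.ndarray:
    if getattr(model, "is_transductive", False):
        return model.class_scores(idx)
    return model.class_scores(ff.X[idx])


def run_cv(
    architecture: str,
    mode: str,
    plan: FoldPlan,
    data: CohortData,
    feature_params: FeatureParams = FeatureParams(),
    model_overrides: dict | None = None,
    model_seed: int = 0,
    return_models: bool = False,
) -> CVResult:
    """5-fold CV with per-fold train-only feature fitting and validation tuning."""
    n = data.n
    preds = np.full(n, -1, dtype=int)
    scores = np.full(n, np.nan)
    val_accs, test_accs, selected, fold_models = [], [], [], []
    for f in range(plan.k):
        train, val, test = _split_cv(plan, f)
        ff = prepare_fold_features(data, mode, train, feature_params)
        spec = M.default_spec(
            architecture, ff.X.shape[1], seed=model_seed + f, **(model_overrides or {})
        )
        model = _train_split(architecture, data, ff, train, val, spec)
        sc = _scores_for(architecture, model, ff, test)
        preds[test] = sc.argmax(axis=1)
        scores[test] = sc[:, 1]
        val_sc = _scores_for(architecture, model, ff, val)
        val_accs.append(accuracy(val_sc.argmax(axis=1), data.y[val]))
        test_accs.append(accuracy(preds[test], data.y[test]))
        selected.append(dict(model.selected))
        if return_models:
            fold_models.append(
                FoldModel(fold=f, model=model, features=ff, test_idx=test, train_idx=train, val_idx=val)
            )
    if (preds < 0).any():
        raise RuntimeError("pooled predictions do not cover every sample")
    return CVResult(
        architecture=architecture,
        mode=mode,
        preds=preds,
        scores=scores,
        fold=plan.fold.copy(),
        y=data.y.copy(),
        per_fold_val_acc=val_accs,
        per_fold_test_acc=test_accs,
        selected=selected,
        fold_models=fold_models,
    )


# ---------------------------------------------------------------------------
# 5x5 nested cross-validation
# ---------------------------------------------------------------------------


@dataclass
class NestedCVResult:
    architecture: str
    mode: str
    votes: np.ndarray  # 5 x n: inner-model predictions, pooled over outer folds
    vote_scores: np.ndarray  # 5 x n autism-class scores
    preds: np.ndarray  # max-voted pooled predictions
    y: np.ndarray
    fold: np.ndarray
    selected: list[dict]  # per outer fold, the jointly selected hyper-parameter
    inner_model_count: int
    fold_models: list[list[FoldModel]] = field(default_factory=list)

    @property
    def pooled_accuracy(self) -> float:
        return accuracy(self.preds, self.y)

    @property
    def per_inner_model_accuracy(self) -> np.ndarray:
        """Accuracy of each of the 5 inner voters over the pooled test sets."""
        return np.array([accuracy(self.votes[i], self.y) for i in range(self.votes.shape[0])])

    @property
    def pooled_auc(self) -> float:
        return roc_auc(self.vote_scores.mean(axis=0), self.y)


def _nested_dl_fold(architecture, data, ff_list, inner_splits, test, specs):
    """One training run per inner fold; the iteration count is selected jointly
    by the mean inner-validation accuracy over the shared checkpoint grid."""
    histories, mods = [], []
    for (itr, iva), ff, spec in zip(inner_splits, ff_list, specs):
        model = _train_split(
            architecture, data, ff, itr, iva, spec, extra_nodes={"outer_test": test}
        )
        histories.append(model.history)
        mods.append(model)
    grid = histories[0].epochs
    mean_val = [np.mean([h.val_acc[i] for h in histories]) for i in range(len(grid))]
    best_epoch = grid[int(np.argmax(mean_val))]
    test_scores = [h.scores_at("outer_test", best_epoch) for h in histories]
    return {"epochs": best_epoch}, test_scores, mods


def run_nested_cv(
    architecture: str,
    mode: str,
    plan: FoldPlan,
    data: CohortData,
    feature_params: FeatureParams = FeatureParams(),
    model_overrides: dict | None = None,
    model_seed: int = 0,
    return_models: bool = False,
) -> NestedCVResult:
    n = data.n
    votes = np.full((plan.k, n), -1, dtype=int)
    vote_scores = np.full((plan.k, n), np.nan)
    selected, all_models = [], []
    trained = 0
    for f in range(plan.k):
        test = plan.test_indices(f)
        rest = np.flatnonzero(plan.fold != f)
        inner_plan = make_stratified_folds(
            data.y[rest], data.sites[rest], k=plan.k, seed=plan.seed * 31 + f + 1
        )
        inner_splits = []
        for i in range(plan.k):
            iva = rest[inner_plan.fold == i]
            itr = rest[inner_plan.fold != i]
            if np.intersect1d(np.concatenate([itr, iva]), test).size:
                raise RuntimeError("outer-test samples leaked into an inner split")
            inner_splits.append((itr, iva))
        ff_list = [
            prepare_fold_features(data, mode, itr, feature_params) for itr, _ in inner_splits
        ]
        specs = [
            M.default_spec(
                architecture,
                ff.X.shape[1],
                seed=model_seed + f * plan.k + i,
                **(model_overrides or {}),
            )
            for i, ff in enumerate(ff_list)
        ]
        if architecture == "svm":
            sel, test_scores, mods = _nested_svm_grid(
                data, ff_list, inner_splits, test, specs[0]
            )
        else:
            sel, test_scores, mods = _nested_dl_fold(
                architecture, data, ff_list, inner_splits, test, specs
            )
        for i, sc in enumerate(test_scores):
            votes[i, test] = sc.argmax(axis=1)
            vote_scores[i, test] = sc[:, 1]
        selected.append(sel)
        trained += len(mods)
        if return_models:
            all_models.append(
                [
                    FoldModel(fold=f, model=m, features=ff, test_idx=test, train_idx=itr, val_idx=iva)
                    for m, ff, (itr, iva) in zip(mods, ff_list, inner_splits)
                ]
            )
    if (votes < 0).any():
        raise RuntimeError("nested votes do not cover every sample")
    preds = max_vote(votes, vote_scores)
    return NestedCVResult(
        architecture=architecture,
        mode=mode,
        votes=votes,
        vote_scores=vote_scores,
        preds=preds,
        y=data.y.copy(),
        fold=plan.fold.copy(),
        selected=selected,
        inner_model_count=trained,
        fold_models=all_models,
    )


def _nested_svm_grid(data, ff_list, inner_splits, test, spec):
    """Per-C grid with per-inner-split feature refits (25 feature fits total)."""
    y = data.y
    per_C = {}
    for C in spec.C_grid:
        accs, test_scores, fitted = [], [], []
        for (itr, iva), ff in zip(inner_splits, ff_list):
            X = ff.X
            svc = SVC(kernel="rbf", gamma="scale", C=C)
            svc.fit(X[itr], y[itr])
            accs.append(float((svc.predict(X[iva]) == y[iva]).mean()))
            platt = LogisticRegression(C=1e6)
            platt.fit(svc.decision_function(X[itr]).reshape(-1, 1), y[itr])
            cls = M.SVMClassifier(svc, platt, C)
            test_scores.append(cls.class_scores(X[test]))
            fitted.append(cls)
        per_C[C] = (float(np.mean(accs)), test_scores, fitted)
    best_C = max(per_C, key=lambda C: per_C[C][0])
    _, test_scores, fitted = per_C[best_C]
    return {"C": best_C}, test_scores, fitted
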