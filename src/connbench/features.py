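"""Feature construction and strictly train-only selection.

The six feature sets benchmarked here combine three blocks, always concatenated
in the order fMRI, sMRI, phenotypes:

* fMRI — the upper triangle of the Pearson functional-connectivity matrix,
  standardized, then reduced with recursive feature elimination (RFE) under a
  ridge-penalized linear classifier;
* sMRI — regional morphometry (by default 68 cortical regions x 9 measures plus
  115 noncortical regions x 7 measures = 1417 features), standardized and
  RFE-reduced the same way;
* phenotypes — the six non-imaging measures (age, sex, FIQ, NUM, PEC, RAT),
  standardized but never selected.

Standardization and RFE are *fitted on training rows only* and re-fitted inside
every cross-validation split; the leakage-guard tests assert that test rows
cannot influence either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import RidgeClassifier

__all__ = [
    "FeatureMatrix",
    "Standardizer",
    "SelectionRanking",
    "pearson_fc",
    "vectorize_upper",
    "edge_feature_ids",
    "assemble_structural",
    "fit_standardizer",
    "apply_standardizer",
    "rfe_rank",
    "select_top_k",
    "assemble_feature_set",
    "write_selection_tsv",
    "FEATURE_MODES",
    "PHENO_FIELDS",
]

FEATURE_MODES = ("s", "s+p", "f", "f+p", "s+f", "s+f+p")
PHENO_FIELDS = ("age", "sex", "fiq", "num", "pec", "rat")

_SCALE_FLOOR = 1e-12


@dataclass
class FeatureMatrix:
    values: np.ndarray  # samples x features
    feature_ids: list[str]
    modality: list[str]  # "fmri" | "smri" | "pheno" per feature

    def __post_init__(self):
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length must match column count")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")


def pearson_fc(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation between every pair of ROI time-series rows."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("timeseries must be ROI x T with T >= 3")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant (zero-variance) ROI rows: {dead.tolist()}")
    fc = np.corrcoef(ts)
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def edge_feature_ids(n_roi: int) -> list[str]:
    i, j = np.triu_indices(n_roi, k=1)
    return [f"edge({a},{b})" for a, b in zip(i, j)]


def vectorize_upper(fc: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Row-major upper-triangle (i<j) vectorization of a symmetric FC matrix."""
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("fc must be square")
    if np.abs(fc - fc.T).max() > 1e-8:
        raise ValueError("fc is not symmetric within 1e-8")
    n = fc.shape[0]
    return fc[np.triu_indices(n, k=1)], edge_feature_ids(n)


CORTICAL_MEASURES = (
    "num_vertices",
    "surface_area",
    "gray_volume",
    "thickness_avg",
    "thickness_sd",
    "mean_curv",
    "gaussian_curv",
    "folding_index",
    "curv_index",
)
NONCORTICAL_MEASURES = (
    "num_voxels",
    "volume",
    "intensity_mean",
    "intensity_sd",
    "intensity_min",
    "intensity_max",
    "intensity_range",
)


def structural_feature_ids(
    cortical_regions: list[str], noncortical_regions: list[str]
) -> list[str]:
    ids = [f"{r}.{m}" for r in cortical_regions for m in CORTICAL_MEASURES]
    ids += [f"{r}.{m}" for r in noncortical_regions for m in NONCORTICAL_MEASURES]
    return ids


def assemble_structural(cortical, noncortical) -> tuple[np.ndarray, list[str]]:
    """Flatten two region x measure tables into one vector, cortical block first.

    Both arguments are pandas DataFrames indexed by region name with the
    canonical measure columns; row order in the input does not matter because
    regions are sorted by label.
    """
    import pandas as pd

    def block(tab: "pd.DataFrame", measures) -> tuple[np.ndarray, list[str]]:
        missing_cols = [m for m in measures if m not in tab.columns]
        if missing_cols:
            raise ValueError(f"missing measure columns: {missing_cols}")
        tab = tab.loc[sorted(tab.index), list(measures)]
        if tab.isna().any().any():
            bad = sorted(tab.index[tab.isna().any(axis=1)])
            raise ValueError(f"missing cells for regions: {bad}")
        ids = [f"{r}.{m}" for r in tab.index for m in measures]
        return tab.to_numpy(dtype=float).ravel(), ids

    cvec, cids = block(cortical, CORTICAL_MEASURES) if len(cortical) else (np.empty(0), [])
    nvec, nids = (
        block(noncortical, NONCORTICAL_MEASURES) if len(noncortical) else (np.empty(0), [])
    )
    return np.concatenate([cvec, nvec]), cids + nids


@dataclass
class Standardizer:
    """Per-feature location/scale, estimated on training rows only.

    Uses the population (1/n) variance convention.  Degenerate columns have
    their scale floored so they standardize to exactly zero.
    """

    mean: np.ndarray
    scale: np.ndarray


def fit_standardizer(X_train: np.ndarray) -> Standardizer:
    X_train = np.asarray(X_train, dtype=float)
    mean = X_train.mean(axis=0)
    scale = X_train.std(axis=0)  # population SD
    scale = np.where(scale < _SCALE_FLOOR, _SCALE_FLOOR, scale)
    return Standardizer(mean=mean, scale=scale)


def apply_standardizer(s: Standardizer, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    out = (X - s.mean) / s.scale
    # columns at the floor are degenerate: force exact zeros
    return np.where(s.scale <= _SCALE_FLOOR, 0.0, out)


@dataclass
class SelectionRanking:
    """Elimination order from RFE: rank 0 = survives longest."""

    ranks: np.ndarray  # permutation of 0..d-1; smaller = more important

    def __post_init__(self):
        r = np.sort(self.ranks)
        if not np.array_equal(r, np.arange(len(self.ranks))):
            raise ValueError("ranks must be a permutation")


def rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    step: float | int = 0.1,
    alpha: float = 1.0,
) -> SelectionRanking:
    """Recursive feature elimination under a ridge classifier.

    At each iteration a ridge-penalized linear classifier is fitted on the
    surviving features and the ``step`` fraction (of *surviving* features,
    minimum 1) with the smallest |coefficient| is removed.  Ranks record the
    elimination order; within a removed batch, features are ordered by
    |coefficient| so the ranking is a strict permutation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    surviving = np.arange(d)
    ranks = np.empty(d, dtype=int)
    next_rank = d - 1
    while surviving.size > 1:
        clf = RidgeClassifier(alpha=alpha)
        clf.fit(X[:, surviving], y)
        coefs = np.abs(np.ravel(clf.coef_))
        n_drop = int(step) if step >= 1 else max(1, int(np.floor(step * surviving.size)))
        n_drop = min(n_drop, surviving.size - 1)
        drop_local = np.argsort(coefs, kind="stable")[:n_drop]
        # least important first -> gets the largest remaining rank
        for li in drop_local:
            ranks[surviving[li]] = next_rank
            next_rank -= 1
        surviving = np.delete(surviving, np.sort(drop_local))
    ranks[surviving[0]] = 0
    return SelectionRanking(ranks=ranks)


def select_top_k(ranking: SelectionRanking, k: int) -> np.ndarray:
    """Boolean mask of the k last-surviving features."""
    d = len(ranking.ranks)
    if k > d:
        raise ValueError(f"k={k} exceeds the {d} available features")
    return ranking.ranks < k


def write_selection_tsv(ranking: SelectionRanking, feature_ids: list[str], k: int, path) -> None:
    """Export an RFE ranking as TSV: feature_id, rank, selected."""
    import pandas as pd

    mask = select_top_k(ranking, k)
    pd.DataFrame(
        {"feature_id": feature_ids, "rank": ranking.ranks, "selected": mask.astype(int)}
    ).to_csv(path, sep="\t", index=False)


def assemble_feature_set(mode: str, parts: dict[str, FeatureMatrix]) -> FeatureMatrix:
    """Concatenate modality blocks for one of the six feature modes.

    ``parts`` maps modality names ("fmri", "smri", "pheno") to aligned
    FeatureMatrix blocks; blocks are concatenated in the fixed order fMRI,
    sMRI, phenotypes.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {FEATURE_MODES}")
    tokens = set(mode.split("+"))
    alias = {"f": "fmri", "s": "smri", "p": "pheno"}
    # fixed block order regardless of how the mode string is spelled
    order = [alias[t] for t in ("f", "s", "p") if t in tokens]
    missing = [m for m in order if m not in parts]
    if missing:
        raise ValueError(f"mode {mode!r} needs parts {missing}")
    n_rows = {m: parts[m].values.shape[0] for m in order}
    if len(set(n_rows.values())) != 1:
        raise ValueError(f"row mismatch across parts: {n_rows}")
    values = np.concatenate([parts[m].values for m in order], axis=1)
    ids = sum((parts[m].feature_ids for m in order), [])
    modality = sum((parts[m].modality for m in order), [])
    return FeatureMatrix(values=values, feature_ids=ids, modality=modality)
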