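"""SmoothGrad saliency and the saliency-SNR stability analysis.

SmoothGrad averages input gradients over noise-perturbed copies of a
participant's features: with noise SD equal to ``noise_scale`` times the
per-feature training range, the saliency of feature ``j`` is (by default)
``| mean_i  d score_autism / d x_j (x + eps_i) |`` over ``n_noisy`` draws.
The gradient target is the autism-class logit before softmax (softmax
saturation suppresses gradients).  The kernel SVM exposes no input gradient
and is excluded.

Stability is measured across the five same-architecture inner models of one
outer nested-CV fold: per participant, the feature-wise mean, standard
deviation (sample, n-1) and their ratio (SNR) are computed over the five
saliency maps, and the participant's stability score is the mean SNR over
features.  Repeating the nested pipeline (different model seeds, same fold
plan) and averaging per participant yields the per-architecture SNR
histograms used to rank model stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .evaluation import FoldModel

__all__ = [
    "SmoothGradConfig",
    "smoothgrad",
    "participant_snr",
    "stability_histogram",
    "nodal_strength",
    "zscore_map",
    "top_features",
    "group_boxplot_data",
    "saliency_for_fold",
    "embed_saliency",
]

_STD_FLOOR = 1e-12


@dataclass(frozen=True)
class SmoothGradConfig:
    n_noisy: int = 10
    noise_scale: float = 0.1  # fraction of the per-feature training range
    target_class: int = 1  # autism
    magnitude: str = "abs-of-mean"  # or "mean-of-abs"
    seed: int = 0

    def __post_init__(self):
        if self.n_noisy < 1:
            raise ValueError("n_noisy must be at least 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self.magnitude not in ("abs-of-mean", "mean-of-abs"):
            raise ValueError("magnitude must be 'abs-of-mean' or 'mean-of-abs'")


def smoothgrad(
    model,
    x: np.ndarray,
    cfg: SmoothGradConfig,
    feature_range: np.ndarray | float = 1.0,
    node_id: int | None = None,
) -> np.ndarray:
    """Saliency map for one participant.

    For transductive models pass ``node_id`` (the participant's node); noise is
    added to that node's feature row with the population graph held fixed, and
    ``x`` is taken from the model's stored node features.
    """
    if not hasattr(model, "input_gradient"):
        raise TypeError("model does not expose input gradients")
    transductive = getattr(model, "is_transductive", False)
    if transductive:
        if node_id is None:
            raise ValueError("transductive models need the participant's node_id")
        x = model.X_all[int(node_id)]
    x = np.asarray(x, dtype=float).ravel()
    sd = cfg.noise_scale * np.broadcast_to(np.asarray(feature_range, dtype=float), x.shape)
    rng = np.random.default_rng(cfg.seed)
    grads = np.zeros((cfg.n_noisy, x.size))
    for i in range(cfg.n_noisy):
        noisy = x + rng.normal(0.0, 1.0, size=x.size) * sd
        if transductive:
            grads[i] = model.input_gradient(node_id, cfg.target_class, row_override=noisy)
        else:
            grads[i] = model.input_gradient(noisy, cfg.target_class)
    if cfg.magnitude == "abs-of-mean":
        return np.abs(grads.mean(axis=0))
    return np.abs(grads).mean(axis=0)


@dataclass
class ParticipantSNR:
    value: float  # mean over features of per-feature mean/std
    n_zero_std: int  # features whose std hit the floor (flagged, still included)
    n_features: int


def participant_snr(maps: np.ndarray) -> ParticipantSNR:
    """Average saliency SNR of one participant across repeat-trained models.

    ``maps`` is an m x d stack (m >= 2 saliency maps from the same outer fold's
    inner models).  Per feature, SNR = mean / sample std (n-1 denominator);
    standard deviations below 1e-12 are floored there and flagged.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need at least two saliency maps")
    mean = maps.mean(axis=0)
    std = maps.std(axis=0, ddof=1)
    flagged = std < _STD_FLOOR
    snr = mean / np.where(flagged, _STD_FLOOR, std)
    return ParticipantSNR(
        value=float(snr.mean()), n_zero_std=int(flagged.sum()), n_features=maps.shape[1]
    )


@dataclass
class StabilityReport:
    participant_ids: list[str]
    snr_per_repeat: np.ndarray  # n_participants x n_repeats
    mean_snr: np.ndarray  # averaged over repeats
    bin_edges: np.ndarray
    histogram: np.ndarray

    @property
    def median_snr(self) -> float:
        return float(np.median(self.mean_snr))


def stability_histogram(
    participant_ids: list[str],
    snr_per_repeat: np.ndarray,
    bins: int = 20,
    bin_range: tuple[float, float] | None = None,
) -> StabilityReport:
    """Average per-participant SNR over repeats and bin it for comparison."""
    snr = np.atleast_2d(np.asarray(snr_per_repeat, dtype=float))
    if snr.shape[0] != len(participant_ids):
        raise ValueError("one SNR row per participant required")
    if np.isnan(snr).any():
        raise ValueError("missing repeat values")
    mean_snr = snr.mean(axis=1)
    hist, edges = np.histogram(mean_snr, bins=bins, range=bin_range)
    return StabilityReport(
        participant_ids=list(participant_ids),
        snr_per_repeat=snr,
        mean_snr=mean_snr,
        bin_edges=edges,
        histogram=hist,
    )


def nodal_strength(edge_saliency: np.ndarray, edge_ids: list[str], n_regions: int) -> np.ndarray:
    """Sum each connection's saliency onto both incident regions."""
    strength = np.zeros(n_regions)
    for val, eid in zip(np.asarray(edge_saliency, dtype=float), edge_ids):
        i, j = _parse_edge_id(eid)
        if i >= n_regions or j >= n_regions:
            raise ValueError(f"edge {eid} references an unknown region")
        strength[i] += val
        strength[j] += val
    return strength


def _parse_edge_id(eid: str) -> tuple[int, int]:
    inner = eid[eid.index("(") + 1 : eid.index(")")]
    i, j = inner.split(",")
    return int(i), int(j)


def zscore_map(scores: np.ndarray) -> np.ndarray:
    """Z-score normalization with a floored scale (constant input -> zeros)."""
    scores = np.asarray(scores, dtype=float)
    sd = scores.std()
    if sd < _STD_FLOOR:
        return np.zeros_like(scores)
    return (scores - scores.mean()) / sd


def top_features(mean_saliency: np.ndarray, feature_ids: list[str], k: int = 100) -> list[str]:
    """The k features with the largest mean saliency, ties broken by id."""
    if k > len(feature_ids):
        raise ValueError("k exceeds the feature count")
    order = sorted(
        range(len(feature_ids)), key=lambda i: (-float(mean_saliency[i]), feature_ids[i])
    )
    return [feature_ids[i] for i in order[:k]]


@dataclass
class GroupSummary:
    group_sizes: dict[str, int]
    quartiles: dict[str, np.ndarray]  # group -> n_features x 3 (Q1, median, Q3)
    p_tp_vs_tn: np.ndarray | None  # per-feature Welch-t p-value, or None if skipped
    skipped: bool


def group_boxplot_data(predictions, labels, feature_values) -> GroupSummary:
    """TP/TN/FP/FN feature summaries with a TP-vs-TN two-sample test.

    Autism is the positive class: TP = correctly classified autism, TN =
    correctly classified TD, FP = TD classified autism, FN = autism classified
    TD.  If either the TP or TN group is empty the test is skipped and flagged.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    X = np.atleast_2d(np.asarray(feature_values, dtype=float))
    if X.shape[0] != labels.size:
        X = X.T
    groups = {
        "TP": (predictions == 1) & (labels == 1),
        "TN": (predictions == 0) & (labels == 0),
        "FP": (predictions == 1) & (labels == 0),
        "FN": (predictions == 0) & (labels == 1),
    }
    sizes = {g: int(m.sum()) for g, m in groups.items()}
    quart = {
        g: (
            np.percentile(X[m], [25, 50, 75], axis=0).T
            if sizes[g]
            else np.full((X.shape[1], 3), np.nan)
        )
        for g, m in groups.items()
    }
    if sizes["TP"] < 2 or sizes["TN"] < 2:
        return GroupSummary(group_sizes=sizes, quartiles=quart, p_tp_vs_tn=None, skipped=True)
    _, p = stats.ttest_ind(X[groups["TP"]], X[groups["TN"]], equal_var=False)
    return GroupSummary(
        group_sizes=sizes, quartiles=quart, p_tp_vs_tn=np.atleast_1d(p), skipped=False
    )


# ---------------------------------------------------------------------------
# orchestration over trained fold models
# ---------------------------------------------------------------------------


def embed_saliency(saliency: np.ndarray, feature_ids: list[str], full_ids: list[str]) -> np.ndarray:
    """Lift a selected-feature-space map into a full feature space (zeros elsewhere)."""
    pos = {fid: i for i, fid in enumerate(full_ids)}
    out = np.zeros(len(full_ids))
    for val, fid in zip(saliency, feature_ids):
        out[pos[fid]] = val
    return out


def _training_range(ff, train_idx) -> np.ndarray:
    Xtr = ff.X[np.asarray(train_idx, dtype=int)]
    return Xtr.max(axis=0) - Xtr.min(axis=0)


def saliency_for_fold(
    fold_models: list[FoldModel],
    full_ids: list[str],
    cfg: SmoothGradConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant SNR and stacked mean saliency for one outer fold.

    ``fold_models`` are the (>= 2, typically 5) inner models of one outer fold;
    every outer-test participant gets one saliency map per inner model, lifted
    into the shared feature space.  Returns ``(snr_values, mean_saliency)``
    where ``snr_values`` aligns with the fold's test indices and
    ``mean_saliency`` is (n_test x n_full_features), averaged over inner models.
    """
    test = fold_models[0].test_idx
    n_models = len(fold_models)
    stacks = np.zeros((len(test), n_models, len(full_ids)))
    for mi, fm in enumerate(fold_models):
        rng_range = _training_range(fm.features, fm.train_idx)
        for ti, node in enumerate(test):
            c = SmoothGradConfig(
                n_noisy=cfg.n_noisy,
                noise_scale=cfg.noise_scale,
                target_class=cfg.target_class,
                magnitude=cfg.magnitude,
                seed=cfg.seed + 1009 * int(node) + mi,
            )
            if getattr(fm.model, "is_transductive", False):
                sal = smoothgrad(fm.model, None, c, rng_range, node_id=int(node))
            else:
                sal = smoothgrad(fm.model, fm.features.X[int(node)], c, rng_range)
            stacks[ti, mi] = embed_saliency(sal, fm.features.feature_ids, full_ids)
    snr = np.array([participant_snr(stacks[ti]).value for ti in range(len(test))])
    return snr, stacks.mean(axis=1)
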