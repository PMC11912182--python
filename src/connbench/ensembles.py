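"""Majority-vote ensembling.

Two schemes are supported: *max voting* over the five same-architecture models
produced by the inner loop of nested cross-validation, and *EMMA* (ensembles
of multiple models and architectures) — a majority vote across the five
architectures' pooled cross-validated predictions.  With an even number of
voters, ties are broken by the mean autism-class score, falling back to TD on
an exact score tie.
"""

from __future__ import annotations

import numpy as np

__all__ = ["max_vote", "emma_vote", "write_votes_tsv", "read_votes_tsv"]


def write_votes_tsv(votes: np.ndarray, sample_ids, voter_ids, path) -> None:
    """Vote matrix (m voters x n samples) as TSV, one row per sample."""
    import pandas as pd

    votes = np.asarray(votes, dtype=int)
    df = pd.DataFrame(votes.T, columns=list(voter_ids))
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, sep="\t", index=False)


def read_votes_tsv(path) -> tuple[np.ndarray, list, list]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    sample_ids = df["sample_id"].tolist()
    voters = [c for c in df.columns if c != "sample_id"]
    return df[voters].to_numpy(dtype=int).T, sample_ids, voters


def max_vote(votes: np.ndarray, scores: np.ndarray | None = None) -> np.ndarray:
    """Per-sample modal label over an m x n binary vote matrix.

    ``scores`` (m x n autism-class scores) resolves even splits: a tied sample
    is labelled autism when the mean autism score exceeds 0.5, TD otherwise.
    """
    votes = np.asarray(votes, dtype=int)
    if votes.ndim != 2 or votes.shape[0] < 1:
        raise ValueError("votes must be a non-empty m x n matrix")
    pos = votes.sum(axis=0)
    m = votes.shape[0]
    out = (2 * pos > m).astype(int)
    tied = 2 * pos == m
    if tied.any():
        if scores is None:
            out[tied] = 0  # deterministic fallback: TD
        else:
            mean_pos = np.asarray(scores, dtype=float).mean(axis=0)
            out[tied] = (mean_pos[tied] > 0.5).astype(int)
    return out


def emma_vote(per_architecture_predictions: dict[str, np.ndarray]) -> np.ndarray:
    """Majority vote across architectures (one prediction per sample each).

    With the five benchmark architectures and two classes no tie is possible;
    fewer (even) voters fall back to the TD tie rule of :func:`max_vote`.
    """
    if not per_architecture_predictions:
        raise ValueError("no architecture predictions supplied")
    rows = []
    n = None
    for arch, preds in sorted(per_architecture_predictions.items()):
        preds = np.asarray(preds, dtype=int)
        if preds.ndim != 1:
            raise ValueError(f"predictions for {arch!r} must be one per sample")
        if n is None:
            n = preds.size
        elif preds.size != n:
            raise ValueError(f"prediction length mismatch for {arch!r}")
        rows.append(preds)
    return max_vote(np.vstack(rows))
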