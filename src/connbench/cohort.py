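"""In-memory design data for a cohort: aligned feature blocks plus metadata."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import features as F
from .synthdata import ParticipantRecord

__all__ = ["CohortData"]

LABELS = ("td", "autism")  # class 1 = autism (the positive class)


@dataclass
class CohortData:
    """Aligned per-participant arrays consumed by the evaluation pipelines."""

    ids: list[str]
    y: np.ndarray  # 0 = TD, 1 = autism
    sites: np.ndarray  # site id per participant
    pheno: np.ndarray  # n x 6: age, sex(0/1), fiq, num, pec, rat
    edge_X: np.ndarray  # n x n_edges upper-triangle FC values
    edge_ids: list[str]
    struct_X: np.ndarray  # n x n_struct
    struct_ids: list[str]

    def __post_init__(self):
        n = len(self.ids)
        for name in ("y", "sites", "pheno", "edge_X", "struct_X"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} is not aligned with ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(
        cls, records: list[ParticipantRecord], struct_ids: list[str] | None = None
    ) -> "CohortData":
        if not records:
            raise ValueError("empty cohort")
        edge_rows, edge_ids = [], None
        for r in records:
            fc = r.fc if r.fc is not None else F.pearson_fc(r.timeseries)
            vec, ids = F.vectorize_upper(fc)
            edge_rows.append(vec)
            if edge_ids is None:
                edge_ids = ids
        pheno = np.array(
            [
                [r.age, 1.0 if r.sex == "M" else 0.0, r.fiq, r.num, r.pec, r.rat]
                for r in records
            ]
        )
        struct_X = np.vstack([r.struct_vec for r in records])
        if struct_ids is None:
            struct_ids = [f"struct_{i}" for i in range(struct_X.shape[1])]
        return cls(
            ids=[r.id for r in records],
            y=np.array([1 if r.label == "autism" else 0 for r in records]),
            sites=np.array([r.site for r in records]),
            pheno=pheno,
            edge_X=np.vstack(edge_rows),
            edge_ids=edge_ids,
            struct_X=struct_X,
            struct_ids=list(struct_ids),
        )

    def site_onehot(self) -> np.ndarray:
        cats = sorted(set(self.sites.tolist()))
        return (self.sites[:, None] == np.array(cats)[None, :]).astype(float)

    def sex_site_onehot(self) -> np.ndarray:
        """[sex one-hot | site one-hot] encoding used by the PAE graph."""
        sex = self.pheno[:, 1]
        sex_oh = np.column_stack([sex, 1.0 - sex])
        return np.concatenate([sex_oh, self.site_onehot()], axis=1)
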