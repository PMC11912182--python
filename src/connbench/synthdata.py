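"""Synthetic multi-site case/control cohort generation.

Real multi-site autism cohorts (ABIDE-style) combine per-participant functional
connectivity (Pearson correlations between regional BOLD time-series),
FreeSurfer-style regional morphometry, and a handful of phenotypes, with strong
between-site heterogeneity.  This module generates cohorts with that
statistical structure and returns the planted ground truth so that feature
selection, classification and saliency analyses can be scored for recovery:

* a small set of "informative" connectivity edges differs between the autism
  and TD classes by a configurable standardized mean difference ``d``; the
  class shift is applied in Fisher-z space and mapped back through tanh so
  correlations stay in (-1, 1);
* likewise a set of informative structural features;
* every site adds its own per-feature offset (drawn once per site with scale
  ``site_shift_sd``) to both modalities, emulating scanner/protocol effects;
* phenotypes (age, sex, FIQ, motion-outlier counts, anatomical quality) are
  drawn per site, independent of the class label by default.

The default 20-site layout reproduces the published composition of the ABIDE I
subsample widely used for benchmarking (870 participants, 403 autism / 467 TD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenerationConfig",
    "GroundTruth",
    "ParticipantRecord",
    "abide_like_site_table",
    "generate_cohort",
    "generate_timeseries",
]

# (site, N, mean age, males, females, autism, TD) — 20-site reference cohort.
_SITE_ROWS = [
    ("PITT", 50, 18.50, 43, 7, 24, 26),
    ("OLIN", 28, 17.04, 23, 5, 14, 14),
    ("OHSU", 25, 10.81, 25, 0, 12, 13),
    ("NYU", 172, 15.33, 136, 36, 74, 98),
    ("SBL", 26, 33.77, 26, 0, 12, 14),
    ("SDSU", 27, 14.36, 21, 6, 8, 19),
    ("STANFORD", 25, 9.99, 18, 7, 12, 13),
    ("TRINITY", 44, 17.03, 44, 0, 19, 25),
    ("UCLA_2", 21, 12.47, 19, 2, 11, 10),
    ("UM_1", 86, 13.77, 61, 25, 34, 52),
    ("UM_2", 34, 16.01, 32, 2, 13, 21),
    ("USM", 67, 22.59, 67, 0, 43, 24),
    ("YALE", 41, 13.31, 25, 16, 22, 19),
    ("CALTECH", 15, 26.79, 10, 5, 5, 10),
    ("CMU", 11, 26.82, 7, 4, 6, 5),
    ("KKI", 33, 10.31, 24, 9, 12, 21),
    ("LEUVEN_1", 28, 22.43, 28, 0, 14, 14),
    ("LEUVEN_2", 28, 14.17, 21, 7, 12, 16),
    ("MAX_MUN", 45, 26.49, 41, 4, 19, 26),
    ("UCLA_1", 64, 13.35, 55, 9, 37, 27),
]

SITE_MEAN_AGE = {r[0]: r[2] for r in _SITE_ROWS}
SITE_MALE_FRACTION = {r[0]: r[3] / r[1] for r in _SITE_ROWS}


def abide_like_site_table(scale: float = 1.0) -> list[tuple[str, int, int]]:
    """Per-site (site_id, n_autism, n_td) counts of the 20-site reference cohort.

    ``scale`` < 1 shrinks every cell by flooring ``scale * count``, keeping at
    least one participant in every cell that is non-empty at full scale.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")

    def cell(c: int) -> int:
        return 0 if c == 0 else max(1, int(c * scale))

    return [(site, cell(aut), cell(n - aut)) for site, n, _, _, _, aut, _ in _SITE_ROWS]


@dataclass(frozen=True)
class GenerationConfig:
    """Knobs of the cohort generator; defaults emulate a full 20-site cohort."""

    n_rois: int = 200
    n_timepoints: int = 150
    site_table: list[tuple[str, int, int]] = field(default_factory=abide_like_site_table)
    n_informative_edges: int = 50
    n_informative_struct: int = 20
    effect_size_d: float = 1.0
    site_shift_sd: float = 0.2
    noise_sd: float = 0.3
    n_cortical: int = 68
    n_noncortical: int = 115
    pheno_label_leak: float = 0.0  # optional label effect on NUM/PEC/RAT for ablations
    with_timeseries: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_rois < 2 or self.n_timepoints < 2:
            raise ValueError("n_rois and n_timepoints must each be at least 2")
        if self.effect_size_d < 0:
            raise ValueError("effect_size_d must be nonnegative")
        if not self.site_table:
            raise ValueError("site_table must be non-empty")
        for site, a, t in self.site_table:
            if a < 0 or t < 0 or a + t == 0:
                raise ValueError(f"site {site!r} must have a positive member count")
        n_edges = self.n_rois * (self.n_rois - 1) // 2
        if self.n_informative_edges > n_edges:
            raise ValueError("n_informative_edges exceeds the edge space")
        if self.n_informative_struct > self.n_struct:
            raise ValueError("n_informative_struct exceeds the structural space")

    @property
    def n_struct(self) -> int:
        return self.n_cortical * 9 + self.n_noncortical * 7


@dataclass
class GroundTruth:
    """Planted signal locations and the per-site offsets actually used."""

    planted_edge_ids: np.ndarray
    planted_struct_ids: np.ndarray
    per_site_edge_offsets: dict[str, np.ndarray]
    per_site_struct_offsets: dict[str, np.ndarray]
    effect_size_d: float


@dataclass
class ParticipantRecord:
    id: str
    site: str
    label: str  # "autism" | "td"
    age: float
    sex: str  # "M" | "F"
    fiq: float
    num: int
    pec: float
    rat: float
    struct_vec: np.ndarray
    fc: np.ndarray | None = None
    timeseries: np.ndarray | None = None

    def __post_init__(self):
        if self.fc is None and self.timeseries is None:
            raise ValueError("a participant needs a time-series or an FC matrix")


def _upper_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def generate_cohort(cfg: GenerationConfig) -> tuple[list[ParticipantRecord], GroundTruth]:
    """Draw a full multi-site cohort plus its ground truth.

    Connectivity is generated directly in Fisher-z edge space:
    ``z = template + site_offset + class_shift + noise`` and mapped through
    tanh, giving symmetric unit-diagonal matrices.  The class shift on planted
    edges equals ``d * sqrt(noise_sd^2 + site_shift_sd^2)`` so the pooled
    within-class standardized mean difference is approximately ``d``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_edges = cfg.n_rois * (cfg.n_rois - 1) // 2
    iu = _upper_indices(cfg.n_rois)

    planted_edges = np.sort(
        rng.choice(n_edges, size=cfg.n_informative_edges, replace=False)
    )
    planted_struct = np.sort(
        rng.choice(cfg.n_struct, size=cfg.n_informative_struct, replace=False)
    )

    # population templates
    edge_template = rng.normal(0.0, 0.25, size=n_edges)  # Fisher-z scale
    struct_template = rng.normal(0.0, 1.0, size=cfg.n_struct)

    within_sd = float(np.hypot(cfg.noise_sd, cfg.site_shift_sd))
    delta = cfg.effect_size_d * within_sd

    edge_offsets: dict[str, np.ndarray] = {}
    struct_offsets: dict[str, np.ndarray] = {}
    records: list[ParticipantRecord] = []
    uid = 0
    for site, n_aut, n_td in cfg.site_table:
        edge_offsets[site] = rng.normal(0.0, cfg.site_shift_sd, size=n_edges)
        struct_offsets[site] = rng.normal(0.0, cfg.site_shift_sd, size=cfg.n_struct)
        mean_age = SITE_MEAN_AGE.get(site, 16.0)
        p_male = SITE_MALE_FRACTION.get(site, 0.8)
        for label, count in (("autism", n_aut), ("td", n_td)):
            sign = 0.5 if label == "autism" else -0.5
            for _ in range(count):
                z = edge_template + edge_offsets[site] + rng.normal(
                    0.0, cfg.noise_sd, size=n_edges
                )
                z[planted_edges] += sign * delta
                fc = np.eye(cfg.n_rois)
                fc[iu] = np.tanh(z)
                fc[(iu[1], iu[0])] = fc[iu]

                sv = struct_template + struct_offsets[site] + rng.normal(
                    0.0, cfg.noise_sd, size=cfg.n_struct
                )
                sv[planted_struct] += sign * delta

                num = int(rng.poisson(5 + cfg.pheno_label_leak * (sign + 0.5) * 5))
                rec = ParticipantRecord(
                    id=f"sub-{uid:04d}",
                    site=site,
                    label=label,
                    age=float(max(6.0, rng.normal(mean_age, 3.0))),
                    sex="M" if rng.random() < p_male else "F",
                    fiq=float(rng.normal(108.0, 14.0)),
                    num=num,
                    pec=float(100.0 * num / cfg.n_timepoints),
                    rat=float(np.clip(rng.normal(0.85, 0.1), 0.0, 1.0)),
                    struct_vec=sv,
                    fc=fc,
                )
                if cfg.with_timeseries:
                    rec.timeseries = generate_timeseries(
                        fc, cfg.n_timepoints, seed=int(rng.integers(2**31))
                    )
                records.append(rec)
                uid += 1

    truth = GroundTruth(
        planted_edge_ids=planted_edges,
        planted_struct_ids=planted_struct,
        per_site_edge_offsets=edge_offsets,
        per_site_struct_offsets=struct_offsets,
        effect_size_d=cfg.effect_size_d,
    )
    return records, truth


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def generate_timeseries(target_corr: np.ndarray, T: int, seed: int = 0) -> np.ndarray:
    """Sample an ROI x T Gaussian time-series whose correlation targets ``target_corr``.

    Non-positive-semidefinite targets (which tanh-mapped synthetic matrices can
    be) are projected to the nearest PSD matrix with a warning.
    """
    target_corr = np.asarray(target_corr, dtype=float)
    if target_corr.ndim != 2 or target_corr.shape[0] != target_corr.shape[1]:
        raise ValueError("target_corr must be square")
    vals = np.linalg.eigvalsh(target_corr)
    if vals.min() < -1e-10:
        warnings.warn("target correlation not PSD; projecting to nearest PSD matrix")
        target_corr = _nearest_psd(target_corr)
    # Cholesky-like factor via eigendecomposition (robust to exact zeros)
    vals, vecs = np.linalg.eigh(target_corr)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(seed)
    return factor @ rng.standard_normal((target_corr.shape[0], T))
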