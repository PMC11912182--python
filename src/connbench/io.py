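"""Delimited-text readers/writers for cohorts and results.

On-disk layout of a cohort directory (all comma-separated, UTF-8, header row,
'.' decimal — the dialect of common phenotype distributions):

* ``phenotypes.csv`` — one row per participant: id, site, label, age, sex,
  fiq, num, pec, rat;
* ``connectivity/<id>.csv`` — one square correlation matrix per participant
  (filename = participant id);
* ``structural.csv`` — one row per participant: id plus one column per
  region.measure structural feature;
* ``ground_truth.json`` — planted feature indices (synthetic cohorts only).

Synthetic and real data flow through the same readers; a writer -> reader
round trip is bit-identical because floats are serialized with ``repr``
round-trip precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import GroundTruth, ParticipantRecord

__all__ = [
    "write_cohort",
    "read_phenotypes",
    "read_connectivity",
    "read_structural",
    "load_cohort",
    "write_json",
    "read_json",
]

PHENO_COLUMNS = ["id", "site", "label", "age", "sex", "fiq", "num", "pec", "rat"]


def write_cohort(
    records: list[ParticipantRecord],
    outdir: str | Path,
    truth: GroundTruth | None = None,
    struct_ids: list[str] | None = None,
) -> Path:
    outdir = Path(outdir)
    (outdir / "connectivity").mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "id": r.id,
            "site": r.site,
            "label": r.label,
            "age": r.age,
            "sex": r.sex,
            "fiq": r.fiq,
            "num": r.num,
            "pec": r.pec,
            "rat": r.rat,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PHENO_COLUMNS).to_csv(
        outdir / "phenotypes.csv", index=False, float_format="%.17g"
    )
    for r in records:
        mat = r.fc if r.fc is not None else None
        if mat is None:
            raise ValueError(f"record {r.id} has no FC matrix to write")
        # %.17g guarantees float64 round-trip through text
        np.savetxt(outdir / "connectivity" / f"{r.id}.csv", mat, delimiter=",", fmt="%.17g")
    d = records[0].struct_vec.size
    if struct_ids is None:
        struct_ids = [f"struct_{i}" for i in range(d)]
    sdf = pd.DataFrame([r.struct_vec for r in records], columns=struct_ids)
    sdf.insert(0, "id", [r.id for r in records])
    sdf.to_csv(outdir / "structural.csv", index=False, float_format="%.17g")
    if truth is not None:
        write_json(
            outdir / "ground_truth.json",
            {
                "planted_edge_ids": truth.planted_edge_ids.tolist(),
                "planted_struct_ids": truth.planted_struct_ids.tolist(),
                "effect_size_d": truth.effect_size_d,
            },
        )
    return outdir


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate participant ids: {dup}")
    for col in ("age", "fiq", "num", "pec", "rat"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise ValueError(f"non-numeric or non-finite values in column {col!r}")
    return df


def read_connectivity(directory: str | Path, ids: list[str]) -> dict[str, np.ndarray]:
    directory = Path(directory)
    out = {}
    missing = []
    for pid in ids:
        f = directory / f"{pid}.csv"
        if not f.exists():
            missing.append(pid)
            continue
        mat = np.loadtxt(f, delimiter=",", ndmin=2)
        if mat.shape[0] != mat.shape[1]:
            raise ValueError(f"connectivity matrix for {pid} is not square")
        if np.abs(mat - mat.T).max() > 1e-8:
            raise ValueError(f"connectivity matrix for {pid} is asymmetric")
        out[pid] = mat
    if missing:
        raise FileNotFoundError(f"connectivity matrices missing for ids: {missing}")
    return out


def read_structural(path: str | Path, ids: list[str]) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, float_precision="round_trip")
    if "id" not in df.columns:
        raise ValueError("structural file needs an 'id' column")
    df = df.set_index("id")
    missing = [pid for pid in ids if pid not in df.index]
    if missing:
        raise ValueError(f"structural rows missing for ids: {missing}")
    df = df.loc[ids]
    return df.to_numpy(dtype=float), list(df.columns)


def load_cohort(directory: str | Path):
    """Read a cohort directory back into ParticipantRecords (+ truth if stored).

    Row order follows the phenotype file.
    """
    directory = Path(directory)
    pheno = read_phenotypes(directory / "phenotypes.csv")
    ids = pheno["id"].astype(str).tolist()
    fcs = read_connectivity(directory / "connectivity", ids)
    struct_X, struct_ids = read_structural(directory / "structural.csv", ids)
    records = []
    for i, row in pheno.iterrows():
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                site=str(row["site"]),
                label=str(row["label"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                fiq=float(row["fiq"]),
                num=int(row["num"]),
                pec=float(row["pec"]),
                rat=float(row["rat"]),
                struct_vec=struct_X[i],
                fc=fcs[str(row["id"])],
            )
        )
    truth_file = directory / "ground_truth.json"
    truth = read_json(truth_file) if truth_file.exists() else None
    return records, struct_ids, truth


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=default))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
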