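"""Reading and writing the package's plain-text formats.

Association matrices travel as edge-list TSV (columns ``mirna_id``,
``disease_id``, ``label``; a positives-only file omits the zeros), similarity
matrices as dense labeled CSV (identifier index and header), and reports as
JSON / per-fold CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .similarity import AssociationMatrix, SimilarityMatrix
from .synthetic import SyntheticDataset

__all__ = [
    "write_association_tsv",
    "read_association_tsv",
    "write_similarity_csv",
    "read_similarity_csv",
    "write_dataset",
    "read_dataset",
    "write_cv_report",
    "write_ranking_tsv",
]


def write_association_tsv(assoc: AssociationMatrix, path: str | Path,
                          positives_only: bool = False) -> None:
    rows = []
    for i, mid in enumerate(assoc.mirna_ids):
        for j, did in enumerate(assoc.disease_ids):
            label = int(assoc.values[i, j])
            if positives_only and label == 0:
                continue
            rows.append((mid, did, label))
    pd.DataFrame(rows, columns=["mirna_id", "disease_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_association_tsv(path: str | Path,
                         mirna_ids: list[str] | None = None,
                         disease_ids: list[str] | None = None) -> AssociationMatrix:
    """Read an edge-list TSV.

    A positives-only file needs `mirna_ids`/`disease_ids` to fix the grid;
    a dense file infers them from the rows (sorted order of appearance).
    """
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "disease_id": str})
    required = {"mirna_id", "disease_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"association TSV must have columns {sorted(required)}")
    mirna_ids = mirna_ids or list(dict.fromkeys(df["mirna_id"]))
    disease_ids = disease_ids or list(dict.fromkeys(df["disease_id"]))
    m_index = {m: i for i, m in enumerate(mirna_ids)}
    d_index = {d: j for j, d in enumerate(disease_ids)}
    values = np.zeros((len(mirna_ids), len(disease_ids)))
    for mid, did, label in df.itertuples(index=False):
        values[m_index[mid], d_index[did]] = float(label)
    return AssociationMatrix(values, mirna_ids, disease_ids)


def write_similarity_csv(view: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(view.values, index=view.ids, columns=view.ids).to_csv(path)


def read_similarity_csv(path: str | Path, view_name: str) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column identifiers differ")
    return SimilarityMatrix(df.to_numpy(dtype=float), list(df.index), view_name)


_VIEW_FILES = {
    "mirna": ("functional", "sequence"),
    "disease": ("semantic", "target"),
}


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_association_tsv(dataset.associations, out / "associations.tsv")
    for side, names in _VIEW_FILES.items():
        views = dataset.mirna_views if side == "mirna" else dataset.disease_views
        for name in names:
            write_similarity_csv(views[name], out / f"{side}_{name}.csv")


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    The planted truth is not serialized; the returned dataset has
    ``truth=None``.
    """
    src = Path(in_dir)
    assoc = read_association_tsv(src / "associations.tsv")
    mirna_views = {
        name: read_similarity_csv(src / f"mirna_{name}.csv", name)
        for name in _VIEW_FILES["mirna"]
    }
    disease_views = {
        name: read_similarity_csv(src / f"disease_{name}.csv", name)
        for name in _VIEW_FILES["disease"]
    }
    return SyntheticDataset(assoc, mirna_views, disease_views, truth=None)


def write_cv_report(report, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "metrics.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    rows = [dict(fold=i, **f.as_dict()) for i, f in enumerate(report.folds)]
    pd.DataFrame(rows).to_csv(out / "folds.csv", index=False)


def write_ranking_tsv(ranking: list[dict], path: str | Path) -> None:
    df = pd.DataFrame(ranking, columns=["rank", "mirna_id", "score", "known"])
    df = df.rename(columns={"known": "known_flag"})
    df.to_csv(path, sep="\t", index=False)
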