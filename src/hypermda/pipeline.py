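"""End-to-end training: folds, cross-validation, ablations, candidate ranking.

Positives (known associations) are shuffled and partitioned into k folds;
negatives are drawn uniformly without replacement from the zero cells,
disjointly between train and test within each fold at a configurable
negative:positive ratio (1:1 by default).  Within every fold the GIP views
are recomputed from the association matrix with that fold's test positives
zeroed, so no training-side computation ever sees a test label.

One global seed fans out, via named seed sequences, to fold assignment,
negative sampling, parameter initialization and dropout, making a full
cross-validation run bit-reproducible.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig
from .losses import EvaluationReport, compute_metrics
from .model import AssociationModel
from .similarity import AssociationMatrix, SimilarityMatrix, assemble_views
from .synthetic import SyntheticDataset

__all__ = [
    "FoldSplit",
    "TrainedModel",
    "CVReport",
    "make_folds",
    "train_fold",
    "cross_validate",
    "rank_candidates",
    "shuffle_associations",
]

Pair = tuple[str, str, int]  # (mirna_id, disease_id, label)


@dataclass
class FoldSplit:
    fold_index: int
    train_pairs: list[Pair]
    test_pairs: list[Pair]
    seed: int


@dataclass
class TrainedModel:
    """A fitted model plus everything needed to score new pairs."""

    model: AssociationModel
    config: ModelConfig
    known_positives: set[tuple[str, str]]
    loss_history: list[float] = field(default_factory=list)

    @property
    def mirna_ids(self) -> list[str]:
        return self.model.mirna_ids

    @property
    def disease_ids(self) -> list[str]:
        return self.model.disease_ids

    def score(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        m_index = {name: i for i, name in enumerate(self.mirna_ids)}
        d_index = {name: j for j, name in enumerate(self.disease_ids)}
        for mid, did in pairs:
            if mid not in m_index:
                raise KeyError(f"unknown miRNA identifier {mid!r}")
            if did not in d_index:
                raise KeyError(f"unknown disease identifier {did!r}")
        mi = [m_index[m] for m, _ in pairs]
        di = [d_index[d] for _, d in pairs]
        return self.model.predict(mi, di)


@dataclass
class CVReport:
    folds: list[EvaluationReport]
    mean: dict[str, float]
    sd: dict[str, float]
    config: dict

    def as_dict(self) -> dict:
        return {
            "folds": [f.as_dict() for f in self.folds],
            "mean": self.mean,
            "sd": self.sd,
            "config": self.config,
        }


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def make_folds(assoc: AssociationMatrix, k: int = 5, neg_ratio: float = 1.0,
               seed: int = 0) -> list[FoldSplit]:
    """Partition positives into k folds and sample per-fold negatives.

    Test positives across folds partition the full positive set.  Within a
    fold, train and test negatives are disjoint draws (without replacement)
    from the zero cells of the association matrix.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if neg_ratio <= 0:
        raise ValueError("neg_ratio must be positive")
    rng_fold, rng_neg = [np.random.default_rng(s) for s in _spawn_seeds(seed, 2)]

    positives = [
        (assoc.mirna_ids[i], assoc.disease_ids[j])
        for i, j in assoc.positive_pairs()
    ]
    order = rng_fold.permutation(len(positives))
    chunks = np.array_split(order, k)

    zero_rows, zero_cols = np.nonzero(assoc.values == 0)
    n_zero = zero_rows.size
    folds = []
    fold_seeds = _spawn_seeds(seed + 1, k)
    for fold_index, test_idx in enumerate(chunks):
        test_set = set(test_idx.tolist())
        test_pos = [positives[i] for i in test_idx]
        train_pos = [positives[i] for i in order if i not in test_set]
        n_test_neg = int(round(len(test_pos) * neg_ratio))
        n_train_neg = int(round(len(train_pos) * neg_ratio))
        if n_test_neg + n_train_neg > n_zero:
            raise ValueError(
                f"fold {fold_index}: need {n_test_neg + n_train_neg} negatives "
                f"but only {n_zero} zero cells exist"
            )
        pick = rng_neg.choice(n_zero, size=n_test_neg + n_train_neg, replace=False)
        negs = [(assoc.mirna_ids[zero_rows[p]], assoc.disease_ids[zero_cols[p]]) for p in pick]
        test_neg, train_neg = negs[:n_test_neg], negs[n_test_neg:]
        folds.append(
            FoldSplit(
                fold_index=fold_index,
                train_pairs=[(m, d, 1) for m, d in train_pos] + [(m, d, 0) for m, d in train_neg],
                test_pairs=[(m, d, 1) for m, d in test_pos] + [(m, d, 0) for m, d in test_neg],
                seed=fold_seeds[fold_index],
            )
        )
    return folds


def _masked_assoc(assoc: AssociationMatrix, test_pairs: list[Pair]) -> AssociationMatrix:
    """Copy of `assoc` with the fold's test positives zeroed (no leakage)."""
    values = assoc.values.copy()
    m_index = {name: i for i, name in enumerate(assoc.mirna_ids)}
    d_index = {name: j for j, name in enumerate(assoc.disease_ids)}
    for mid, did, label in test_pairs:
        if label == 1:
            values[m_index[mid], d_index[did]] = 0.0
    return AssociationMatrix(values, assoc.mirna_ids, assoc.disease_ids)


def train_fold(
    dataset: SyntheticDataset,
    fold: FoldSplit,
    config: ModelConfig,
    log=None,
) -> tuple[TrainedModel, EvaluationReport]:
    """Train on one fold's training pairs and evaluate on its test pairs."""
    assoc = dataset.associations
    fold_assoc = _masked_assoc(assoc, fold.test_pairs)
    views = assemble_views(
        fold_assoc,
        dataset.mirna_views["functional"],
        dataset.mirna_views["sequence"],
        dataset.disease_views["semantic"],
        dataset.disease_views["target"],
        gamma_prime=config.gamma_prime,
    )
    model = AssociationModel(views, config, seed=fold.seed)

    m_index = {name: i for i, name in enumerate(assoc.mirna_ids)}
    d_index = {name: j for j, name in enumerate(assoc.disease_ids)}
    train_idx = [(m_index[m], d_index[d]) for m, d, _ in fold.train_pairs]
    train_labels = [label for _, _, label in fold.train_pairs]
    history = model.fit(train_idx, train_labels, log=log)

    known = {(m, d) for m, d, label in fold.train_pairs if label == 1}
    trained = TrainedModel(model, config, known, history)
    scores = trained.score([(m, d) for m, d, _ in fold.test_pairs])
    labels = [label for _, _, label in fold.test_pairs]
    report = compute_metrics(scores, labels, threshold=config.threshold)
    return trained, report


def cross_validate(dataset: SyntheticDataset, config: ModelConfig,
                   verbose: bool = False) -> CVReport:
    """k-fold cross-validation; aggregates fold metrics as mean and sd."""
    folds = make_folds(
        dataset.associations, k=config.n_folds,
        neg_ratio=config.neg_ratio, seed=config.seed,
    )
    reports = []
    for fold in folds:
        if verbose:
            print(f"[fold {fold.fold_index}] training...", file=sys.stderr)
        log = (
            (lambda e, l, i=fold.fold_index: print(
                f"[fold {i}] epoch {e}: loss {l:.5f}", file=sys.stderr))
            if verbose else None
        )
        _, report = train_fold(dataset, fold, config, log=log)
        if verbose:
            print(f"[fold {fold.fold_index}] AUC {report.auc:.4f} "
                  f"AUPRC {report.auprc:.4f}", file=sys.stderr)
        reports.append(report)

    keys = ("auc", "auprc", "accuracy", "f1", "precision", "recall")
    mean = {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
    sd = {k: float(np.std([getattr(r, k) for r in reports], ddof=1)) for k in keys}
    return CVReport(reports, mean, sd, config.as_dict())


def rank_candidates(
    trained: TrainedModel,
    disease_id: str,
    exclude_known: bool = True,
    top_k: int = 10,
) -> list[dict]:
    """Rank miRNA candidates for a disease by predicted probability.

    Returns up to `top_k` rows ``{rank, mirna_id, score, known}`` sorted by
    descending score with ties broken by identifier.  Known training
    positives are excluded when `exclude_known`.
    """
    if disease_id not in set(trained.disease_ids):
        raise KeyError(f"unknown disease identifier {disease_id!r}")
    candidates = [
        m for m in trained.mirna_ids
        if not (exclude_known and (m, disease_id) in trained.known_positives)
    ]
    if not candidates:
        return []
    scores = trained.score([(m, disease_id) for m in candidates])
    ranked = sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    return [
        {
            "rank": r + 1,
            "mirna_id": m,
            "score": float(s),
            "known": (m, disease_id) in trained.known_positives,
        }
        for r, (m, s) in enumerate(ranked[:top_k])
    ]


def shuffle_associations(assoc: AssociationMatrix, seed: int) -> AssociationMatrix:
    """Permute all association labels over the cell grid (null control).

    Destroys the coupling between links and the similarity structure while
    preserving the overall density, so a sound model should score chance-level
    AUC on data shuffled this way.
    """
    rng = np.random.default_rng(seed)
    flat = assoc.values.ravel().copy()
    rng.shuffle(flat)
    return AssociationMatrix(flat.reshape(assoc.values.shape),
                             assoc.mirna_ids, assoc.disease_ids)
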