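"""Association matrix, similarity views, and the Gaussian interaction-profile kernel.

The predictor consumes one binary miRNA x disease association matrix and, per
entity class, three square similarity views: two supplied externally
(functional + sequence for miRNAs, semantic + target-based for diseases) and
one Gaussian interaction-profile (GIP) kernel computed here from the
association matrix itself.  All views are symmetric, unit-diagonal matrices
with entries in [0, 1], sharing the association matrix's identifier order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "SimilarityViewSet",
    "gip_kernel",
    "assemble_views",
]

#: |V - V.T| above this is an error; below it the matrix is symmetrized.
SYMMETRY_TOL = 1e-8

MIRNA_VIEW_NAMES = ("functional", "sequence", "gip")
DISEASE_VIEW_NAMES = ("semantic", "target", "gip")


@dataclass
class AssociationMatrix:
    """Binary bipartite matrix of known miRNA-disease associations.

    Entry (i, j) is 1 when miRNA i is experimentally linked to disease j and
    0 when the pair is unobserved (the candidate-negative pool).
    """

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mirna_ids = list(self.mirna_ids)
        self.disease_ids = list(self.disease_ids)
        if self.values.ndim != 2:
            raise ValueError("association values must be a 2-D matrix")
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match id lists "
                f"({len(self.mirna_ids)} x {len(self.disease_ids)})"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association entries must be 0 or 1")

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    @property
    def n_positive(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one entity class, unit diagonal, [0, 1]."""

    values: np.ndarray
    ids: list[str]
    view_name: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.ids = list(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"view '{self.view_name}' asymmetric by {asym:.3g} (tolerance {SYMMETRY_TOL})"
            )
        # absorb round-trip noise below tolerance
        self.values = (self.values + self.values.T) / 2.0
        if not np.allclose(np.diag(self.values), 1.0, atol=SYMMETRY_TOL):
            bad = np.argmax(np.abs(np.diag(self.values) - 1.0))
            raise ValueError(
                f"view '{self.view_name}' diagonal entry {self.ids[bad]!r} != 1 "
                f"({self.values[bad, bad]:.6g})"
            )
        np.fill_diagonal(self.values, 1.0)
        if self.values.min() < -SYMMETRY_TOL or self.values.max() > 1.0 + SYMMETRY_TOL:
            raise ValueError(f"view '{self.view_name}' has entries outside [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def reorder(self, ids: list[str]) -> "SimilarityMatrix":
        """Return a copy whose rows/columns follow `ids`; all ids must be present."""
        missing = [i for i in ids if i not in set(self.ids)]
        if missing:
            raise KeyError(
                f"view '{self.view_name}' is missing identifiers: {missing[:10]}"
            )
        pos = {name: k for k, name in enumerate(self.ids)}
        perm = np.array([pos[i] for i in ids], dtype=np.intp)
        return SimilarityMatrix(self.values[np.ix_(perm, perm)], list(ids), self.view_name)


@dataclass
class SimilarityViewSet:
    """The per-class view collections feeding the multi-view encoder."""

    mirna_views: list[SimilarityMatrix] = field(default_factory=list)
    disease_views: list[SimilarityMatrix] = field(default_factory=list)

    def __post_init__(self):
        for views, names in (
            (self.mirna_views, MIRNA_VIEW_NAMES),
            (self.disease_views, DISEASE_VIEW_NAMES),
        ):
            if tuple(v.view_name for v in views) != names:
                raise ValueError(
                    f"expected views {names}, got {[v.view_name for v in views]}"
                )
            base = views[0].ids
            for v in views[1:]:
                if v.ids != base:
                    raise ValueError(
                        f"view '{v.view_name}' id order differs from '{views[0].view_name}'"
                    )

    @property
    def mirna_ids(self) -> list[str]:
        return self.mirna_views[0].ids

    @property
    def disease_ids(self) -> list[str]:
        return self.disease_views[0].ids


def gip_kernel(assoc: AssociationMatrix, axis: str, gamma_prime: float = 1.0) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over one side of the association matrix.

    The interaction profile of entity i is its row (miRNAs) or column
    (diseases) of the binary association matrix.  The kernel is

        K[i, j] = exp(-gamma * ||IP(i) - IP(j)||^2),
        gamma   = gamma_prime / mean_i ||IP(i)||^2,

    the bandwidth-normalized form standard in association-prediction work.

    Parameters
    ----------
    assoc
        Binary association matrix.
    axis
        ``"mirna"`` (rows) or ``"disease"`` (columns).
    gamma_prime
        Bandwidth multiplier; must be positive.  Default 1.

    Raises
    ------
    ValueError
        If every interaction profile is all-zero (the bandwidth is then
        undefined): supply at least one known association, or provide the
        view externally.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    if axis == "mirna":
        profiles, ids = assoc.values, assoc.mirna_ids
    elif axis == "disease":
        profiles, ids = assoc.values.T, assoc.disease_ids
    else:
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")

    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise ValueError(
            "all interaction profiles are zero; the GIP bandwidth is undefined "
            "(add known associations or supply this view directly)"
        )
    gamma = gamma_prime / mean_sq
    # ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(sq_dist, 0.0, out=sq_dist)
    kernel = np.exp(-gamma * sq_dist)
    np.fill_diagonal(kernel, 1.0)
    return SimilarityMatrix((kernel + kernel.T) / 2.0, ids, "gip")


def assemble_views(
    assoc: AssociationMatrix,
    mirna_functional: SimilarityMatrix,
    mirna_sequence: SimilarityMatrix,
    disease_semantic: SimilarityMatrix,
    disease_target: SimilarityMatrix,
    gamma_prime: float = 1.0,
) -> SimilarityViewSet:
    """Validate the supplied views, add the GIP views, and align everything
    to the association matrix's identifier order.

    Input views may list their identifiers in any order; they are permuted to
    match `assoc`.  A view missing identifiers raises ``KeyError`` naming them.
    """
    mirna_views = [
        mirna_functional.reorder(assoc.mirna_ids),
        mirna_sequence.reorder(assoc.mirna_ids),
        gip_kernel(assoc, "mirna", gamma_prime),
    ]
    disease_views = [
        disease_semantic.reorder(assoc.disease_ids),
        disease_target.reorder(assoc.disease_ids),
        gip_kernel(assoc, "disease", gamma_prime),
    ]
    for view, name in zip(mirna_views, MIRNA_VIEW_NAMES):
        view.view_name = name
    for view, name in zip(disease_views, DISEASE_VIEW_NAMES):
        view.view_name = name
    return SimilarityViewSet(mirna_views, disease_views)
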