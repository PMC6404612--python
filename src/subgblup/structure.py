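"""Population-structure removal by SVD of the whole marker matrix.

In a Hardy-Weinberg population the subgenomes of an allopolyploid segregate
independently, so realized subgenome kinships are uncorrelated. Breeding
populations violate this: shared ancestry (population structure) induces
collinearity between the subgenome kernels and confounds the partition of
genetic variance. Because every additive kernel is proportional to
``M M^T``, the structure can be removed from all subgenomes at once by a
single SVD of the column-centered whole marker matrix: the first ``k``
principal-component scores ``Q`` are set aside as fixed covariates, and the
marker matrix is reconstructed with those ``k`` singular values zeroed,
yielding a deflated matrix ``M~`` from which the subgenome kernels are then
built.

``subgenome_collinearity`` gives the diagnostic for choosing ``k``: the
pairwise correlation of off-diagonal kinship entries between subgenome
kernels, which levels off once the dominant structure axes are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import MarkerSet
from .kernels import GeneticKernel, KernelError

#: default number of structure axes removed, the choice used for both
#: shipped dataset configurations; always overridable, with the
#: collinearity diagnostic as guidance
DEFAULT_K = 5


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class StructureBasis:
    """Result of removing ``k`` structure axes from a marker matrix.

    ``Q`` holds principal-component scores (left singular vectors scaled by
    singular values); ``m_tilde`` is the deflated marker matrix with column
    means restored (real-valued, no longer integer scores).
    """

    Q: np.ndarray
    singular_values: np.ndarray
    k: int
    m_tilde: np.ndarray
    line_ids: tuple[str, ...]
    column_means: np.ndarray

    def covariates(self, standardize: bool = True) -> np.ndarray:
        """Q as fixed-effect covariates, optionally scaled to unit SD.

        Column scaling only conditions the normal equations; the fit is
        invariant to it.
        """
        if self.k == 0:
            return np.empty((len(self.line_ids), 0))
        Q = self.Q.copy()
        if standardize:
            sd = Q.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Q = Q / sd
        return Q


def _centered(marker_set: MarkerSet) -> tuple[np.ndarray, np.ndarray]:
    if marker_set.n_missing:
        raise StructureError("marker set has missing scores; impute before structure removal")
    M = marker_set.scores
    mu = M.mean(axis=0)
    return M - mu, mu


def _signed_svd(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD with a deterministic sign convention.

    Each right singular vector's sign is fixed so its largest-magnitude
    element is positive, making the decomposition reproducible across
    BLAS implementations.
    """
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    return U, s, Vt


def decompose_structure(marker_set: MarkerSet, k: int = DEFAULT_K) -> StructureBasis:
    """Split the centered marker matrix into k structure axes and a remainder.

    ``M - mean = Q V_k^T + (M~ - mean)`` with ``Q^T (M~ - mean) = 0``: the
    deflated matrix carries no variance along the removed axes, so kernels
    built from ``M~`` are free of them in every subgenome simultaneously.
    """
    X, mu = _centered(marker_set)
    U, s, Vt = _signed_svd(X)
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    if not 0 <= k < max(rank, 1):
        raise StructureError(f"k={k} must satisfy 0 <= k < rank ({rank}) of the centered marker matrix")
    Q = U[:, :k] * s[:k]
    deflated = U[:, k:] @ (s[k:, None] * Vt[k:])
    return StructureBasis(
        Q=Q,
        singular_values=s[:k].copy(),
        k=k,
        m_tilde=deflated + mu,
        line_ids=marker_set.line_ids,
        column_means=mu,
    )


def deflated_marker_set(marker_set: MarkerSet, basis: StructureBasis) -> MarkerSet:
    """Marker set whose scores are the structure-deflated matrix M~.

    Downstream kernel construction re-centers by M~'s own column means
    (recomputed, not the original frequencies). Scores are real-valued, so
    the coding declaration no longer applies and kernel builders treat the
    matrix through its column means alone.
    """
    if basis.line_ids != marker_set.line_ids:
        raise StructureError("structure basis was computed on a different line set")
    return _RealValuedMarkerSet(
        scores=basis.m_tilde.copy(),
        line_ids=marker_set.line_ids,
        marker_ids=marker_set.marker_ids,
        chrom=marker_set.chrom,
        subgenome=marker_set.subgenome,
        coding=marker_set.coding,
    )


@dataclass(frozen=True)
class _RealValuedMarkerSet(MarkerSet):
    """MarkerSet carrying real-valued (deflated) scores.

    Inherits everything; only the score-alphabet invariant is waived.
    """

    def __post_init__(self) -> None:  # noqa: D105
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        for name in ("chrom", "subgenome"):
            if getattr(self, name) == ():
                object.__setattr__(self, name, ("",) * self.scores.shape[1])

    def take_markers(self, idx):
        idx = list(idx)
        return _RealValuedMarkerSet(
            scores=self.scores[:, idx],
            line_ids=self.line_ids,
            marker_ids=tuple(self.marker_ids[j] for j in idx),
            chrom=tuple(self.chrom[j] for j in idx),
            subgenome=tuple(self.subgenome[j] for j in idx),
            coding=self.coding,
        )


def variance_explained(marker_set: MarkerSet, k: int) -> float:
    """Fraction of centered marker-matrix variance on the first k axes.

    Sum of the first ``k`` squared singular values over the total sum of
    squared singular values; nondecreasing in ``k`` and 1 at full rank.
    """
    if k < 1:
        raise StructureError("k must be >= 1")
    X, _ = _centered(marker_set)
    s = np.linalg.svd(X, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise StructureError("marker matrix is constant")
    return float(np.sum(s[: min(k, s.size)] ** 2) / total)


def subgenome_collinearity(kernels: Mapping[str, GeneticKernel]) -> pd.DataFrame:
    """Pearson correlation of off-diagonal kinship entries between kernels.

    For each pair of subgenome kernels, correlates the strictly lower
    triangles. High correlation means shared structure; the value at which
    it levels off as ``k`` grows guides the choice of ``k``.
    """
    labels = list(kernels)
    if len(labels) < 2:
        raise StructureError("need at least two kernels")
    n = kernels[labels[0]].n
    if n < 3:
        raise StructureError("need at least 3 lines for a correlation of off-diagonal entries")
    order = kernels[labels[0]].line_ids
    for lb in labels[1:]:
        if kernels[lb].line_ids != order:
            raise KernelError(f"kernel {lb!r} line ordering differs")
    tri = np.tril_indices(n, k=-1)
    vecs = {lb: kernels[lb].values[tri] for lb in labels}
    out = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        r = float(np.corrcoef(vecs[a], vecs[b])[0, 1])
        out.loc[a, b] = out.loc[b, a] = r
    return out


def write_covariates(basis: StructureBasis, path) -> None:
    """Export Q as a covariate table (line id + k PC columns)."""
    Q = basis.covariates(standardize=False)
    pd.DataFrame(
        Q, index=list(basis.line_ids), columns=[f"PC{i + 1}" for i in range(basis.k)]
    ).to_csv(path, sep="\t", index_label="line")
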