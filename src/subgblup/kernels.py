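"""Genomic relationship kernels: whole-genome, subgenome, epistatic, interaction.

The additive kernel follows VanRaden's method I,

    K = c^-1 (M - P)(M - P)^T + nugget * I,

with ``P = 1_n (2p)^T`` and ``c = 2 p^T (1 - p)`` for {0,1,2} allele counts.
For inbred boolean scores ({0,1}) the analogous construction centers by the
column means p and uses ``c = sum p (1 - p)``; an optional flag doubles the
scores to {0,2} for the literal diploid form instead.

The additive-by-additive epistatic kernel is

    H = K o K - c^-2 (W o W)(W o W)^T,        W = M - P,

where ``o`` is the Hadamard (element-wise) product; ``K o K`` alone is its
large-m approximation. Because no marker is shared across subgenomes,
inter-genomic interaction covariances are exactly the Hadamard products of
the component subgenome kernels (K_A o K_B, ..., K_A o K_B o K_D).

Interaction and epistatic kernels must be built from nugget-free additive
components (the ridge would otherwise leak into cross terms); each kernel
that enters a model fit then receives its own small ridge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_io import DataError, MarkerSet

#: ridge added to a fitted kernel's diagonal to restore full rank
DEFAULT_NUGGET = 0.01

SUBGENOMES = ("A", "B", "D")


class KernelError(ValueError):
    """Raised for degenerate kernel constructions."""


@dataclass(frozen=True)
class GeneticKernel:
    """A labeled symmetric line x line relationship matrix.

    ``c`` is the scaling constant of an additive kernel (``2 p^T (1-p)``),
    or the product of the component constants for interaction kernels.
    ``nugget`` records the ridge currently on the diagonal.
    """

    values: np.ndarray
    line_ids: tuple[str, ...]
    label: str
    c: float
    nugget: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise KernelError(f"kernel {self.label!r} is not square: {v.shape}")
        if v.shape[0] != len(self.line_ids):
            raise KernelError(f"kernel {self.label!r}: {len(self.line_ids)} ids for {v.shape[0]} rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def with_nugget(self, nugget: float = DEFAULT_NUGGET) -> "GeneticKernel":
        """Return a copy with the diagonal ridge set to ``nugget``."""
        delta = nugget - self.nugget
        return GeneticKernel(
            self.values + delta * np.eye(self.n), self.line_ids, self.label, self.c, nugget
        )

    def is_symmetric(self, tol: float = 1e-10) -> bool:
        return bool(np.allclose(self.values, self.values.T, atol=tol, rtol=0.0))

    def min_eigenvalue_ratio(self) -> float:
        """Smallest over largest eigenvalue; >= -1e-8 for a PSD kernel."""
        w = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        top = max(w[-1], np.finfo(float).tiny)
        return float(w[0] / top)


# ---------------------------------------------------------------------------
# centering helpers
# ---------------------------------------------------------------------------


def allele_frequencies(marker_set: MarkerSet) -> np.ndarray:
    """Minor/alternate allele frequency per marker from the score matrix."""
    if marker_set.n_missing:
        raise KernelError("marker set has missing scores; impute before kernel construction")
    mean = marker_set.scores.mean(axis=0)
    return mean / 2.0 if 2 in marker_set.coding else mean


def centered_scores(
    marker_set: MarkerSet,
    p: np.ndarray | None = None,
    double_inbred: bool = False,
) -> tuple[np.ndarray, float]:
    """Return the centered score matrix ``W = M - P`` and scaling ``c``."""
    M = marker_set.scores
    diploid = 2 in marker_set.coding
    if double_inbred and not diploid:
        M = 2.0 * M
        diploid = True
    if p is None:
        if marker_set.n_missing:
            raise KernelError("marker set has missing scores; impute before kernel construction")
        p = M.mean(axis=0) / 2.0 if diploid else M.mean(axis=0)
    else:
        p = np.asarray(p, dtype=float)
        if p.shape != (marker_set.n_markers,):
            raise KernelError(f"allele-frequency vector has shape {p.shape}, expected ({marker_set.n_markers},)")
    if diploid:
        W = M - 2.0 * p
        c = float(2.0 * np.sum(p * (1.0 - p)))
    else:
        W = M - p
        c = float(np.sum(p * (1.0 - p)))
    return W, c


# ---------------------------------------------------------------------------
# kernel constructors
# ---------------------------------------------------------------------------


def vanraden_kernel(
    marker_set: MarkerSet,
    p: np.ndarray | None = None,
    nugget: float = DEFAULT_NUGGET,
    label: str = "G",
    double_inbred: bool = False,
) -> GeneticKernel:
    """Additive genomic relationship matrix (VanRaden method I).

    ``p`` defaults to frequencies estimated from the marker set itself, in
    which case centering forces every row of ``c^-1 W W^T`` to sum to zero,
    so kernel row sums equal the nugget.
    """
    if marker_set.n_markers == 0:
        raise KernelError("no markers")
    W, c = centered_scores(marker_set, p=p, double_inbred=double_inbred)
    if c <= 0.0:
        raise KernelError("scaling constant c = 0: all markers monomorphic under the supplied frequencies")
    K = (W @ W.T) / c
    if nugget:
        K = K + nugget * np.eye(marker_set.n_lines)
    return GeneticKernel(K, marker_set.line_ids, label, c, nugget)


def subgenome_kernels(
    marker_set: MarkerSet,
    nugget: float = DEFAULT_NUGGET,
    subgenomes: Sequence[str] = SUBGENOMES,
    double_inbred: bool = False,
) -> dict[str, GeneticKernel]:
    """One additive kernel per subgenome, each from its own marker block.

    Each block uses its own allele frequencies and scaling constant, exactly
    as the whole-genome kernel does on all markers.
    """
    out: dict[str, GeneticKernel] = {}
    for sg in subgenomes:
        try:
            block = marker_set.subgenome_block(sg)
        except DataError as exc:
            raise KernelError(f"cannot build kernel for subgenome {sg}: {exc}") from exc
        out[sg] = vanraden_kernel(block, nugget=nugget, label=sg, double_inbred=double_inbred)
    return out


def epistatic_kernel(
    marker_set: MarkerSet,
    exact: bool = True,
    label: str = "I",
    double_inbred: bool = False,
) -> GeneticKernel:
    """Additive-by-additive epistatic relationship matrix.

    ``exact=True`` removes the same-marker "interaction" of each locus with
    itself: H = K o K - c^-2 (W o W)(W o W)^T, leaving exactly the pairwise
    cross products 2 c^-2 sum_{j<k} (w_j o w_k)(w_j o w_k)^T.
    ``exact=False`` returns the large-m approximation K o K. Built from the
    nugget-free additive kernel.
    """
    if marker_set.n_markers == 0:
        raise KernelError("no markers")
    W, c = centered_scores(marker_set, double_inbred=double_inbred)
    if c <= 0.0:
        raise KernelError("scaling constant c = 0")
    K = (W @ W.T) / c
    H = K * K
    if exact:
        W2 = W * W
        H = H - (W2 @ W2.T) / (c * c)
    return GeneticKernel(H, marker_set.line_ids, label, c, 0.0)


def interaction_kernel(kernels: Sequence[GeneticKernel], label: str | None = None) -> GeneticKernel:
    """Hadamard product of 2-3 nugget-free additive kernels.

    Valid as an inter-genomic interaction covariance because the component
    kernels are built from disjoint marker sets. Line orderings must match
    exactly; no silent reordering.
    """
    if not 2 <= len(kernels) <= 3:
        raise KernelError(f"interaction kernel takes 2-3 components, got {len(kernels)}")
    first = kernels[0]
    for k in kernels[1:]:
        if k.line_ids != first.line_ids:
            raise KernelError(
                f"line orderings of kernels {first.label!r} and {k.label!r} differ; reorder explicitly"
            )
    for k in kernels:
        if k.nugget != 0.0:
            raise KernelError(
                f"component kernel {k.label!r} carries a nugget ({k.nugget}); "
                "interaction kernels must be built from nugget-free components"
            )
    values = kernels[0].values.copy()
    c = kernels[0].c
    for k in kernels[1:]:
        values *= k.values
        c *= k.c
    return GeneticKernel(values, first.line_ids, label or "".join(k.label for k in kernels), c, 0.0)


# ---------------------------------------------------------------------------
# model kernel sets
# ---------------------------------------------------------------------------

#: named model formulations: random genetic terms of each model
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "G": ("G",),
    "ABD": ("A", "B", "D"),
    "GxG": ("G", "I"),
    "ABDxABD": ("A", "B", "D", "AB", "AD", "BD"),
    "ABDxABD+3way": ("A", "B", "D", "AB", "AD", "BD", "ABD"),
}


def model_kernels(
    marker_set: MarkerSet,
    model: str = "ABDxABD",
    nugget: float = DEFAULT_NUGGET,
    exact_h: bool = True,
    double_inbred: bool = False,
) -> list[GeneticKernel]:
    """Build the ordered kernel list for a named model formulation.

    Interaction and epistatic kernels are formed from nugget-free additive
    components and then each kernel receives the ridge it enters the model
    fit with.
    """
    if model not in MODEL_TERMS:
        raise KernelError(f"unknown model {model!r}; choose from {sorted(MODEL_TERMS)}")
    terms = MODEL_TERMS[model]
    need_sub = any(t in terms for t in ("A", "B", "D", "AB", "AD", "BD", "ABD"))
    sub = (
        subgenome_kernels(marker_set, nugget=0.0, double_inbred=double_inbred) if need_sub else {}
    )
    out: list[GeneticKernel] = []
    for t in terms:
        if t == "G":
            k = vanraden_kernel(marker_set, nugget=0.0, double_inbred=double_inbred)
        elif t == "I":
            k = epistatic_kernel(marker_set, exact=exact_h, double_inbred=double_inbred)
        elif t in sub:
            k = sub[t]
        else:  # pairwise or three-way Hadamard interaction
            k = interaction_kernel([sub[s] for s in t])
        out.append(k.with_nugget(nugget))
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_kernel(kernel: GeneticKernel, path) -> None:
    """Write a kernel as a labeled square tab-delimited table."""
    import pandas as pd

    pd.DataFrame(kernel.values, index=list(kernel.line_ids), columns=list(kernel.line_ids)).to_csv(
        path, sep="\t", index_label=kernel.label
    )


def read_kernel(path) -> GeneticKernel:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    label = str(df.index.name or "K")
    return GeneticKernel(df.to_numpy(dtype=float), tuple(str(i) for i in df.index), label, c=float("nan"))
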