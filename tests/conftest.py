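"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately avoid the package's own computation
paths: the restricted likelihood is evaluated through the error-contrast
density, and epistatic/interaction kernels through explicit pairwise
interaction design matrices.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import linalg, stats

import subgblup as sg


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def restricted_loglik_bruteforce(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """REML log-likelihood as the exact density of error contrasts.

    With A an orthonormal basis of the null space of X', the restricted
    likelihood is the N(0, A'VA) density of A'y - an evaluation route with
    no projection matrices or determinant identities shared with the
    solver.
    """
    A = linalg.null_space(X.T)
    z = A.T @ y
    return float(stats.multivariate_normal(mean=np.zeros(z.size), cov=A.T @ V @ A).logpdf(z))


def covariance_at(fit: "sg.REMLFit") -> np.ndarray:
    """Record covariance V implied by a fit's reported parameters."""
    d = fit.design
    V = fit.sigma2["residual"] * np.eye(d.y.size)
    for label, kern in fit.spec.random_terms:
        V += fit.sigma2[label] * (d.Z @ kern.values @ d.Z.T)
    return V


def pairwise_epistasis_oracle(W: np.ndarray, c: float) -> np.ndarray:
    """H = 2 c^-2 E E' from the explicit j<k interaction design matrix."""
    m = W.shape[1]
    cols = [W[:, j] * W[:, k] for j, k in itertools.combinations(range(m), 2)]
    if not cols:
        return np.zeros((W.shape[0], W.shape[0]))
    E = np.column_stack(cols)
    return 2.0 / (c * c) * (E @ E.T)


def cross_subgenome_oracle(WX: np.ndarray, cX: float, WY: np.ndarray, cY: float) -> np.ndarray:
    """K_X o K_Y = (cX cY)^-1 F F' with F all cross products w_a o w_b."""
    F = np.column_stack([WX[:, a] * WY[:, b] for a in range(WX.shape[1]) for b in range(WY.shape[1])])
    return (F @ F.T) / (cX * cY)


def random_marker_set(rng: np.random.Generator, n: int, m_per: tuple[int, int, int], coding=(0, 1)) -> sg.MarkerSet:
    """Small random marker set with guaranteed-polymorphic columns."""
    cols, chrom, subg = [], [], []
    top = max(coding)
    for sgname, m in zip(("A", "B", "D"), m_per):
        for j in range(m):
            while True:
                if coding == (0, 1):
                    col = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(float)
                else:
                    col = rng.choice([0.0, 1.0, 2.0], size=n, p=_gt_probs(rng))
                if 0 < col.mean() < top:
                    break
            cols.append(col)
            chrom.append(f"{1 + j % 7}{sgname}")
            subg.append(sgname)
    ids = tuple(f"L{i}" for i in range(n))
    mids = tuple(f"M{j}" for j in range(len(cols)))
    return sg.MarkerSet(np.column_stack(cols), ids, mids, chrom=tuple(chrom), subgenome=tuple(subg), coding=coding)


def _gt_probs(rng) -> np.ndarray:
    p = rng.uniform(0.2, 0.8)
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_sim() -> sg.SimData:
    """120-line additive-architecture dataset used across modules."""
    cfg = sg.SimConfig(n_lines=120, m_per_subgenome=(40, 50, 20), seed=11)
    return sg.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_sim) -> sg.REMLFit:
    """ABD model fit on the shared small dataset."""
    ks = sg.model_kernels(small_sim.marker_set, "ABD")
    ph = sg.standardize_phenotypes(small_sim.pheno, ["yield"])
    spec = sg.ModelSpec("yield", list(zip(("A", "B", "D"), ks)))
    return sg.fit_reml(ph, spec)
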