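"""Multi-kernel linear mixed models fit by restricted maximum likelihood.

The model for a vector of records y is

    y = 1 mu + X beta + Q gamma + sum_l Z g_l + e,
    g_l ~ N(0, sigma2_l K_l),   e ~ N(0, sigma2 I),

with trial (environment) dummies in X, optional population-structure scores
Q as fixed covariates, and one random genetic term per relationship kernel
K_l (whole genome, subgenomes, and/or their Hadamard interactions). Z maps
each record to its line; lines without records are carried in the kernels
and receive predictions through their relationships alone.

Variance components are estimated by average-information (AI) REML: a
Newton-type step using the AI approximation to the Hessian of the
restricted likelihood, falling back to an EM-style fixed-point update when
the AI step fails to improve the likelihood or leaves the parameter space.
Components that converge onto the lower bound are reported as exactly zero
and flagged as boundary estimates. The inverse of the AI matrix at
convergence provides asymptotic standard errors and sampling correlations
of the variance estimates.

The restricted log-likelihood is the error-contrast form

    l_R = -1/2 [ (n-p) log 2*pi + log|V| + log|X'V^-1 X| - log|X'X|
                 + y'Py ],

which equals the exact density of any orthonormal basis of error contrasts,
so it is directly comparable against a brute-force evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .data_io import PhenoTable
from .kernels import GeneticKernel
from .structure import StructureBasis

logger = logging.getLogger("subgblup")

RESIDUAL = "residual"


class FitError(RuntimeError):
    pass


class ConvergenceError(FitError):
    """Raised when REML fails to converge; carries the likelihood trajectory."""

    def __init__(self, msg: str, trajectory: list[float]):
        super().__init__(msg)
        self.trajectory = trajectory


# ---------------------------------------------------------------------------
# model specification and design construction
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Which trait to fit and with which random genetic terms.

    The fixed part is always intercept + trial dummies (first trial as the
    reference level); if ``structure`` is given its standardized PC scores
    enter as additional fixed covariates with slopes gamma.
    """

    trait: str
    random_terms: list[tuple[str, GeneticKernel]]
    structure: StructureBasis | None = None

    def __post_init__(self) -> None:
        if not self.random_terms:
            raise FitError("at least one random genetic term is required")
        ids = self.random_terms[0][1].line_ids
        for label, k in self.random_terms[1:]:
            if k.line_ids != ids:
                raise FitError(f"kernel {label!r} has a different line ordering")
        if self.structure is not None and self.structure.line_ids != ids:
            raise FitError("structure basis line ordering differs from the kernels'")

    @property
    def line_ids(self) -> tuple[str, ...]:
        return self.random_terms[0][1].line_ids

    @property
    def term_labels(self) -> tuple[str, ...]:
        return tuple(lb for lb, _ in self.random_terms)


@dataclass
class Design:
    """Record-level design matrices for one trait."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    Z: np.ndarray  # n_records x n_lines incidence
    line_ids: tuple[str, ...]
    record_lines: list[str]
    trials: list[str]


def build_design(pheno: PhenoTable, spec: ModelSpec) -> Design:
    """Assemble y, X (intercept + trial dummies + Q) and Z for a trait."""
    recs = pheno.values(spec.trait)
    line_ids = spec.line_ids
    pos = {lid: i for i, lid in enumerate(line_ids)}
    unknown = sorted(set(recs["line"]) - set(line_ids))
    if unknown:
        raise FitError(f"records refer to lines absent from the kernels: {unknown[:5]}")
    n = len(recs)
    Z = np.zeros((n, len(line_ids)))
    for r, lid in enumerate(recs["line"]):
        Z[r, pos[lid]] = 1.0
    trials = sorted(recs["trial"].unique())
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for t in trials[1:]:  # reference-level convention: first trial dropped
        cols.append((recs["trial"] == t).to_numpy(dtype=float))
        names.append(f"trial[{t}]")
    if spec.structure is not None and spec.structure.k > 0:
        Qline = spec.structure.covariates(standardize=True)
        Qrec = Z @ Qline
        for j in range(Qline.shape[1]):
            cols.append(Qrec[:, j])
            names.append(f"PC{j + 1}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise FitError(f"singular fixed-effect design; aliased columns: {aliased}")
    if n <= X.shape[1]:
        raise FitError(f"{n} records cannot support {X.shape[1]} fixed-effect parameters")
    return Design(
        y=recs["y"].to_numpy(dtype=float),
        X=X,
        fixed_names=names,
        Z=Z,
        line_ids=line_ids,
        record_lines=list(recs["line"]),
        trials=trials,
    )


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    tol = np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(np.abs(np.diag(R)) > tol))
    return [names[j] for j in sorted(piv[rank:])]


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------


@dataclass
class REMLFit:
    """Converged REML solution for one model on one trait."""

    spec: ModelSpec
    design: Design
    sigma2: dict[str, float]  # per random term + "residual", trait-SD^2 units
    se: dict[str, float]
    ai_matrix: pd.DataFrame
    loglik: float
    aic: float
    beta: pd.Series  # all fixed effects, by design-column name
    blups: pd.DataFrame  # n_lines x n_terms, BLUPs g_l for every kernel line
    boundary: dict[str, bool]
    converged: bool
    n_iter: int
    Py: np.ndarray = field(repr=False, default=None)

    @property
    def gamma(self) -> pd.Series:
        """Structure-covariate slopes (subset of beta)."""
        return self.beta[[n for n in self.beta.index if n.startswith("PC")]]

    @property
    def n_variance_params(self) -> int:
        return len(self.sigma2)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"term": t, "sigma2": self.sigma2[t], "se": self.se[t], "boundary": self.boundary[t]}
            for t in self.sigma2
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the solver
# ---------------------------------------------------------------------------


def _loglik_and_derivs(
    y: np.ndarray,
    X: np.ndarray,
    Vparts: list[np.ndarray],
    theta: np.ndarray,
    logdet_XtX: float,
    want_derivs: bool = True,
):
    """Restricted log-likelihood and, optionally, score and AI matrix."""
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for th, Vl in zip(theta[:-1], Vparts):
        V += th * Vl
    cf, lower = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(cf))))
    Vinv = linalg.cho_solve((cf, lower), np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    cfx = linalg.cho_factor(XtVinvX, check_finite=False)
    logdet_XtVinvX = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
    P = Vinv - VinvX @ linalg.cho_solve(cfx, VinvX.T, check_finite=False)
    Py = P @ y
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi) + logdet_V + logdet_XtVinvX - logdet_XtX + float(y @ Py)
    )
    if not want_derivs:
        return ll, P, Py, None, None
    n_par = len(theta)
    score = np.empty(n_par)
    t_vecs = []  # V_i P y for each component
    for i in range(n_par):
        if i < n_par - 1:
            Vi = Vparts[i]
            tr = float(np.sum(P * Vi))  # tr(P V_i) via the Hadamard identity
            ViPy = Vi @ Py
        else:
            tr = float(np.trace(P))
            ViPy = Py
        score[i] = -0.5 * (tr - float(Py @ ViPy))
        t_vecs.append(ViPy)
    T = np.column_stack(t_vecs)
    AI = 0.5 * (T.T @ P @ T)
    return ll, P, Py, score, AI


def fit_reml(
    pheno: PhenoTable,
    spec: ModelSpec,
    max_iter: int = 100,
    tol: float = 1e-6,
    verbose: bool = False,
) -> REMLFit:
    """Estimate variance components by AI-REML with EM fallback.

    Start values split the phenotypic variance equally over all components.
    An AI (Newton) step is accepted only if the restricted likelihood does
    not decrease; otherwise the step is halved, and failing that an EM-style
    fixed-point update is taken. Convergence is declared when the likelihood
    changes by less than ``tol`` between accepted iterations. Components at
    the lower bound (1e-8 x phenotypic variance) are reported as zero and
    flagged ``boundary``.
    """
    design = build_design(pheno, spec)
    y, X, Z = design.y, design.X, design.Z
    n = y.size
    Vparts = [Z @ term.values @ Z.T for _, term in spec.random_terms]
    labels = list(spec.term_labels) + [RESIDUAL]
    n_par = len(labels)
    vary = float(np.var(y, ddof=1))
    lb = 1e-8 * vary
    theta = np.full(n_par, vary / n_par)
    sign, logdet_XtX = np.linalg.slogdet(X.T @ X)
    trajectory: list[float] = []

    ll, P, Py, score, AI = _loglik_and_derivs(y, X, Vparts, theta, logdet_XtX)
    trajectory.append(ll)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # active set: components pinned at the lower bound whose score pushes
        # them further down are held fixed and left out of the Newton solve
        free = ~((theta <= lb * 1.5) & (score < 0.0))
        candidates: list[np.ndarray] = []
        if free.any():
            try:
                delta = np.zeros(n_par)
                delta[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
                # full clipped Newton step first
                candidates.append(np.clip(theta + delta, lb, None))
                # then the step truncated where it first hits the lower
                # bound, so the blocking component lands exactly on the
                # bound (and is pinned by the active set next iteration)
                # instead of distorting the ascent direction by clipping
                neg = delta < 0.0
                t_max = 1.0
                if neg.any():
                    t_max = min(1.0, float(np.min((theta[neg] - lb) / -delta[neg])))
                step = t_max
                for _ in range(8):
                    candidates.append(np.clip(theta + step * delta, lb, None))
                    step *= 0.5
            except np.linalg.LinAlgError:
                pass
        # EM-style fixed point: theta_i <- theta_i * (y'P V_i P y) / tr(P V_i)
        em = theta.copy()
        for i in range(n_par):
            Vi_Py = Vparts[i] @ Py if i < n_par - 1 else Py
            tr = float(np.sum(P * Vparts[i])) if i < n_par - 1 else float(np.trace(P))
            if tr > 0:
                em[i] = theta[i] * float(Py @ Vi_Py) / tr
        candidates.append(np.clip(em, lb, None))

        accepted = None
        for cand in candidates:
            ll_new, P_new, Py_new, score_new, AI_new = _loglik_and_derivs(
                y, X, Vparts, cand, logdet_XtX
            )
            if ll_new >= ll - 1e-12:
                accepted = (cand, ll_new, P_new, Py_new, score_new, AI_new)
                break
        if accepted is None:
            converged = True  # no update improves the likelihood
            break
        theta, ll_new, P, Py, score, AI = accepted
        if verbose:
            logger.info("REML iter %d: loglik %.8f theta %s", it, ll_new, theta)
        delta_ll = ll_new - ll
        ll = ll_new
        trajectory.append(ll)
        if abs(delta_ll) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"REML did not converge in {max_iter} iterations", trajectory)

    boundary_mask = theta <= lb * 1.5
    theta_report = np.where(boundary_mask, 0.0, theta)
    if boundary_mask[-1]:
        raise FitError("residual variance collapsed to the boundary; model is degenerate")
    # final quantities at the reported parameters (boundary terms exactly 0)
    ll, P, Py, score, AI = _loglik_and_derivs(y, X, Vparts, theta_report, logdet_XtX)

    VinvX_beta = _gls_fixed_effects(y, X, Vparts, theta_report)
    beta = pd.Series(VinvX_beta, index=design.fixed_names)
    ZtPy = Z.T @ Py
    blup_cols = {}
    for (label, term), th in zip(spec.random_terms, theta_report[:-1]):
        blup_cols[label] = th * (term.values @ ZtPy)
    blups = pd.DataFrame(blup_cols, index=list(design.line_ids))

    ai_df = pd.DataFrame(AI, index=labels, columns=labels)
    se = _ai_standard_errors(AI, labels)
    aic = -2.0 * ll + 2.0 * n_par  # all variance parameters counted, boundary included
    return REMLFit(
        spec=spec,
        design=design,
        sigma2=dict(zip(labels, (float(t) for t in theta_report))),
        se=se,
        ai_matrix=ai_df,
        loglik=float(ll),
        aic=float(aic),
        beta=beta,
        blups=blups,
        boundary=dict(zip(labels, (bool(b) for b in boundary_mask))),
        converged=True,
        n_iter=it,
        Py=Py,
    )


def _gls_fixed_effects(y, X, Vparts, theta) -> np.ndarray:
    n = y.size
    V = theta[-1] * np.eye(n)
    for th, Vl in zip(theta[:-1], Vparts):
        V += th * Vl
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    Vinv_y = linalg.cho_solve(cf, y, check_finite=False)
    VinvX = linalg.cho_solve(cf, X, check_finite=False)
    return np.linalg.solve(X.T @ VinvX, X.T @ Vinv_y)


def _ai_standard_errors(AI: np.ndarray, labels: list[str]) -> dict[str, float]:
    try:
        cov = np.linalg.inv(AI)
        var = np.diag(cov)
        if np.any(var < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("AI matrix singular or indefinite; standard errors from pseudo-inverse")
        cov = np.linalg.pinv(AI)
        var = np.clip(np.diag(cov), 0.0, None)
    return dict(zip(labels, (float(np.sqrt(v)) for v in var)))


# ---------------------------------------------------------------------------
# post-fit accessors
# ---------------------------------------------------------------------------


def blup_effects(fit: REMLFit) -> pd.DataFrame:
    """Per-term BLUP effect vectors g_l for every line in the kernels.

    Boundary terms have sigma2 = 0 and hence exactly zero effect vectors.
    """
    if not fit.converged:
        raise FitError("fit did not converge")
    return fit.blups.copy()


def fitted_decomposition(fit: REMLFit) -> pd.DataFrame:
    """Record-level decomposition: y = fixed + sum_l g_l + residual."""
    d = fit.design
    fixed = d.X @ fit.beta.to_numpy()
    parts = {"fixed": fixed}
    for label in fit.spec.term_labels:
        parts[label] = d.Z @ fit.blups[label].to_numpy()
    resid = fit.sigma2[RESIDUAL] * fit.Py
    parts[RESIDUAL] = resid
    out = pd.DataFrame(parts)
    out.insert(0, "y", d.y)
    return out


def model_aic(fit: REMLFit) -> float:
    """AIC = -2 loglik + 2 t with t = number of variance parameters.

    Boundary-clamped components still count. Comparable only across fits
    sharing data and fixed-effect design.
    """
    if not fit.converged:
        raise FitError("fit did not converge")
    return fit.aic


def compare_aic(fits: Sequence[REMLFit]) -> pd.DataFrame:
    """Tabulate AICs; warns when fixed designs differ (not comparable)."""
    designs = {tuple(f.design.fixed_names) for f in fits}
    if len(designs) > 1:
        warnings.warn("comparing AICs across different fixed-effect designs")
    return pd.DataFrame(
        {
            "model": ["+".join(f.spec.term_labels) for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
        }
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(full: REMLFit, reduced: REMLFit, boundary_mixture: bool = True) -> LRTResult:
    """REML likelihood-ratio test of nested random structures.

    The added components are variances tested on the boundary of the
    parameter space, so the default null is the equal mixture
    0.5 chi2_0 + 0.5 chi2_d for d added terms; ``boundary_mixture=False``
    gives the plain chi2_d reference.
    """
    full_terms = set(full.spec.term_labels)
    red_terms = set(reduced.spec.term_labels)
    if not red_terms <= full_terms:
        raise FitError(f"models are not nested: {sorted(red_terms)} vs {sorted(full_terms)}")
    if full.design.fixed_names != reduced.design.fixed_names or full.design.y.shape != reduced.design.y.shape or not np.allclose(full.design.y, reduced.design.y):
        raise FitError("LRT requires identical data and fixed-effect design")
    d = len(full_terms) - len(red_terms)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if stat == 0.0 or d == 0:
        p = 1.0
    elif boundary_mixture:
        p = 0.5 * float(stats.chi2.sf(stat, d))
    else:
        p = float(stats.chi2.sf(stat, d))
    return LRTResult(float(stat), d, p)


def sampling_correlations(fit: REMLFit) -> pd.DataFrame:
    """Asymptotic correlations of the variance estimates from inv(AI)."""
    AI = fit.ai_matrix.to_numpy()
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError as exc:
        raise FitError(
            "AI matrix is singular; variance estimates are not jointly identifiable "
            "- consider dropping terms from the model"
        ) from exc
    d = np.sqrt(np.clip(np.diag(cov), np.finfo(float).tiny, None))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=fit.ai_matrix.index, columns=fit.ai_matrix.columns)


def write_fit_summary(fit: REMLFit, path) -> None:
    """Tidy (term, sigma2, se, boundary) table plus loglik/AIC footer."""
    df = fit.summary()
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write(f"# loglik\t{fit.loglik:.10g}\n# aic\t{fit.aic:.10g}\n")
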