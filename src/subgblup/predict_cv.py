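"""Breeding-value assembly, quantile ranking and replicated cross-validation.

The whole-genome value (GEBV) of a line is the sum of all its genetic term
effects plus, when population structure was removed, the column-centered
structure contribution Q gamma. Subgenome breeding values (SGEBVs) are the
per-kernel BLUPs g_A, g_B, g_D; inter-genomic interaction effects come from
the Hadamard-kernel terms.

Cross-validation follows the replicated masking scheme: per replicate the
lines are randomly split into k groups (any remainder pooled into the last
group, so n = 1447 with 5 folds gives 4 groups of 289 and one of 291); all
records of a fold's lines are masked, the model refit, and the masked
lines' whole-genome values predicted through their kernel relationships.
Predictions from all folds are pooled and correlated once per replicate
against "true" genetic values, i.e. line BLUPs from a fit in which lines
are treated as independent (K = I).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import PhenoTable
from .kernels import GeneticKernel
from .reml import FitError, ModelSpec, REMLFit, fit_reml
from .structure import StructureBasis

logger = logging.getLogger("subgblup")

WHOLE_GENOME = "whole_genome"
STRUCTURE = "structure"


# ---------------------------------------------------------------------------
# effect assembly
# ---------------------------------------------------------------------------


@dataclass
class EffectTable:
    """Per-line genetic effect decomposition.

    ``table`` has one column per genetic term, a ``structure`` column
    (centered Q gamma; zero when no structure covariates were fitted) and a
    ``whole_genome`` column equal to their sum.
    """

    table: pd.DataFrame

    @property
    def columns(self) -> list[str]:
        return [c for c in self.table.columns]


def assemble_effects(fit: REMLFit, structure: StructureBasis | None = None) -> EffectTable:
    """Decompose each line's genetic value into its model terms.

    ``structure`` defaults to the basis carried by the fit's model spec.
    The structure contribution is column-centered before summation, so the
    whole-genome column is centered apart from BLUP shrinkage.
    """
    if not fit.converged:
        raise FitError("fit did not converge")
    structure = structure if structure is not None else fit.spec.structure
    gamma = fit.gamma
    tab = fit.blups.copy()
    if len(gamma):
        if structure is None:
            raise FitError("structure covariates were fitted but no StructureBasis supplied")
        Q = structure.covariates(standardize=True)
        contrib = Q @ gamma.to_numpy()
        contrib = contrib - contrib.mean()
        tab[STRUCTURE] = contrib
    else:
        tab[STRUCTURE] = 0.0
    tab[WHOLE_GENOME] = tab.sum(axis=1)
    return EffectTable(tab)


def quantile_report(effects: EffectTable, q: float = 0.95) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag lines at or above the q-quantile of each column, and rank them.

    Returns ``(flags, ranks)``: boolean flags per column, and dense ranks
    with 1 = highest value. The upper quantile identifies parental-selection
    candidates per (sub)genome.
    """
    tab = effects.table
    if len(tab) < 2:
        raise FitError("need at least 2 lines to rank")
    thresholds = tab.quantile(q)
    flags = tab.ge(thresholds, axis=1)
    ranks = tab.rank(method="dense", ascending=False).astype(int)
    return flags, ranks


def write_effect_table(effects: EffectTable, path) -> None:
    effects.table.to_csv(path, sep="\t", index_label="line")


# ---------------------------------------------------------------------------
# "true" genetic values
# ---------------------------------------------------------------------------


def true_genetic_values(pheno: PhenoTable, trait: str) -> pd.Series:
    """Line BLUPs under an identity genetic covariance (independent lines).

    The benchmark for cross-validation in unbalanced trial data: the same
    trial-adjusted mixed model, but with K = I so no marker information is
    shared between lines. Lines with no records are absent from the result.
    """
    recs = pheno.values(trait)
    lines = tuple(sorted(recs["line"].unique()))
    if not lines:
        raise FitError(f"no records for trait {trait!r}")
    identity = GeneticKernel(np.eye(len(lines)), lines, "line", c=float(len(lines)), nugget=0.0)
    spec = ModelSpec(trait=trait, random_terms=[("line", identity)])
    fit = fit_reml(pheno, spec)
    return fit.blups["line"].copy()


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Replicated k-fold cross-validation accuracies."""

    folds: list[dict[str, int]]  # per replicate: line -> fold index
    seed: int
    accuracies: np.ndarray  # one Pearson correlation per replicate

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"replicate": np.arange(1, len(self.accuracies) + 1), "accuracy": self.accuracies})
        return df


def fold_sizes(n: int, folds: int) -> list[int]:
    """k-fold group sizes with the remainder pooled into the last group.

    1447 lines in 5 folds gives [289, 289, 289, 289, 291].
    """
    if folds < 2 or folds > n:
        raise FitError(f"cannot split {n} lines into {folds} folds")
    base = n // folds
    return [base] * (folds - 1) + [base + n - base * folds]


def assign_folds(lines: list[str], folds: int, rng: np.random.Generator) -> dict[str, int]:
    sizes = fold_sizes(len(lines), folds)
    perm = rng.permutation(len(lines))
    out: dict[str, int] = {}
    start = 0
    for f, size in enumerate(sizes):
        for i in perm[start : start + size]:
            out[lines[i]] = f
        start += size
    return out


def _mask_lines(pheno: PhenoTable, trait: str, masked: set[str]) -> PhenoTable:
    recs = pheno.records
    keep = ~recs["line"].isin(masked)
    return PhenoTable(recs[keep].reset_index(drop=True), dict(pheno.standardized), dict(pheno.scale_info))


def predict_whole_genome(fit: REMLFit, include_structure: bool = True) -> pd.Series:
    """Whole-genome predicted values for every line carried by the kernels."""
    eff = assemble_effects(fit)
    if include_structure:
        return eff.table[WHOLE_GENOME]
    return eff.table[WHOLE_GENOME] - eff.table[STRUCTURE]


def cross_validate(
    pheno: PhenoTable,
    spec: ModelSpec,
    folds: int = 5,
    reps: int = 10,
    seed: int = 0,
    include_structure: bool = True,
    true_values: pd.Series | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> CVResult:
    """Replicated k-fold cross-validation of whole-genome prediction.

    Kernels (and hence allele frequencies) are those carried by ``spec``,
    computed once on all genotyped lines; per fold only the phenotype
    records of the masked lines are removed. Accuracy per replicate is the
    Pearson correlation of the pooled masked-line predictions with the
    K = I "true" genetic values, computed once over all folds.
    """
    recs = pheno.values(spec.trait)
    lines = sorted(recs["line"].unique())
    all_trials = set(recs["trial"].unique())
    if true_values is None:
        true_values = true_genetic_values(pheno, spec.trait)
    true_values = true_values.dropna()
    fold_maps: list[dict[str, int]] = []
    accuracies = np.empty(reps)
    rng = np.random.default_rng(seed)
    for rep in range(reps):
        assignment = assign_folds(lines, folds, rng)
        fold_maps.append(assignment)
        preds: dict[str, float] = {}
        for f in range(folds):
            masked = {l for l, g in assignment.items() if g == f}
            train = _mask_lines(pheno, spec.trait, masked)
            train_trials = set(train.values(spec.trait)["trial"].unique())
            lost = all_trials - train_trials
            if lost:
                raise FitError(
                    f"fold {f} removed every record of trial(s) {sorted(lost)}; "
                    "their fixed effects are inestimable - use fewer folds"
                )
            fit = fit_reml(train, spec, max_iter=max_iter, tol=tol)
            wg = predict_whole_genome(fit, include_structure=include_structure)
            for l in masked:
                preds[l] = float(wg.loc[l])
        common = [l for l in lines if l in true_values.index]
        pred_vec = np.array([preds[l] for l in common])
        true_vec = true_values.loc[common].to_numpy()
        if pred_vec.std() == 0.0 or true_vec.std() == 0.0:
            # a constant vector (e.g. all genetic terms shrunk to the
            # boundary under zero heritability) carries no signal
            accuracies[rep] = 0.0
        else:
            accuracies[rep] = float(np.corrcoef(pred_vec, true_vec)[0, 1])
        logger.info("CV replicate %d/%d: accuracy %.4f", rep + 1, reps, accuracies[rep])
    return CVResult(folds=fold_maps, seed=seed, accuracies=accuracies)
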