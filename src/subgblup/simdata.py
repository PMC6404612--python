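"""Synthetic allohexaploid populations with known subgenome architecture.

Genotypes are inbred {0,1} minor-allele indicators on three subgenomes (A,
B, D) with unequal marker counts and diversity - the D subgenome, being the
most recent and most bottlenecked wheat subgenome, gets fewer markers drawn
from a narrower allele-frequency range. Subpopulation structure follows a
Balding-Nichols-style divergence model: each subpopulation's allele
frequency is drawn around the ancestral frequency with variance
``F p (1 - p)``.

Phenotypes follow the subgenome decomposition of the total genetic effect,
G = A + B + D + AB + AD + BD + ABD: per-subgenome additive effects from
centered marker scores with normal effect sizes, and inter-genomic
epistatic effects from products of centered cross-subgenome marker pairs at
a sampled set of causal pairs. Each term is rescaled so its realized
variance equals the configured component exactly. Records mimic an
unbalanced multi-environment trial: most lines appear in a single random
trial while a small set of check lines is replicated across every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import MarkerSet, PhenoTable

SUBGENOMES = ("A", "B", "D")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic population.

    Defaults describe a mid-sized inbred breeding population: 500 lines in
    three subpopulations with moderate divergence (F = 0.05), 1500 markers
    split 550/650/300 over A/B/D, mostly-additive architecture
    (sigma2 A:B:D = 0.3:0.4:0.1 against residual 1.0, epistasis off unless
    configured), and each line evaluated in 3 of 6 trials with 2%
    fully-replicated checks - the multi-environment record depth that keeps
    line and residual variances separable in an identity-covariance fit.
    """

    n_lines: int = 500
    m_per_subgenome: tuple[int, int, int] = (550, 650, 300)
    n_subpop: int = 3
    divergence: float = 0.05
    maf_floor: float = 0.02
    sigma2_A: float = 0.3
    sigma2_B: float = 0.4
    sigma2_D: float = 0.1
    sigma2_AB: float = 0.0
    sigma2_AD: float = 0.0
    sigma2_BD: float = 0.0
    sigma2_ABD: float = 0.0
    sigma2_e: float = 1.0
    n_trials: int = 6
    records_per_line: int = 3
    check_fraction: float = 0.02
    missing_rate: float = 0.0
    trial_effect_sd: float = 0.5
    n_causal_pairs: int = 200
    trait: str = "yield"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_A", "sigma2_B", "sigma2_D", "sigma2_AB", "sigma2_AD",
                     "sigma2_BD", "sigma2_ABD", "sigma2_e"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if any(m < 1 for m in self.m_per_subgenome):
            raise SimulationError("each subgenome needs at least 1 marker")
        if not 0.0 <= self.maf_floor < 0.5:
            raise SimulationError(f"maf_floor {self.maf_floor} infeasible (must be < 0.5)")
        if self.n_subpop < 1 or self.n_lines < self.n_subpop:
            raise SimulationError("need n_lines >= n_subpop >= 1")

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "A": self.sigma2_A, "B": self.sigma2_B, "D": self.sigma2_D,
            "AB": self.sigma2_AB, "AD": self.sigma2_AD, "BD": self.sigma2_BD,
            "ABD": self.sigma2_ABD,
        }


@dataclass
class SimTruth:
    """Ground truth of a simulated phenotype."""

    effects: pd.DataFrame  # n_lines x terms, true per-term effect vectors
    variance_fractions: dict[str, float]
    causal_pairs: dict[str, np.ndarray]
    seed: int

    @property
    def total(self) -> pd.Series:
        return self.effects.sum(axis=1)


# per-subgenome ancestral allele-frequency ranges: A and B carry the bulk of
# the diversity; D is narrower (recent single-lineage origin)
_FREQ_HI = {"A": 0.5, "B": 0.5, "D": 0.25}


def simulate_genotypes(config: SimConfig) -> tuple[MarkerSet, np.ndarray]:
    """Draw an inbred {0,1} marker matrix with subpopulation structure.

    Returns the marker set (chromosome labels 1A..7D assigned cyclically
    within each subgenome, subgenome field populated) and the integer
    subpopulation label of each line. Columns whose realized MAF falls
    below the floor are redrawn.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lines
    sizes = [n // config.n_subpop] * config.n_subpop
    sizes[-1] += n - sum(sizes)
    subpop = np.repeat(np.arange(config.n_subpop), sizes)
    cols: list[np.ndarray] = []
    chrom: list[str] = []
    subg: list[str] = []
    F = config.divergence
    for sg, m in zip(SUBGENOMES, config.m_per_subgenome):
        lo = max(config.maf_floor, 0.01)
        hi = _FREQ_HI[sg]
        for j in range(m):
            col = _draw_marker(rng, subpop, sizes, lo, hi, F, config.maf_floor)
            cols.append(col)
            chrom.append(f"{1 + j % 7}{sg}")
            subg.append(sg)
    scores = np.column_stack(cols).astype(float)
    line_ids = tuple(f"L{i + 1:04d}" for i in range(n))
    marker_ids = tuple(f"M{sg}{j + 1:04d}" for sg, m in zip(SUBGENOMES, config.m_per_subgenome) for j in range(m))
    ms = MarkerSet(scores, line_ids, marker_ids, chrom=tuple(chrom), subgenome=tuple(subg), coding=(0, 1))
    return ms, subpop


def _draw_marker(rng, subpop, sizes, lo, hi, F, maf_floor, max_tries: int = 100) -> np.ndarray:
    for _ in range(max_tries):
        p_anc = rng.uniform(lo, hi)
        if F > 0:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            p_sub = rng.beta(a, b, size=len(sizes))
        else:
            p_sub = np.full(len(sizes), p_anc)
        col = rng.random(len(subpop)) < p_sub[subpop]
        freq = col.mean()
        if min(freq, 1 - freq) >= max(maf_floor, 1e-9):
            return col.astype(float)
    raise SimulationError(f"could not draw a marker with realized MAF >= {maf_floor}")


def simulate_phenotypes(marker_set: MarkerSet, config: SimConfig) -> tuple[PhenoTable, SimTruth]:
    """Simulate trial records from a subgenome-decomposed genetic model.

    Each genetic term (A, B, D additive; AB, AD, BD pairwise; ABD three-way)
    is built from the centered scores and rescaled so its realized line
    variance equals the configured component exactly; terms with a zero
    component are identically zero. Trial effects and residual noise are
    then added over an unbalanced record layout.
    """
    if marker_set.n_missing:
        raise SimulationError("marker set must be complete (imputed) before phenotype simulation")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9151]))
    W = marker_set.scores - marker_set.scores.mean(axis=0)
    blocks = {sg: np.flatnonzero(np.array(marker_set.subgenome) == sg) for sg in SUBGENOMES}
    for sg, idx in blocks.items():
        if idx.size == 0:
            raise SimulationError(f"subgenome {sg} has no markers")
    n = marker_set.n_lines
    effects: dict[str, np.ndarray] = {}
    causal: dict[str, np.ndarray] = {}
    for sg in SUBGENOMES:
        s2 = config.variance_components[sg]
        a = rng.standard_normal(blocks[sg].size)
        effects[sg] = _rescale(W[:, blocks[sg]] @ a, s2)
    for term in ("AB", "AD", "BD", "ABD"):
        s2 = config.variance_components[term]
        parts = [blocks[sg] for sg in term]
        n_avail = int(np.prod([len(p) for p in parts]))
        k = min(config.n_causal_pairs, n_avail)
        if s2 > 0 and k == 0:
            raise SimulationError(f"no causal marker combinations available for term {term}")
        picks = np.column_stack([rng.choice(p, size=k, replace=True) for p in parts])
        coef = rng.standard_normal(k)
        design = np.ones((n, k))
        for d in range(len(parts)):
            design *= W[:, picks[:, d]]
        effects[term] = _rescale(design @ coef, s2)
        causal[term] = picks
    eff = pd.DataFrame(effects, index=list(marker_set.line_ids))
    g = eff.sum(axis=1).to_numpy()

    # unbalanced trial layout with replicated checks
    trials = [f"T{t + 1:02d}" for t in range(config.n_trials)]
    trial_eff = rng.normal(0.0, config.trial_effect_sd, size=config.n_trials)
    n_checks = int(round(config.check_fraction * n))
    check_idx = set(rng.choice(n, size=n_checks, replace=False)) if n_checks else set()
    rows = []
    for i, lid in enumerate(marker_set.line_ids):
        if i in check_idx:
            rec_trials = range(config.n_trials)
        else:
            rec_trials = rng.choice(config.n_trials, size=config.records_per_line, replace=False)
        for t in rec_trials:
            y = trial_eff[t] + g[i] + rng.normal(0.0, np.sqrt(config.sigma2_e))
            if config.missing_rate and rng.random() < config.missing_rate:
                y = np.nan
            rows.append((lid, trials[t], y))
    records = pd.DataFrame(rows, columns=["line", "trial", config.trait])
    total_var = sum(config.variance_components.values()) + config.sigma2_e
    fractions = {t: v / total_var for t, v in config.variance_components.items()}
    truth = SimTruth(effects=eff, variance_fractions=fractions, causal_pairs=causal, seed=config.seed)
    return PhenoTable(records), truth


def _rescale(u: np.ndarray, target_var: float) -> np.ndarray:
    if target_var == 0.0:
        return np.zeros_like(u)
    u = u - u.mean()
    v = float(np.var(u, ddof=1))
    if v <= 0:
        raise SimulationError("degenerate effect vector; cannot rescale to a positive variance")
    return u * np.sqrt(target_var / v)


def simulate_from_model(
    random_terms,
    sigma2,
    sigma2_e: float = 1.0,
    records_per_line: int = 2,
    n_trials: int = 4,
    trial_effect_sd: float = 0.5,
    trait: str = "yield",
    seed: int = 0,
) -> tuple[PhenoTable, SimTruth]:
    """Draw phenotypes exactly from a multi-kernel mixed model.

    Each genetic term is sampled as g_l ~ N(0, sigma2[l] * K_l) via the
    kernel's Cholesky factor, so the fitted model and the generating model
    coincide - the clean design for variance-component recovery studies.
    ``random_terms`` is a sequence of (label, GeneticKernel) sharing one
    line ordering; kernels should carry their fitting ridge so they are
    full rank.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 40271]))
    labels = [lb for lb, _ in random_terms]
    line_ids = random_terms[0][1].line_ids
    n = len(line_ids)
    effects = {}
    for lb, kern in random_terms:
        s2 = float(sigma2[lb])
        if kern.line_ids != line_ids:
            raise SimulationError(f"kernel {lb!r} has a different line ordering")
        if s2 == 0.0:
            effects[lb] = np.zeros(n)
            continue
        L = np.linalg.cholesky(kern.values + 1e-10 * np.eye(n))
        effects[lb] = np.sqrt(s2) * (L @ rng.standard_normal(n))
    eff = pd.DataFrame(effects, index=list(line_ids))
    g = eff.sum(axis=1).to_numpy()
    trials = [f"T{t + 1:02d}" for t in range(n_trials)]
    trial_eff = rng.normal(0.0, trial_effect_sd, size=n_trials)
    rows = []
    for i, lid in enumerate(line_ids):
        for t in rng.choice(n_trials, size=records_per_line, replace=False):
            rows.append((lid, trials[t], trial_eff[t] + g[i] + rng.normal(0.0, np.sqrt(sigma2_e))))
    records = pd.DataFrame(rows, columns=["line", "trial", trait])
    total = float(sum(sigma2[lb] for lb in labels)) + sigma2_e
    fractions = {lb: float(sigma2[lb]) / total for lb in labels}
    truth = SimTruth(effects=eff, variance_fractions=fractions, causal_pairs={}, seed=seed)
    return PhenoTable(records), truth


@dataclass
class SimData:
    """One complete synthetic dataset."""

    config: SimConfig
    marker_set: MarkerSet
    subpop: np.ndarray
    pheno: PhenoTable
    truth: SimTruth


def simulate_dataset(config: SimConfig) -> SimData:
    """Genotypes + phenotypes in one call."""
    ms, subpop = simulate_genotypes(config)
    pheno, truth = simulate_phenotypes(ms, config)
    return SimData(config=config, marker_set=ms, subpop=subpop, pheno=pheno, truth=truth)
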