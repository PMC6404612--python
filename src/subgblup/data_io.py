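"""Marker and phenotype input/output, quality control and standardization.

Marker scores are held as a lines x markers matrix of allele counts, either
diploid-coded ({0, 1, 2} copies of the minor allele) or inbred boolean
({0, 1} indicators of the minor allele, the common encoding for selfing
species genotyped by sequencing). Each marker carries a chromosome label in
the hexaploid-wheat ``1A ... 7D`` convention from which its subgenome
(A, B or D) is derived.

Phenotypes are long-format records ``(line, trial, trait value)`` from
unbalanced multi-environment trials; traits are standardized globally
(never within environment) so that genetic variances are expressed in
squared trait-SD units.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("subgblup")

#: default marker quality-control thresholds
DEFAULT_MAF_MIN = 0.01
DEFAULT_MAX_MISSING = 0.30
DEFAULT_MAX_HET = 0.10

_CHROM_RE = re.compile(r"^(?:chr)?([1-7])([ABD])$", re.IGNORECASE)


class DataError(ValueError):
    """Raised for malformed or inconsistent marker/phenotype inputs."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerSet:
    """Lines x markers allele-score matrix with chromosome/subgenome labels.

    Parameters
    ----------
    scores
        ``(n_lines, n_markers)`` float array of allele counts. Missing values
        are ``np.nan``.
    line_ids, marker_ids
        Unique identifiers for rows and columns.
    chrom
        Chromosome label per marker (e.g. ``"1A"``); empty string if unknown.
    subgenome
        Subgenome letter per marker (``"A"``, ``"B"``, ``"D"``), or ``""``
        until :func:`assign_subgenomes` has run.
    coding
        Declared score alphabet: ``(0, 1, 2)`` or ``(0, 1)``.
    """

    scores: np.ndarray
    line_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    chrom: tuple[str, ...] = field(default=())
    subgenome: tuple[str, ...] = field(default=())
    coding: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        n, m = scores.shape
        if len(self.line_ids) != n:
            raise DataError(f"{len(self.line_ids)} line ids for {n} rows")
        if len(self.marker_ids) != m:
            raise DataError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if len(set(self.line_ids)) != n:
            raise DataError("duplicate line ids")
        if len(set(self.marker_ids)) != m:
            raise DataError("duplicate marker ids")
        for name in ("chrom", "subgenome"):
            labels = getattr(self, name)
            if labels == ():
                object.__setattr__(self, name, ("",) * m)
            elif len(labels) != m:
                raise DataError(f"{name} has {len(labels)} labels for {m} markers")
        allowed = set(self.coding)
        observed = scores[~np.isnan(scores)]
        if observed.size and not set(np.unique(observed)) <= allowed:
            bad = sorted(set(np.unique(observed)) - allowed)
            raise DataError(f"scores {bad} outside declared coding {self.coding}")

    @property
    def n_lines(self) -> int:
        return self.scores.shape[0]

    @property
    def n_markers(self) -> int:
        return self.scores.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.scores).sum())

    def subgenome_block(self, sg: str) -> "MarkerSet":
        """Restrict to the markers assigned to subgenome ``sg``."""
        idx = [j for j, s in enumerate(self.subgenome) if s == sg]
        if not idx:
            raise DataError(f"subgenome {sg!r} has no markers")
        return self.take_markers(idx)

    def take_markers(self, idx: Sequence[int]) -> "MarkerSet":
        idx = list(idx)
        return replace(
            self,
            scores=self.scores[:, idx],
            marker_ids=tuple(self.marker_ids[j] for j in idx),
            chrom=tuple(self.chrom[j] for j in idx),
            subgenome=tuple(self.subgenome[j] for j in idx),
        )

    def take_lines(self, idx: Sequence[int]) -> "MarkerSet":
        idx = list(idx)
        return replace(
            self,
            scores=self.scores[idx, :],
            line_ids=tuple(self.line_ids[i] for i in idx),
        )

    def with_scores(self, scores: np.ndarray, coding: tuple[int, ...] | None = None) -> "MarkerSet":
        return replace(self, scores=scores, coding=coding or self.coding)


@dataclass
class PhenoTable:
    """Long-format phenotype records with per-trait standardization state.

    ``records`` has columns ``line``, ``trial`` and one column per trait;
    missing trait values are NaN. ``scale_info`` maps a standardized trait to
    the ``(mean, sd)`` that was removed, enabling back-transformation.
    """

    records: pd.DataFrame
    standardized: dict[str, bool] = field(default_factory=dict)
    scale_info: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("line", "trial"):
            if col not in self.records.columns:
                raise DataError(f"phenotype table lacks required column {col!r}")
        self.records = self.records.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.records.columns if c not in ("line", "trial")]

    def values(self, trait: str) -> pd.DataFrame:
        """Non-missing records of one trait as (line, trial, y)."""
        if trait not in self.traits:
            raise DataError(f"unknown trait {trait!r}")
        sub = self.records[["line", "trial", trait]].dropna(subset=[trait])
        return sub.rename(columns={trait: "y"}).reset_index(drop=True)

    def back_transform(self, trait: str, values: np.ndarray) -> np.ndarray:
        """Return ``values`` on the original trait scale."""
        mean, sd = self.scale_info[trait]
        return np.asarray(values) * sd + mean


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_marker_table(path, fmt: str = "table") -> MarkerSet:
    """Read a marker score matrix from a tab-delimited table or a VCF.

    The table dialect is lines-as-rows: a header row of marker ids, first
    column line ids, cells in the score alphabet with missing cells empty or
    ``NA``. VCF genotypes are collapsed to alternate-allele counts per
    sample and then recoded to minor-allele counts.

    Coding is auto-detected: ``(0, 1)`` if no score of 2 is observed,
    else ``(0, 1, 2)``.
    """
    if fmt == "table":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=["NA", ""])
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate line ids in {path}: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate marker ids in {path}: {dups[:5]}")
        scores = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
        line_ids = tuple(str(i) for i in df.index)
        marker_ids = tuple(str(c) for c in df.columns)
    elif fmt == "vcf":
        scores, line_ids, marker_ids = _read_vcf(path)
    else:
        raise DataError(f"unknown marker format {fmt!r}")
    coding = _detect_coding(scores)
    return MarkerSet(scores, line_ids, marker_ids, coding=coding)


def _detect_coding(scores: np.ndarray) -> tuple[int, ...]:
    observed = scores[~np.isnan(scores)]
    return (0, 1) if not np.any(observed == 2) else (0, 1, 2)


def _read_vcf(path) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    from cyvcf2 import VCF  # deferred: VCF support is optional

    vcf = VCF(str(path))
    line_ids = tuple(vcf.samples)
    cols: list[np.ndarray] = []
    marker_ids: list[str] = []
    for i, variant in enumerate(vcf):
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types, dtype=float)
        alt_count = np.select([gt == 2, gt == 3], [np.nan, 2.0], default=gt)
        marker_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        cols.append(alt_count)
    vcf.close()
    if not cols:
        raise DataError(f"no variants in {path}")
    scores = np.column_stack(cols)
    # recode to minor-allele counts so the frequency spectrum matches the
    # boolean minor-allele convention of the table dialect
    freq = np.nanmean(scores, axis=0) / 2.0
    flip = freq > 0.5
    scores[:, flip] = 2.0 - scores[:, flip]
    dup = pd.Index(marker_ids)
    if dup.has_duplicates:
        raise DataError(f"duplicate marker ids in {path}")
    return scores, line_ids, tuple(marker_ids)


def load_marker_map(path) -> pd.DataFrame:
    """Read a marker map (marker, chromosome, position columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    marker_col = next((cols[k] for k in ("marker", "snp", "id") if k in cols), df.columns[0])
    chrom_col = next((cols[k] for k in ("chromosome", "chrom", "chr") if k in cols), df.columns[1])
    out = df[[marker_col, chrom_col]].rename(columns={marker_col: "marker", chrom_col: "chromosome"})
    return out


def load_phenotypes(path) -> PhenoTable:
    """Read a long-format phenotype table (line, trial, trait columns)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    cols = {c.lower(): c for c in df.columns}
    ren = {}
    for want, aliases in (("line", ("line", "gid", "genotype", "id")), ("trial", ("trial", "env", "environment"))):
        for a in aliases:
            if a in cols:
                ren[cols[a]] = want
                break
        else:
            raise DataError(f"phenotype table lacks a {want} column")
    df = df.rename(columns=ren)
    df["line"] = df["line"].astype(str)
    df["trial"] = df["trial"].astype(str)
    return PhenoTable(df)


# ---------------------------------------------------------------------------
# subgenome assignment
# ---------------------------------------------------------------------------


def assign_subgenomes(
    marker_set: MarkerSet,
    marker_map: pd.DataFrame | Mapping[str, str],
    chrom_to_subgenome: Mapping[str, str] | None = None,
) -> MarkerSet:
    """Attach chromosome labels and derive the subgenome of every marker.

    Subgenome = trailing letter of a ``1A ... 7D`` chromosome name; an
    explicit ``chrom_to_subgenome`` override table handles nonstandard
    labels. Every marker in the matrix must appear in the map.
    """
    if isinstance(marker_map, pd.DataFrame):
        mapping = dict(zip(marker_map["marker"].astype(str), marker_map["chromosome"].astype(str)))
    else:
        mapping = {str(k): str(v) for k, v in marker_map.items()}
    chrom: list[str] = []
    subg: list[str] = []
    for mid in marker_set.marker_ids:
        if mid not in mapping:
            raise DataError(f"marker {mid!r} present in matrix but absent from map")
        label = mapping[mid]
        chrom.append(label)
        subg.append(_subgenome_of(label, chrom_to_subgenome))
    return replace(marker_set, chrom=tuple(chrom), subgenome=tuple(subg))


def _subgenome_of(label: str, override: Mapping[str, str] | None) -> str:
    if override and label in override:
        sg = str(override[label]).upper()
        if sg not in {"A", "B", "D"}:
            raise DataError(f"override for {label!r} maps to {sg!r}, not one of A/B/D")
        return sg
    m = _CHROM_RE.match(label)
    if not m:
        raise DataError(
            f"chromosome label {label!r} does not match the 1A..7D convention "
            "and no override was supplied"
        )
    return m.group(2).upper()


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def minor_allele_frequency(scores: np.ndarray, coding: tuple[int, ...]) -> np.ndarray:
    """Per-marker MAF from non-missing calls.

    With {0,1,2} coding a het contributes one copy of each allele; with
    {0,1} coding MAF is ``min(mean, 1 - mean)`` of the boolean scores.
    """
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(scores, axis=0)
    freq = mean / 2.0 if 2 in coding else mean
    return np.minimum(freq, 1.0 - freq)


def filter_markers(
    marker_set: MarkerSet,
    maf_min: float = DEFAULT_MAF_MIN,
    max_missing: float = DEFAULT_MAX_MISSING,
    max_het: float = DEFAULT_MAX_HET,
) -> MarkerSet:
    """Drop markers failing the MAF / missingness / heterozygosity rules.

    A marker survives iff MAF >= ``maf_min``, fraction missing <=
    ``max_missing`` and fraction heterozygous (score 1 under {0,1,2}
    coding) <= ``max_het``. The rules are applied jointly, so the survivor
    set does not depend on any rule order. Counts removed per rule are
    logged.
    """
    for name, v in (("maf_min", maf_min), ("max_missing", max_missing), ("max_het", max_het)):
        if not 0.0 <= v <= 1.0:
            raise DataError(f"{name}={v} outside [0, 1]")
    S = marker_set.scores
    n = marker_set.n_lines
    missing = np.isnan(S)
    frac_missing = missing.mean(axis=0)
    n_called = n - missing.sum(axis=0)
    maf = minor_allele_frequency(S, marker_set.coding)
    maf = np.where(n_called == 0, 0.0, np.nan_to_num(maf))
    if 2 in marker_set.coding:
        frac_het = np.where(n_called > 0, (S == 1).sum(axis=0) / np.maximum(n_called, 1), 0.0)
    else:
        frac_het = np.zeros(marker_set.n_markers)  # inbred boolean coding has no hets
    fail_maf = maf < maf_min
    fail_missing = frac_missing > max_missing
    fail_het = frac_het > max_het
    keep = ~(fail_maf | fail_missing | fail_het)
    logger.info(
        "marker QC: %d/%d kept (removed %d by MAF<%g, %d by missing>%g, %d by het>%g)",
        int(keep.sum()), marker_set.n_markers,
        int(fail_maf.sum()), maf_min, int(fail_missing.sum()), max_missing,
        int(fail_het.sum()), max_het,
    )
    if not keep.any():
        raise DataError("all markers removed by quality filters")
    return marker_set.take_markers(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute_mode(
    marker_set: MarkerSet,
    het_policy: str = "to_mode",
    imputer: Callable[[np.ndarray], np.ndarray] | None = None,
) -> MarkerSet:
    """Replace missing calls with the per-marker mode.

    With ``het_policy="to_mode"`` and {0,1,2} coding, heterozygous calls are
    first replaced by the modal homozygote (ties between homozygote counts
    break toward the lower score, i.e. the reference/major homozygote, with
    a warning). A user-supplied ``imputer`` taking and returning the full
    score matrix may replace the mode rule for the missing values.
    """
    if het_policy not in ("to_mode", "keep"):
        raise DataError(f"unknown het_policy {het_policy!r}")
    S = marker_set.scores.copy()
    homozygote_levels = [lv for lv in marker_set.coding if lv != 1] if 2 in marker_set.coding else list(marker_set.coding)
    if 2 in marker_set.coding and het_policy == "to_mode":
        for j in range(S.shape[1]):
            col = S[:, j]
            if not np.any(col == 1):
                continue
            mode = _column_mode(col, homozygote_levels, marker_set.marker_ids[j])
            col[col == 1] = mode
    if imputer is not None:
        S = imputer(S)
        if np.isnan(S).any():
            raise DataError("user imputer left missing values")
    else:
        levels = homozygote_levels if (2 in marker_set.coding and het_policy == "to_mode") else list(marker_set.coding)
        for j in range(S.shape[1]):
            col = S[:, j]
            miss = np.isnan(col)
            if not miss.any():
                continue
            mode = _column_mode(col, levels, marker_set.marker_ids[j])
            col[miss] = mode
    return marker_set.with_scores(S)


def _column_mode(col: np.ndarray, levels: Sequence[float], marker_id: str) -> float:
    counts = [(lv, int(np.sum(col == lv))) for lv in levels]
    best = max(c for _, c in counts)
    winners = [lv for lv, c in counts if c == best]
    if len(winners) > 1:
        logger.warning("mode tie for marker %s; breaking toward score %g", marker_id, min(winners))
    return float(min(winners))


# ---------------------------------------------------------------------------
# phenotype standardization
# ---------------------------------------------------------------------------


def standardize_phenotypes(pheno: PhenoTable, traits: Sequence[str] | None = None) -> PhenoTable:
    """Center and scale each trait globally to mean 0, SD 1.

    Standardization is over the pooled phenotype vector, never within
    environment, so between-trial differences are preserved on the new
    scale. The removed (mean, SD) is kept for back-transformation.
    """
    traits = list(traits) if traits is not None else pheno.traits
    df = pheno.records.copy()
    scale_info = dict(pheno.scale_info)
    standardized = dict(pheno.standardized)
    for trait in traits:
        if trait not in pheno.traits:
            raise DataError(f"unknown trait {trait!r}")
        v = df[trait].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if np.unique(v[ok]).size < 2:
            raise DataError(f"trait {trait!r} is constant; cannot standardize")
        mean = float(v[ok].mean())
        sd = float(v[ok].std(ddof=1))
        df[trait] = (v - mean) / sd
        scale_info[trait] = (mean, sd)
        standardized[trait] = True
    return PhenoTable(df, standardized=standardized, scale_info=scale_info)


# ---------------------------------------------------------------------------
# writing (round-trip with the loaders above)
# ---------------------------------------------------------------------------


def write_marker_table(marker_set: MarkerSet, path) -> None:
    fmt = {0.0: "0", 1.0: "1", 2.0: "2"}
    df = pd.DataFrame(
        [[("NA" if np.isnan(v) else fmt.get(v, repr(v))) for v in row] for row in marker_set.scores],
        index=list(marker_set.line_ids),
        columns=list(marker_set.marker_ids),
    )
    df.to_csv(path, sep="\t", index_label="line")


def write_marker_map(marker_set: MarkerSet, path) -> None:
    pd.DataFrame(
        {"marker": marker_set.marker_ids, "chromosome": marker_set.chrom, "position": range(1, marker_set.n_markers + 1)}
    ).to_csv(path, sep="\t", index=False)


def write_phenotypes(pheno: PhenoTable, path) -> None:
    pheno.records.to_csv(path, sep="\t", index=False, na_rep="NA")
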