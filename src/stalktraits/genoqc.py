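"""Genotype calling and site-level QC for read-count matrices.

Calling rule for an inbred panel, applied per site x individual to raw
allele read counts: the site must have at least ``min_depth`` reads; an
allele "passes" when its frequency among the reads is strictly greater
than ``min_allele_freq`` AND it was observed at least ``min_allele_count``
times; exactly one passing allele yields a call, zero or two-plus passing
alleles (apparent heterozygote) yield MISSING.

Site filters: discard sites whose missing-call fraction is at or above a
class-specific ceiling (0.80 for reference-anchored sites, 0.95 for
assembled-transcript sites), and sites whose minor allele frequency across
non-missing calls is strictly below 0.05.

Imputation accuracy is the proportion of imputed (originally missing)
sites whose imputed call matches an independent reference call, per
individual and averaged over individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ALLELES",
    "QcThresholds",
    "call_genotype",
    "call_matrix",
    "missing_fraction",
    "minor_allele_frequency",
    "filter_sites_by_missingness",
    "filter_sites_by_maf",
    "imputation_accuracy",
    "bonferroni_neglog_threshold",
]

MISSING = "."
ALLELES = ("A", "C", "G", "T")
SITE_CLASSES = ("reference", "assembled")


@dataclass(frozen=True)
class QcThresholds:
    """Calling and filtering thresholds.

    Defaults follow the RNA-Seq SNP pipeline convention: a call needs
    >= 5 reads, an allele counts only when its read fraction is > 5% and
    it was seen >= 2 times; reference-anchored sites tolerate < 80%
    missingness and assembled-transcript sites < 95%; GWAS sites need
    MAF >= 0.05.
    """

    min_depth: int = 5
    min_allele_freq: float = 0.05  # strict >
    min_allele_count: int = 2  # inclusive >=
    site_missing_max_reference: float = 0.80  # discard at >= this fraction
    site_missing_max_assembled: float = 0.95
    gwas_maf_min: float = 0.05  # discard strictly below
    bonferroni_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_allele_count < 0:
            raise ValueError("count thresholds must be non-negative")
        if not 0 <= self.min_allele_freq < 1:
            raise ValueError("min_allele_freq must lie in [0, 1)")
        for f in (self.site_missing_max_reference, self.site_missing_max_assembled):
            if not 0 < f <= 1:
                raise ValueError("site missingness ceilings must lie in (0, 1]")
        if not 0 <= self.gwas_maf_min <= 0.5:
            raise ValueError("gwas_maf_min must lie in [0, 0.5]")
        if not 0 < self.bonferroni_alpha < 1:
            raise ValueError("bonferroni_alpha must lie in (0, 1)")


def call_genotype(
    counts: Mapping[str, int], thresholds: QcThresholds | None = None
) -> str:
    """Call one site x individual cell from its allele read counts."""
    thresholds = thresholds or QcThresholds()
    clean: dict[str, int] = {}
    for allele, n in counts.items():
        if allele not in ALLELES:
            raise ValueError(f"unknown allele symbol {allele!r}")
        if n < 0:
            raise ValueError("read counts must be non-negative")
        if n:
            clean[allele] = int(n)
    depth = sum(clean.values())
    if depth < thresholds.min_depth:
        return MISSING
    passing = [
        a
        for a, n in clean.items()
        if n / depth > thresholds.min_allele_freq and n >= thresholds.min_allele_count
    ]
    if len(passing) == 1:
        return passing[0]
    return MISSING  # zero passers, or apparent heterozygote


def call_matrix(
    counts: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    sites: Iterable[str] | None = None,
    individuals: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Call a sites x individuals genotype matrix from long-format counts.

    ``counts`` columns: site, individual, allele, count. Cells with no
    reads at all are MISSING. ``sites``/``individuals`` fix the output
    grid (useful when zero-depth cells are absent from the table).
    """
    thresholds = thresholds or QcThresholds()
    for col in ("site", "individual", "allele", "count"):
        if col not in counts.columns:
            raise ValueError(f"counts table lacks column {col!r}")
    site_list = list(sites) if sites is not None else sorted(counts["site"].unique())
    ind_list = (
        list(individuals)
        if individuals is not None
        else sorted(counts["individual"].unique())
    )
    wide = counts.pivot_table(
        index=["site", "individual"],
        columns="allele",
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
    for allele in ALLELES:
        if allele not in wide.columns:
            wide[allele] = 0
    arr = wide[list(ALLELES)].to_numpy(dtype=float)
    depth = arr.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.divide(arr, depth[:, None], out=np.zeros_like(arr), where=depth[:, None] > 0)
    passing = (frac > thresholds.min_allele_freq) & (arr >= thresholds.min_allele_count)
    n_pass = passing.sum(axis=1)
    callable_ = (depth >= thresholds.min_depth) & (n_pass == 1)
    winner = passing.argmax(axis=1)
    calls = np.where(callable_, np.array(ALLELES)[winner], MISSING)

    out = pd.DataFrame(MISSING, index=site_list, columns=ind_list, dtype=object)
    cell = pd.Series(calls, index=wide.index)
    for (site, ind), call in cell.items():
        if site in out.index and ind in out.columns:
            out.loc[site, ind] = call
    out.index.name = "site"
    return out


def missing_fraction(matrix: pd.DataFrame) -> pd.Series:
    """Per-site fraction of MISSING calls."""
    return (matrix == MISSING).mean(axis=1).rename("missing_fraction")


def minor_allele_frequency(matrix: pd.DataFrame) -> pd.Series:
    """Per-site MAF across non-missing calls (0 for monomorphic or empty)."""
    mafs = {}
    for site, row in matrix.iterrows():
        calls = row[row != MISSING]
        n = len(calls)
        if n == 0:
            mafs[site] = 0.0
            continue
        counts = calls.value_counts()
        mafs[site] = float((n - counts.iloc[0]) / n)
    return pd.Series(mafs, name="maf")


def filter_sites_by_missingness(
    matrix: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    site_class: str | pd.Series = "reference",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard sites whose missing fraction reaches the class ceiling.

    ``site_class`` is 'reference' / 'assembled' for all sites, or a
    per-site Series of those labels. Returns (filtered matrix, report of
    discarded sites with their fractions and class).
    """
    thresholds = thresholds or QcThresholds()
    if isinstance(site_class, str):
        classes = pd.Series(site_class, index=matrix.index)
    else:
        classes = site_class.reindex(matrix.index)
    bad = ~classes.isin(SITE_CLASSES)
    if bad.any():
        raise ValueError(
            f"unknown site class(es): {sorted(classes[bad].dropna().unique())} "
            f"(sites {list(classes.index[bad])[:5]}...)"
        )
    frac = missing_fraction(matrix)
    ceiling = classes.map(
        {
            "reference": thresholds.site_missing_max_reference,
            "assembled": thresholds.site_missing_max_assembled,
        }
    )
    discard = frac >= ceiling
    report = pd.DataFrame(
        {
            "missing_fraction": frac[discard],
            "site_class": classes[discard],
            "ceiling": ceiling[discard],
        }
    )
    report.index.name = "site"
    return matrix.loc[~discard], report


def filter_sites_by_maf(
    matrix: pd.DataFrame, thresholds: QcThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Discard sites with MAF strictly below the floor (0.05 by default).

    Sites at exactly the floor are retained; monomorphic sites (MAF 0)
    are always discarded. Returns (filtered matrix, discard report).
    """
    thresholds = thresholds or QcThresholds()
    maf = minor_allele_frequency(matrix)
    discard = maf < thresholds.gwas_maf_min
    report = pd.DataFrame({"maf": maf[discard]})
    report.index.name = "site"
    return matrix.loc[~discard], report


def imputation_accuracy(
    imputed: pd.DataFrame,
    reference: pd.DataFrame,
    original: pd.DataFrame | None = None,
    only_imputed: bool = True,
) -> tuple[pd.Series, float, list[str]]:
    """Concordance of imputed calls with an independent reference.

    Per individual, accuracy = matching cells / comparable cells, where a
    cell is comparable when both matrices are non-missing there and — when
    ``only_imputed`` and ``original`` is given — the cell was MISSING
    before imputation (accuracy over the positions imputation actually
    filled). Individuals with zero comparable cells are excluded from the
    mean and returned in the third element.
    """
    common_sites = imputed.index.intersection(reference.index)
    common_inds = imputed.columns.intersection(reference.columns)
    if len(common_sites) == 0 or len(common_inds) == 0:
        raise ValueError("imputed and reference matrices share no cells")
    imp = imputed.loc[common_sites, common_inds]
    ref = reference.loc[common_sites, common_inds]
    comparable = (imp != MISSING) & (ref != MISSING)
    if only_imputed and original is not None:
        orig = original.reindex(index=common_sites, columns=common_inds)
        comparable &= orig.isna() | (orig == MISSING)
    match = (imp == ref) & comparable

    n_comp = comparable.sum(axis=0)
    n_match = match.sum(axis=0)
    excluded = [str(i) for i in n_comp.index[n_comp == 0]]
    with np.errstate(invalid="ignore"):
        acc = n_match / n_comp
    acc = acc[n_comp > 0].astype(float).rename("accuracy")
    if acc.empty:
        raise ValueError("no individual has comparable cells")
    return acc, float(acc.mean()), excluded


def bonferroni_neglog_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """-log10(alpha / n_tests): the Bonferroni genome-wide cutoff on the
    -log10(p) scale. Pipelines should treat the published cutoff they aim
    to match as configuration; this helper only evaluates the formula."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(-math.log10(alpha / n_tests))
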