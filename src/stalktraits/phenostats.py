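"""Multi-environment trait statistics.

For a balanced randomized-complete-block trial repeated across
environments (years), with genotype, environment, replication-within-
environment and genotype-by-environment all treated as random effects:

    y_ijk = mu + G_i + E_j + R_k(j) + GE_ij + eps_ijk

variance components are estimated by equating balanced-design ANOVA mean
squares to their expectations (on balanced data these coincide with REML
whenever all solutions are interior), broad-sense heritability on an
entry-mean basis is

    h2 = var_G / (var_G + var_GE / y + var_e / (r * y))

with y environments and r replications, and per-genotype trait values are
the grand mean plus the BLUP of the genotype effect, which for a balanced
design is the shrunken genotype-mean deviation

    BLUP_i = h2 * (ybar_i.. - ybar...).

Scalar helpers cover the trait summaries reported for such trials:
max/min fold difference, control-vs-transgenic percent reduction, and
internode length as plant height / node count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "TraitEstimates",
    "TraitSummary",
    "UnbalancedTableError",
    "check_balanced",
    "estimate_variance_components",
    "heritability",
    "blup_trait_values",
    "gxe_f_test",
    "summarize_trait",
    "fold_difference",
    "spearman_matrix",
    "percent_reduction",
    "internode_length",
]

REQUIRED_COLUMNS = ("genotype", "environment", "replication", "value")


class UnbalancedTableError(ValueError):
    """The trait table is not a complete balanced genotype x env x rep grid."""


@dataclass(frozen=True)
class VarianceComponents:
    var_G: float
    var_E: float
    var_RwithinE: float
    var_GE: float
    var_e: float
    y: int  # environments (years)
    r: int  # replications per environment
    n_genotypes: int
    truncated: tuple[str, ...] = ()  # components clamped at zero
    ge_fixed_zero: bool = False  # single-environment design: GE not estimable


@dataclass(frozen=True)
class TraitEstimates:
    grand_mean: float
    blups: pd.Series  # per-genotype BLUP deviations
    trait_values: pd.Series  # grand_mean + BLUP
    heritability: float


@dataclass(frozen=True)
class TraitSummary:
    mean: float
    sd: float
    min: float
    max: float
    fold_difference: float | None  # None (flagged) when min <= 0


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table lacks columns: {missing}")
    if table.duplicated(subset=["genotype", "environment", "replication"]).any():
        raise ValueError("duplicate (genotype, environment, replication) keys")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("trait values must be finite")
    return table


def check_balanced(table: pd.DataFrame) -> tuple[int, int, int]:
    """Return (n_genotypes, n_environments, n_replications) or raise."""
    _validate_table(table)
    g = table["genotype"].nunique()
    y = table["environment"].nunique()
    r = table["replication"].nunique()
    counts = table.groupby(["genotype", "environment"], observed=True)["value"].count()
    if len(table) != g * y * r or len(counts) != g * y or not (counts == r).all():
        raise UnbalancedTableError(
            "table is not a complete balanced genotype x environment x "
            "replication grid; balance it (e.g. drop incomplete genotypes) first"
        )
    return g, y, r


def estimate_variance_components(table: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments (expected mean squares) on a balanced table.

    Negative solutions are clamped to zero and recorded in ``truncated``.
    With a single environment the GE component is not estimable and is
    fixed at zero (flagged via ``ge_fixed_zero``).
    """
    g, y, r = check_balanced(table)
    if g < 2:
        raise ValueError("need at least two genotypes")
    if r < 2:
        raise ValueError("need at least two replications")

    cell = table.pivot_table(
        index="genotype", columns=["environment", "replication"], values="value",
        observed=True,
    )
    data = cell.to_numpy(dtype=float).reshape(g, y, r)

    grand = data.mean()
    m_g = data.mean(axis=(1, 2))  # genotype means
    m_e = data.mean(axis=(0, 2))  # environment means
    m_ge = data.mean(axis=2)  # genotype x environment means
    m_er = data.mean(axis=0)  # environment x replication means

    ss_g = r * y * np.sum((m_g - grand) ** 2)
    ss_e = r * g * np.sum((m_e - grand) ** 2)
    ss_re = g * np.sum((m_er - m_e[:, None]) ** 2)
    ss_ge = r * np.sum((m_ge - m_g[:, None] - m_e[None, :] + grand) ** 2)
    resid = data - m_ge[:, :, None] - m_er[None, :, :] + m_e[None, :, None]
    ss_err = np.sum(resid**2)

    ms_g = ss_g / (g - 1)
    ms_err = ss_err / ((g - 1) * y * (r - 1)) if (g - 1) * y * (r - 1) > 0 else 0.0
    ms_re = ss_re / (y * (r - 1)) if y * (r - 1) > 0 else 0.0

    truncated: list[str] = []

    def clamp(name: str, value: float) -> float:
        if value < 0:
            truncated.append(name)
            return 0.0
        return value

    if y > 1:
        ms_e = ss_e / (y - 1)
        ms_ge = ss_ge / ((g - 1) * (y - 1))
        var_e = clamp("var_e", ms_err)
        var_ge = clamp("var_GE", (ms_ge - ms_err) / r)
        var_g = clamp("var_G", (ms_g - ms_ge) / (r * y))
        var_re = clamp("var_RwithinE", (ms_re - ms_err) / g)
        var_env = clamp("var_E", (ms_e - ms_ge - ms_re + ms_err) / (r * g))
        ge_fixed = False
    else:
        # single environment: GE and error are confounded
        var_e = clamp("var_e", ms_err)
        var_ge = 0.0
        var_g = clamp("var_G", (ms_g - ms_err) / r)
        var_re = clamp("var_RwithinE", (ms_re - ms_err) / g)
        var_env = 0.0
        ge_fixed = True

    return VarianceComponents(
        var_G=float(var_g),
        var_E=float(var_env),
        var_RwithinE=float(var_re),
        var_GE=float(var_ge),
        var_e=float(var_e),
        y=y,
        r=r,
        n_genotypes=g,
        truncated=tuple(truncated),
        ge_fixed_zero=ge_fixed,
    )


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability on an entry-mean basis.

    h2 = var_G / (var_G + var_GE / y + var_e / (r * y)).
    """
    if vc.y < 1 or vc.r < 1:
        raise ValueError("y and r must be at least 1")
    denom = vc.var_G + vc.var_GE / vc.y + vc.var_e / (vc.r * vc.y)
    if denom <= 0:
        raise ValueError("all variance components are zero; heritability undefined")
    return float(vc.var_G / denom)


def blup_trait_values(table: pd.DataFrame, vc: VarianceComponents) -> TraitEstimates:
    """Grand mean + BLUP genotype deviations for a balanced table.

    The balanced-design BLUP of the genotype effect shrinks the genotype
    mean deviation by the entry-mean heritability.
    """
    check_balanced(table)
    h2 = heritability(vc)
    grand = float(table["value"].mean())
    geno_means = table.groupby("genotype", observed=True)["value"].mean()
    blups = h2 * (geno_means - grand)
    blups.name = "blup"
    values = grand + blups
    values.name = "trait_value"
    return TraitEstimates(
        grand_mean=grand, blups=blups, trait_values=values, heritability=h2
    )


def gxe_f_test(table: pd.DataFrame) -> tuple[float, float]:
    """F-test of the genotype-by-environment interaction (MS_GE / MS_error)."""
    g, y, r = check_balanced(table)
    if y < 2 or r < 2:
        raise ValueError("GxE test needs >= 2 environments and >= 2 replications")
    cell = table.pivot_table(
        index="genotype", columns=["environment", "replication"], values="value",
        observed=True,
    )
    data = cell.to_numpy(dtype=float).reshape(g, y, r)
    grand = data.mean()
    m_g = data.mean(axis=(1, 2))
    m_e = data.mean(axis=(0, 2))
    m_ge = data.mean(axis=2)
    m_er = data.mean(axis=0)
    ss_ge = r * np.sum((m_ge - m_g[:, None] - m_e[None, :] + grand) ** 2)
    resid = data - m_ge[:, :, None] - m_er[None, :, :] + m_e[None, :, None]
    ss_err = np.sum(resid**2)
    df_ge = (g - 1) * (y - 1)
    df_err = (g - 1) * y * (r - 1)
    ms_ge = ss_ge / df_ge
    ms_err = ss_err / df_err
    f = ms_ge / ms_err
    p = float(stats.f.sf(f, df_ge, df_err))
    return float(f), p


# ---------------------------------------------------------------------------
# Scalar summaries
# ---------------------------------------------------------------------------


def fold_difference(minimum: float, maximum: float) -> float:
    """max/min rounded to two decimals (requires min > 0)."""
    if minimum <= 0:
        raise ValueError("fold difference requires a positive minimum")
    return round(maximum / minimum, 2)


def summarize_trait(values) -> TraitSummary:
    """Mean, sample SD, range and fold difference of per-genotype values."""
    arr = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("need at least two finite values")
    vmin, vmax = float(arr.min()), float(arr.max())
    fold = fold_difference(vmin, vmax) if vmin > 0 else None
    return TraitSummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        min=vmin,
        max=vmax,
        fold_difference=fold,
    )


def spearman_matrix(estimates: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations between trait columns.

    Ranks use midranks for ties. Pairs with fewer than ``min_shared``
    jointly observed genotypes, or with a constant vector, yield NaN.
    """
    cols = list(estimates.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pair = estimates[[a, b]].dropna()
            if len(pair) < min_shared:
                rho = float("nan")
            else:
                va, vb = pair[a].to_numpy(float), pair[b].to_numpy(float)
                if np.ptp(va) == 0 or np.ptp(vb) == 0:
                    rho = float("nan")
                else:
                    rho = float(stats.spearmanr(va, vb).statistic)
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def percent_reduction(control_mean: float, transgenic_mean: float) -> int:
    """Percent reduction relative to control, rounded to the nearest integer."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    pct = 100.0 * (control_mean - transgenic_mean) / control_mean
    # round half away from zero so 19.5 -> 20, -19.5 -> -20
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def internode_length(plant_height_cm: float, node_count: int) -> float:
    """Mean internode length: plant height divided by node count."""
    if node_count < 1:
        raise ValueError("node_count must be at least 1")
    if plant_height_cm < 0:
        raise ValueError("plant height must be non-negative")
    return plant_height_cm / node_count
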