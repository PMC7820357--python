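"""Derived evolutionary quantities from mutation parameters.

* equilibrium GC content alpha/(alpha+beta) from the AT->GC and GC->AT
  conditional class rates;
* equilibrium heterozygosity mu_bs/(mu_bs + mu_gc) under a
  mutation/gene-conversion balance;
* effective population size from neutral diversity, Ne = pi/(4 mu);
* broad-sense heritability and evolvability of the mutation rate as a
  trait, from a one-way random-effects decomposition of line-level rates
  grouped by genotype;
* Spearman correlation with its t approximation, and one-way ANOVA with
  Tukey HSD for comparisons across populations.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class QuantGenError(ValueError):
    pass


def gc_equilibrium(class_rates: Mapping[str, float]) -> float:
    """Expected GC fraction at mutational equilibrium.

    alpha = r(A:T>G:C) + r(A:T>C:G) per A:T site (AT->GC flux);
    beta = r(C:G>A:T) + r(C:G>T:A) per C:G site (GC->AT flux);
    returns alpha/(alpha+beta).  Invariant to rescaling all rates.
    """
    alpha = class_rates.get("A:T>G:C", 0.0) + class_rates.get("A:T>C:G", 0.0)
    beta = class_rates.get("C:G>A:T", 0.0) + class_rates.get("C:G>T:A", 0.0)
    if alpha < 0 or beta < 0:
        raise QuantGenError("class rates must be >= 0")
    if alpha == 0 and beta == 0:
        raise QuantGenError("no GC-changing mutation flux: equilibrium undefined")
    return alpha / (alpha + beta)


def expected_heterozygosity(mu_bs: float, mu_gc: float) -> float:
    """Equilibrium heterozygosity under mutation vs. gene conversion.

    H = mu_bs/(mu_bs + mu_gc): new substitutions create heterozygous
    sites, conversion removes them.  Monotone increasing in mu_bs and
    decreasing in mu_gc.
    """
    if mu_bs < 0 or mu_gc < 0:
        raise QuantGenError("rates must be >= 0")
    if mu_bs + mu_gc == 0:
        raise QuantGenError("both rates zero: equilibrium undefined")
    return mu_bs / (mu_bs + mu_gc)


def effective_population_size(pi_s: float, mu: float) -> float:
    """Ne = pi_s / (4 mu) from neutral diversity at synonymous sites."""
    if mu <= 0:
        raise QuantGenError("mu must be > 0")
    if pi_s < 0:
        raise QuantGenError("pi_s must be >= 0")
    return pi_s / (4.0 * mu)


@dataclasses.dataclass
class QuantGenResult:
    """One-way random-effects decomposition of a trait.

    ``V_G`` is the among-genotype variance component, ``V_E`` the
    within-genotype (among-line) residual, ``H2 = V_G/(V_G+V_E)`` the
    broad-sense heritability.  Two evolvability conventions are emitted:
    mean-squared-scaled ``I_G = V_G / mean^2`` and mean-scaled
    ``V_G / mean``.  ``truncated`` flags a negative method-of-moments
    V_G clamped to zero.
    """

    V_G: float
    V_E: float
    H2: float
    evolvability_mean_squared: float
    evolvability_mean: float
    grand_mean: float
    truncated: bool
    scheme: str = "one-way random effects (expected mean squares)"


def heritability_evolvability(
    values: Sequence[float], groups: Sequence[str]
) -> QuantGenResult:
    """Variance components of line-level rates grouped by genotype.

    V_E = MS_within; V_G = (MS_between - MS_within)/n0 with
    n0 = (N - sum n_i^2 / N)/(k - 1), the effective group size for
    unbalanced designs.  Requires >= 2 genotypes with >= 2 lines each.
    H2 is NaN (flagged undefined) when V_G + V_E = 0.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    sizes = df.groupby("group").size()
    if len(sizes) < 2:
        raise QuantGenError("need >= 2 genotypes")
    if (sizes < 2).any():
        raise QuantGenError("need >= 2 lines per genotype")
    N = len(df)
    k = len(sizes)
    grand = df["value"].mean()
    means = df.groupby("group")["value"].mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(
        ((df["value"] - df["group"].map(means)) ** 2).sum()
    )
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - float((sizes**2).sum()) / N) / (k - 1)
    v_g = (ms_between - ms_within) / n0
    truncated = v_g < 0
    if truncated:
        warnings.warn("negative method-of-moments V_G truncated to 0")
        v_g = 0.0
    v_e = ms_within
    total = v_g + v_e
    h2 = v_g / total if total > 0 else np.nan
    if total == 0:
        warnings.warn("zero total variance: H2 undefined")
    return QuantGenResult(
        V_G=v_g,
        V_E=v_e,
        H2=h2,
        evolvability_mean_squared=v_g / grand**2 if grand != 0 else np.nan,
        evolvability_mean=v_g / grand if grand != 0 else np.nan,
        grand_mean=float(grand),
        truncated=truncated,
    )


@dataclasses.dataclass
class CorrelationResult:
    rho: float
    t: float
    df: int
    p: float
    method: str = "spearman"


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> CorrelationResult:
    """Rank correlation with the t approximation t = rho*sqrt((n-2)/(1-rho^2)).

    Perfectly monotone pairs give |rho| = 1 and an infinite t (flagged
    with a warning, p = 0).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise QuantGenError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise QuantGenError("need >= 3 pairs")
    if method == "spearman":
        rho = float(stats.spearmanr(x, y).statistic)
    elif method == "pearson":
        rho = float(stats.pearsonr(x, y).statistic)
    else:
        raise QuantGenError(f"unknown method {method!r}")
    df = n - 2
    if abs(rho) >= 1.0:
        warnings.warn("perfect monotone association: t statistic infinite")
        t = np.inf if rho > 0 else -np.inf
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(rho=rho, t=float(t), df=df, p=float(p), method=method)


@dataclasses.dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    transform: str
    tukey: pd.DataFrame | None


def population_anova(
    values: Sequence[float],
    groups: Sequence[str],
    transform: str = "none",
) -> AnovaResult:
    """One-way ANOVA of (optionally log10-transformed) rates across groups.

    Tukey HSD pairwise comparisons are attached when every group has at
    least two observations (they require a within-group error term).
    """
    vals = np.asarray(list(values), dtype=float)
    grp = np.asarray(list(groups), dtype=object)
    if transform == "log10":
        if np.any(vals <= 0):
            raise QuantGenError("log10 transform requires positive values")
        vals = np.log10(vals)
    elif transform != "none":
        raise QuantGenError(f"unknown transform {transform!r}")
    labels = pd.unique(grp)
    if len(labels) < 2:
        raise QuantGenError("need >= 2 groups")
    arrays = [vals[grp == lab] for lab in labels]
    res = stats.f_oneway(*arrays)
    df1 = len(labels) - 1
    df2 = len(vals) - len(labels)
    tukey = None
    if min(len(a) for a in arrays) >= 2:
        hsd = pairwise_tukeyhsd(vals, grp)
        tukey = pd.DataFrame(
            hsd.summary().data[1:], columns=hsd.summary().data[0]
        )
    return AnovaResult(
        F=float(res.statistic),
        df1=df1,
        df2=df2,
        p=float(res.pvalue),
        transform=transform,
        tukey=tukey,
    )
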