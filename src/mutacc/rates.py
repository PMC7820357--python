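"""Per-generation mutation-rate estimators, aggregation and bootstrap CIs.

The three estimators:

* nuclear base substitution: mu_bs = x_bs / (g * 2n), with n the haploid
  callable site count (2n diploid bases are at risk);
* mitochondrial base substitution (neutral heteroplasmy accounting):
  mu_m = sum_i f_i / (g * n), with f_i the allele frequency of
  heteroplasmy i and n the mitochondrial callable length;
* gene conversion: mu_g = x_g / (g * n_het), with x_g converted sites and
  n_het ancestral heterozygous sites.

Rates aggregate at four levels (line, genotype, population, species)
under two schemes: ``pooled`` (sum of events over sum of exposures -
exposure-weighted, the default) and ``mean_of_means`` (the unweighted
mean of the next level down).  Confidence intervals come from a
percentile bootstrap that resamples lines, the independent unit of an MA
design.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd


class RateError(ValueError):
    pass


LEVELS = ("line", "genotype", "population", "species")
_GROUP_COLUMN = {
    "line": "line_id",
    "genotype": "genotype_id",
    "population": "population_id",
}


@dataclasses.dataclass
class RateEstimate:
    """A rate with its provenance: counts, exposure and optional CI."""

    level: str
    partition: str
    kind: str
    value: float
    units: str
    event_count: float
    exposure: float
    group: str = ""
    scheme: str = "pooled"
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise RateError("rate must be >= 0")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.value + 1e-12 and self.value <= self.ci_high + 1e-12):
                raise RateError("CI must bracket the point estimate")


def nuclear_bs_rate(x_bs: float, g: float, n_callable_haploid: float) -> float:
    """x_bs / (g * 2n): per diploid base per generation."""
    if g < 1:
        raise RateError("g must be >= 1")
    if n_callable_haploid <= 0:
        raise RateError("zero callable exposure: rate undefined")
    if x_bs < 0:
        raise RateError("event count must be >= 0")
    return x_bs / (g * 2.0 * n_callable_haploid)


def mito_bs_rate(frequencies: Sequence[float], g: float, n_mito: float) -> float:
    """sum(f_i) / (g * n): per base per generation, assuming neutrality."""
    if g < 1:
        raise RateError("g must be >= 1")
    if n_mito <= 0:
        raise RateError("zero mito exposure: rate undefined")
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size and (np.any(freqs <= 0) or np.any(freqs > 1)):
        raise RateError("heteroplasmy frequencies must lie in (0, 1]")
    return float(freqs.sum()) / (g * n_mito)


def conversion_rate(x_g: float, g: float, n_het: float) -> float:
    """x_g / (g * n_het): per ancestral heterozygous site per generation."""
    if g < 1:
        raise RateError("g must be >= 1")
    if n_het <= 0:
        raise RateError("no ancestral heterozygous sites: rate undefined")
    if x_g < 0:
        raise RateError("converted-site count must be >= 0")
    return x_g / (g * n_het)


def line_rate_table(
    events: pd.Series,
    exposures: pd.Series,
    genotype_of_line: pd.Series | dict,
    population_of_line: pd.Series | dict,
) -> pd.DataFrame:
    """Assemble the per-line events/exposure frame used by aggregation.

    *events* may be counts (nuclear, conversion) or frequency sums (mito);
    *exposures* are site-generations (g*2n, g*n or g*n_het per line).
    """
    events = pd.Series(events, dtype=float)
    exposures = pd.Series(exposures, dtype=float)
    idx = exposures.index
    df = pd.DataFrame(
        {
            "line_id": idx,
            "events": events.reindex(idx, fill_value=0.0).to_numpy(),
            "exposure": exposures.to_numpy(),
            "genotype_id": idx.map(
                genotype_of_line if not isinstance(genotype_of_line, dict) else genotype_of_line.get
            ),
            "population_id": idx.map(
                population_of_line
                if not isinstance(population_of_line, dict)
                else population_of_line.get
            ),
        }
    ).reset_index(drop=True)
    if (df["exposure"] <= 0).any():
        raise RateError("all line exposures must be positive")
    df["rate"] = df["events"] / df["exposure"]
    return df


def aggregate(
    line_table: pd.DataFrame,
    level: str,
    scheme: str = "pooled",
) -> pd.DataFrame:
    """Aggregate line-level events and exposures to a higher level.

    ``pooled``: sum of events over sum of exposures within each group.
    ``mean_of_means``: the unweighted mean of the values one level down
    (genotype = mean of line rates; population = mean of genotype values;
    species = mean of population values).
    Returns a frame with columns group, value, event_count, exposure,
    scheme, level.
    """
    if level not in LEVELS:
        raise RateError(f"unknown level {level!r}")
    if scheme not in ("pooled", "mean_of_means"):
        raise RateError(f"unknown scheme {scheme!r}")
    if not len(line_table):
        raise RateError("empty line table")

    if level == "line":
        out = line_table.assign(
            group=line_table["line_id"], value=line_table["rate"]
        )
        return out[["group", "value", "events", "exposure"]].rename(
            columns={"events": "event_count"}
        ).assign(scheme=scheme, level=level)

    if scheme == "pooled":
        if level == "species":
            grouped = line_table.assign(group="species").groupby("group")
        else:
            grouped = line_table.groupby(
                line_table[_GROUP_COLUMN[level]].rename("group")
            )
        agg = grouped.agg(event_count=("events", "sum"), exposure=("exposure", "sum"))
        agg["value"] = agg["event_count"] / agg["exposure"]
        return (
            agg.reset_index()[["group", "value", "event_count", "exposure"]]
            .assign(scheme=scheme, level=level)
        )

    # mean_of_means: climb the hierarchy one level at a time
    geno = line_table.groupby("genotype_id").agg(
        value=("rate", "mean"),
        event_count=("events", "sum"),
        exposure=("exposure", "sum"),
        population_id=("population_id", "first"),
    )
    if level == "genotype":
        return (
            geno.reset_index()
            .rename(columns={"genotype_id": "group"})[
                ["group", "value", "event_count", "exposure"]
            ]
            .assign(scheme=scheme, level=level)
        )
    pop = geno.groupby("population_id").agg(
        value=("value", "mean"),
        event_count=("event_count", "sum"),
        exposure=("exposure", "sum"),
    )
    if level == "population":
        return (
            pop.reset_index()
            .rename(columns={"population_id": "group"})[
                ["group", "value", "event_count", "exposure"]
            ]
            .assign(scheme=scheme, level=level)
        )
    return pd.DataFrame(
        {
            "group": ["species"],
            "value": [pop["value"].mean()],
            "event_count": [pop["event_count"].sum()],
            "exposure": [pop["exposure"].sum()],
            "scheme": scheme,
            "level": level,
        }
    )


def convert_units(
    rate: float,
    diploid_genome_size: float | None = None,
    generation_time_days: float | None = None,
) -> float:
    """Convert a per-bp/generation rate to per-genome/generation or per-bp/day.

    Exactly one conversion factor must be given: ``diploid_genome_size``
    multiplies (per-genome rate); ``generation_time_days`` divides
    (per-day rate).
    """
    if (diploid_genome_size is None) == (generation_time_days is None):
        raise RateError("give exactly one of diploid_genome_size, generation_time_days")
    if rate < 0:
        raise RateError("rate must be >= 0")
    if diploid_genome_size is not None:
        if diploid_genome_size <= 0:
            raise RateError("genome size must be positive")
        return rate * diploid_genome_size
    if generation_time_days <= 0:
        raise RateError("generation time must be positive")
    return rate / generation_time_days


def bootstrap_ci(
    events: Sequence[float],
    exposures: Sequence[float],
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a pooled rate, resampling lines.

    Lines (event, exposure) pairs are resampled with replacement B times;
    the pooled rate of each replicate forms the bootstrap distribution and
    the (alpha/2, 1-alpha/2) percentiles are returned.  Deterministic for
    a given seed.
    """
    if B < 100:
        raise RateError("B must be >= 100")
    events = np.asarray(list(events), dtype=float)
    exposures = np.asarray(list(exposures), dtype=float)
    if events.shape != exposures.shape or events.ndim != 1:
        raise RateError("events and exposures must be equal-length vectors")
    n = events.size
    if n == 0:
        raise RateError("no lines to resample")
    if n == 1:
        warnings.warn("single line: bootstrap CI is degenerate")
        v = events[0] / exposures[0]
        return (float(v), float(v))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    reps = events[idx].sum(axis=1) / exposures[idx].sum(axis=1)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def rate_ratio_table(
    nuclear: pd.Series,
    mito: pd.Series,
) -> pd.Series:
    """Elementwise mito:nuclear rate ratio by group (e.g. genotype).

    A zero mito rate gives ratio 0; a zero nuclear rate with nonzero mito
    rate is flagged infinite (with a warning).
    """
    nuclear = pd.Series(nuclear, dtype=float)
    mito = pd.Series(mito, dtype=float).reindex(nuclear.index)
    if mito.isna().any():
        raise RateError("nuclear and mito estimates must be paired by group")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mito / nuclear
    ratio[(mito == 0) & (nuclear == 0)] = 0.0
    if np.isinf(ratio).any():
        warnings.warn("zero nuclear rate with nonzero mito rate: infinite ratio")
    return ratio


def estimate_with_ci(
    line_table: pd.DataFrame,
    level: str,
    partition: str,
    kind: str,
    units: str,
    scheme: str = "pooled",
    B: int = 1000,
    seed: int = 0,
) -> list[RateEstimate]:
    """Aggregate and attach bootstrap CIs (pooled scheme only)."""
    agg = aggregate(line_table, level, scheme)
    out = []
    for i, row in enumerate(agg.itertuples(index=False)):
        ci_low = ci_high = None
        nb = 0
        if scheme == "pooled" and level != "line":
            if level == "species":
                sub = line_table
            else:
                sub = line_table[line_table[_GROUP_COLUMN[level]] == row.group]
            if len(sub) >= 2:
                ci_low, ci_high = bootstrap_ci(
                    sub["events"], sub["exposure"], B=B, seed=seed + i
                )
                nb = B
        out.append(
            RateEstimate(
                level=level,
                partition=partition,
                kind=kind,
                value=float(row.value),
                units=units,
                event_count=float(row.event_count),
                exposure=float(row.exposure),
                group=str(row.group),
                scheme=scheme,
                ci_low=ci_low,
                ci_high=ci_high,
                n_bootstrap=nb,
            )
        )
    return out


def estimates_to_frame(estimates: Sequence[RateEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in estimates])
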