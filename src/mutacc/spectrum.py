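"""Mutation spectrum: six collapsed substitution classes, 32 trinucleotide
contexts, conditional rates, Ts:Tv and CpG contrasts.

Substitutions are collapsed onto the strand whose reference base is a
pyrimidine-free representative: the six classes are written with the base
pair on each side, e.g. a G->A change is the same event as C->T and both
collapse to ``C:G>T:A``.  Trinucleotide contexts are collapsed so the
central base is A or C, giving 32 contexts.

Conditional rates divide each count by the callable opportunity of its
class or context: rate = count / (exposure_generations * 2 * denominator),
where the factor 2 converts the haploid site denominator to diploid bases.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .callset_io import BASE_CLASSES, COMPLEMENT, CONTEXTS, ReferenceGenome

#: The six strand-collapsed substitution classes.
CLASSES = [
    "A:T>C:G",
    "A:T>G:C",
    "A:T>T:A",
    "C:G>A:T",
    "C:G>G:C",
    "C:G>T:A",
]

#: Transition classes (the other four are transversions).
TRANSITIONS = ("A:T>G:C", "C:G>T:A")
TRANSVERSIONS = tuple(c for c in CLASSES if c not in TRANSITIONS)

#: CpG contexts: central C immediately followed by G (strand-symmetric
#: under the collapsed representation).
CPG_CONTEXTS = tuple(c for c in CONTEXTS if c[1] == "C" and c[2] == "G")
NON_CPG_C_CONTEXTS = tuple(
    c for c in CONTEXTS if c[1] == "C" and c not in CPG_CONTEXTS
)


class SpectrumError(ValueError):
    pass


def collapse_substitution(ref: str, alt: str) -> str:
    """Collapse a single-base substitution into one of the six classes.

    ``collapse(x->y) == collapse(comp(x)->comp(y))`` for every ordered
    pair, e.g. G->A and C->T both map to ``C:G>T:A``.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise SpectrumError(f"invalid bases {ref!r}->{alt!r}")
    if ref == alt:
        raise SpectrumError(f"ref == alt ({ref!r})")
    if ref in "GT":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}:{COMPLEMENT[ref]}>{alt}:{COMPLEMENT[alt]}"


def collapse_context(trinuc: str) -> str | None:
    """Collapse a 3-mer so the central base is A or C; None if any N."""
    trinuc = trinuc.upper()
    if len(trinuc) != 3 or any(b not in "ACGT" for b in trinuc):
        return None
    if trinuc[1] in "GT":
        trinuc = "".join(COMPLEMENT[b] for b in reversed(trinuc))
    return trinuc


def context_at(reference: ReferenceGenome, contig: str, pos: int) -> str | None:
    """Collapsed trinucleotide context of a 1-based position.

    Circular contigs wrap; linear contig ends (and windows containing N)
    have no context.
    """
    seq = reference.contigs[contig]
    n = len(seq)
    if reference.circular[contig]:
        window = seq[(pos - 2) % n] + seq[pos - 1] + seq[pos % n]
    else:
        if pos < 2 or pos > n - 1:
            return None
        window = seq[pos - 2 : pos + 1]
    return collapse_context(window)


def class_of_context(context: str) -> str:
    """Central-base class (A:T or C:G) of a collapsed context."""
    return "A:T" if context[1] == "A" else "C:G"


@dataclasses.dataclass
class SpectrumTable:
    """Counts, opportunities and conditional rates of a call set.

    ``exposure_generations`` is the summed line-generations contributing
    the counts; denominators are haploid callable site counts and the
    conditional rates are per diploid base (hence the factor 2).
    """

    class_counts: pd.Series
    context_counts: pd.Series
    class_denominators: pd.Series
    context_denominators: pd.Series
    exposure_generations: float

    def __post_init__(self) -> None:
        self.class_counts = self.class_counts.reindex(CLASSES, fill_value=0)
        self.context_counts = self.context_counts.reindex(CONTEXTS, fill_value=0)
        marg = class_marginals(self.context_counts)
        by_class = pd.Series(
            {
                "A:T": int(self.class_counts[list(CLASSES[:3])].sum()),
                "C:G": int(self.class_counts[list(CLASSES[3:])].sum()),
            }
        )
        if not marg.equals(by_class):
            raise SpectrumError(
                "context counts are inconsistent with class counts: "
                f"{marg.to_dict()} vs {by_class.to_dict()}"
            )
        zero_denom = (self.context_denominators.reindex(CONTEXTS, fill_value=0) == 0) & (
            self.context_counts > 0
        )
        if zero_denom.any():
            raise SpectrumError(
                f"counts at zero-denominator contexts: {list(self.context_counts.index[zero_denom])}"
            )

    @property
    def total(self) -> int:
        return int(self.class_counts.sum())

    def class_rates(self) -> pd.Series:
        """Conditional per-class rates, per diploid base per generation."""
        denom = np.array(
            [float(self.class_denominators[c.split(">")[0]]) for c in CLASSES]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = self.class_counts / (self.exposure_generations * 2.0 * denom)
        return rates.replace([np.inf, -np.inf], np.nan).fillna(0.0)

    def context_rates(self) -> pd.Series:
        """Conditional per-context rates, per diploid base per generation."""
        denom = self.context_denominators.reindex(CONTEXTS, fill_value=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = self.context_counts / (self.exposure_generations * 2.0 * denom)
        return rates.replace([np.inf, -np.inf], np.nan).fillna(0.0)

    def central_base_rates(self) -> pd.Series:
        """Aggregate conditional rate for central-A vs central-C sites."""
        out = {}
        for cls in BASE_CLASSES:
            ctxs = [c for c in CONTEXTS if class_of_context(c) == cls]
            count = self.context_counts[ctxs].sum()
            denom = self.context_denominators.reindex(ctxs, fill_value=0).sum()
            out[cls] = (
                count / (self.exposure_generations * 2.0 * denom) if denom else 0.0
            )
        return pd.Series(out)


def class_marginals(context_counts: pd.Series) -> pd.Series:
    """Central-base-class marginals of a 32-context count table."""
    counts = context_counts.reindex(CONTEXTS, fill_value=0)
    out = {"A:T": 0, "C:G": 0}
    for ctx, n in counts.items():
        out[class_of_context(ctx)] += int(n)
    return pd.Series(out)


def context_conditional_rates(
    calls: pd.DataFrame,
    context_denominators: pd.Series,
    exposure_generations: float,
) -> SpectrumTable:
    """Build a :class:`SpectrumTable` from annotated mutation calls.

    *calls* must carry ``collapsed_class`` and ``context`` columns (as
    produced by nuclear detection).  Class denominators are the
    central-base marginals of the context denominators.
    """
    if exposure_generations <= 0:
        raise SpectrumError("exposure must be positive")
    if len(calls):
        class_counts = calls["collapsed_class"].value_counts().reindex(
            CLASSES, fill_value=0
        )
        context_counts = calls["context"].value_counts().reindex(CONTEXTS, fill_value=0)
    else:
        class_counts = pd.Series(0, index=CLASSES)
        context_counts = pd.Series(0, index=CONTEXTS)
    class_denoms = class_marginals(context_denominators)
    return SpectrumTable(
        class_counts=class_counts.astype(np.int64),
        context_counts=context_counts.astype(np.int64),
        class_denominators=class_denoms,
        context_denominators=context_denominators.reindex(CONTEXTS, fill_value=0),
        exposure_generations=float(exposure_generations),
    )


def ts_tv(table: SpectrumTable, weighting: str = "count") -> float:
    """Transition:transversion ratio.

    ``count`` divides raw transition counts by raw transversion counts;
    ``conditional`` uses the conditional class rates instead.  Returns
    ``inf`` (with a warning) when there are no transversions.
    """
    if weighting == "count":
        ts = float(table.class_counts[list(TRANSITIONS)].sum())
        tv = float(table.class_counts[list(TRANSVERSIONS)].sum())
    elif weighting == "conditional":
        rates = table.class_rates()
        ts = float(rates[list(TRANSITIONS)].sum())
        tv = float(rates[list(TRANSVERSIONS)].sum())
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if tv == 0:
        warnings.warn("no transversions observed; Ts:Tv is infinite")
        return np.inf
    return ts / tv


@dataclasses.dataclass
class CpGContrast:
    cpg_rate: float
    non_cpg_rate: float
    t: float
    df: int
    p: float
    differences: pd.Series


def cpg_contrast(context_rates_by_group: pd.DataFrame) -> CpGContrast:
    """Paired CpG vs non-CpG central-C rate comparison across groups.

    *context_rates_by_group* is a frame of conditional context rates with
    one row per group (typically genotype) and 32 context columns.  The
    per-group CpG rate is the unweighted mean over the four NCG contexts;
    the comparison is a paired t-test on (CpG - non-CpG) differences with
    df = n_groups - 1.
    """
    cpg = context_rates_by_group[list(CPG_CONTEXTS)].mean(axis=1)
    non = context_rates_by_group[list(NON_CPG_C_CONTEXTS)].mean(axis=1)
    diffs = cpg - non
    n = len(diffs)
    if n < 2:
        raise SpectrumError("need >= 2 groups for a paired contrast")
    scale = max(float(cpg.abs().max()), float(non.abs().max()), 1e-300)
    if float(diffs.std(ddof=1)) == 0.0:
        # degenerate paired test: zero variance of the differences
        if abs(float(diffs.iloc[0])) <= 1e-9 * scale:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.inf * np.sign(diffs.iloc[0])), 0.0
    else:
        t, p = stats.ttest_rel(cpg, non)
        t, p = float(t), float(p)
    return CpGContrast(
        cpg_rate=float(cpg.mean()),
        non_cpg_rate=float(non.mean()),
        t=t,
        df=n - 1,
        p=p,
        differences=diffs,
    )


def spectrum_homogeneity_test(
    class_counts: pd.Series, class_denominators: pd.Series
) -> tuple[float, int]:
    """Chi-square goodness of fit of class counts against site opportunity.

    The expectation for each class is proportional to the callable sites
    of its reference base pair (each pair offers three classes with equal
    a-priori weight), so a spectrum that simply mirrors base composition
    gives chi-square 0.  df = 5 for six classes.
    """
    obs = class_counts.reindex(CLASSES, fill_value=0).astype(float)
    total = obs.sum()
    if total <= 0:
        raise SpectrumError("no mutations to test")
    opp = np.array([float(class_denominators[c.split(">")[0]]) for c in CLASSES])
    expected = total * opp / opp.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, len(CLASSES) - 1
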