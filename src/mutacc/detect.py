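"""De novo event detection from ancestor vs. descendant call sets.

Three detectors operate on the harmonised call tables:

* :func:`call_nuclear_mutations` - new alleles at ancestrally homozygous
  callable sites, with depth/quality filters and a uniqueness filter
  (a variant shared by several independently propagated lines cannot be
  de novo and is treated as ancestral polymorphism or artifact);
* :func:`call_mito_mutations` - heteroplasmies absent from the ancestor,
  with frequency and alt-read floors;
* :func:`detect_conversion_tracts` - runs of ancestrally heterozygous
  sites rendered homozygous in one line (loss of heterozygosity),
  clustered into tracts by single-linkage with a maximum gap, with a
  depth-ratio guard against hemizygous deletions masquerading as
  conversion.

Detection is a pure function of (call sets, filters): identical inputs
give identical output, row order included.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from . import callset_io as cio
from .callset_io import (
    AncestralState,
    CallsetBundle,
    MALineRecord,
    ReferenceGenome,
)
from .spectrum import collapse_substitution, context_at


class DetectionError(ValueError):
    pass


@dataclasses.dataclass
class FilterConfig:
    """Thresholds applied before accepting a candidate event.

    ``max_depth_factor`` bounds depth at a multiple of the line's mean
    depth (copy-number artifacts); ``lod_depth_ratio_min`` is the
    hemizygous-deletion guard for LOH candidates: a true conversion keeps
    diploid depth, a deletion halves it, so candidates below this
    fraction of the line mean are excluded.
    """

    min_depth: int = 10
    max_depth_factor: float = 2.0
    min_quality: float = 30.0
    require_unique_to_line: bool = True
    mito_min_frequency: float = 0.05
    mito_min_alt_reads: int = 2
    lod_depth_ratio_min: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "min_depth",
            "max_depth_factor",
            "min_quality",
            "mito_min_frequency",
            "mito_min_alt_reads",
            "lod_depth_ratio_min",
        ):
            if getattr(self, name) < 0:
                raise DetectionError(f"{name} must be >= 0")


@dataclasses.dataclass
class ConversionTract:
    """A run of ancestral het sites rendered homozygous in one line."""

    line_id: str
    contig: str
    positions: tuple[int, ...]
    directions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise DetectionError("empty tract")
        if list(self.positions) != sorted(self.positions):
            raise DetectionError("tract positions must be sorted")
        if len(self.directions) != len(self.positions):
            raise DetectionError("one direction per member site required")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def span(self) -> int:
        return self.positions[-1] - self.positions[0] + 1


MUTATION_COLUMNS = [
    "line_id",
    "contig",
    "pos",
    "ref",
    "alt",
    "partition",
    "collapsed_class",
    "context",
    "f_i",
]


def _empty_mutations() -> pd.DataFrame:
    return pd.DataFrame(columns=MUTATION_COLUMNS)


def _records_by_line(records: Sequence[MALineRecord]) -> dict[str, MALineRecord]:
    return {r.line_id: r for r in records}


def _line_mean_depth(table: pd.DataFrame, nuclear_contigs: set[str]) -> float:
    nuc = table[table["contig"].isin(nuclear_contigs)]
    if not len(nuc):
        return 0.0
    return float(nuc["depth"].mean())


def _callable_at(
    reference: ReferenceGenome,
    line_mask: Mapping[str, np.ndarray] | None,
    contigs: pd.Series,
    pos: pd.Series,
) -> np.ndarray:
    out = np.zeros(len(contigs), dtype=bool)
    for contig in contigs.unique():
        sel = (contigs == contig).to_numpy()
        idx = pos.to_numpy()[sel] - 1
        ok = reference.callable_mask[contig][idx]
        if line_mask is not None and contig in line_mask:
            ok = ok & line_mask[contig][idx]
        out[sel] = ok
    return out


def call_nuclear_mutations(
    ancestors: Mapping[str, AncestralState],
    calls: Mapping[str, pd.DataFrame],
    records: Sequence[MALineRecord],
    reference: ReferenceGenome,
    filters: FilterConfig | None = None,
    genotype_of_line: Mapping[str, str] | None = None,
    line_masks: Mapping[str, Mapping[str, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Accepted de novo nuclear substitutions across all lines.

    A site is called iff it is ancestrally homozygous (not in the line's
    ancestor het index), callable in ancestor and line, the line carries a
    new allele (het or hom-alt genotype), depth lies within
    ``[min_depth, max_depth_factor * line mean depth]``, quality passes,
    and (by default) the variant is unique to one line.
    """
    filters = filters or FilterConfig()
    rec_by_line = _records_by_line(records)
    nuclear = set(reference.nuclear_contigs())
    frames = []
    for line_id in sorted(calls):
        if line_id not in rec_by_line:
            raise DetectionError(f"line {line_id!r} absent from metadata")
        genotype_id = (
            genotype_of_line[line_id]
            if genotype_of_line is not None
            else rec_by_line[line_id].genotype_id
        )
        anc = ancestors.get(genotype_id)
        if anc is None:
            raise DetectionError(f"no ancestral state for genotype {genotype_id!r}")
        table = calls[line_id]
        nuc = table[table["contig"].isin(nuclear)]
        mean_depth = _line_mean_depth(table, nuclear)
        cand = nuc[nuc["genotype"].isin([cio.GT_HET, cio.GT_HOM_ALT])].copy()
        if not len(cand):
            continue
        # ancestrally homozygous: exclude the ancestor's het sites
        key = pd.MultiIndex.from_frame(cand[["contig", "pos"]])
        cand = cand[~key.isin(anc.het_index)]
        if not len(cand):
            continue
        ok = _callable_at(
            reference,
            None if line_masks is None else line_masks.get(line_id),
            cand["contig"],
            cand["pos"],
        )
        cand = cand[ok]
        cand = cand[
            (cand["depth"] >= filters.min_depth)
            & (cand["depth"] <= filters.max_depth_factor * mean_depth)
            & (cand["quality"] >= filters.min_quality)
        ]
        if len(cand):
            frames.append(cand.assign(line_id=line_id))
    if not frames:
        return _empty_mutations()
    allcand = pd.concat(frames, ignore_index=True)
    if filters.require_unique_to_line:
        counts = allcand.groupby(["contig", "pos", "alt"])["line_id"].transform("nunique")
        allcand = allcand[counts == 1]
    if not len(allcand):
        return _empty_mutations()
    allcand = allcand.assign(
        partition=cio.NUCLEAR,
        collapsed_class=[
            collapse_substitution(r, a) for r, a in zip(allcand["ref"], allcand["alt"])
        ],
        context=[
            context_at(reference, c, int(p))
            for c, p in zip(allcand["contig"], allcand["pos"])
        ],
        f_i=np.nan,
    )
    out = allcand[MUTATION_COLUMNS].sort_values(["line_id", "contig", "pos"])
    return out.reset_index(drop=True)


def call_mito_mutations(
    ancestors_mito: Mapping[str, pd.DataFrame] | None,
    calls: Mapping[str, pd.DataFrame],
    records: Sequence[MALineRecord],
    reference: ReferenceGenome,
    filters: FilterConfig | None = None,
    genotype_of_line: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Accepted heteroplasmic mitochondrial mutations with frequencies.

    A site is called iff it is absent from the ancestor's mito call set,
    its frequency is at least ``mito_min_frequency`` and its implied
    alternate read count (frequency x depth) is at least
    ``mito_min_alt_reads``.  Frequencies are retained as ``f_i`` for the
    frequency-sum rate estimator.
    """
    filters = filters or FilterConfig()
    mito_contig = reference.mito_contig
    if mito_contig is None:
        raise DetectionError("reference has no mito contig")
    rec_by_line = _records_by_line(records)
    frames = []
    for line_id in sorted(calls):
        if line_id not in rec_by_line:
            raise DetectionError(f"line {line_id!r} absent from metadata")
        genotype_id = (
            genotype_of_line[line_id]
            if genotype_of_line is not None
            else rec_by_line[line_id].genotype_id
        )
        table = calls[line_id]
        cand = table[table["contig"] == mito_contig].copy()
        if not len(cand):
            continue
        freq = cand["allele_frequency"].fillna(1.0)
        if ((freq < 0) | (freq > 1)).any():
            raise DetectionError(f"line {line_id}: allele frequency outside [0, 1]")
        anc_tab = (ancestors_mito or {}).get(genotype_id)
        if anc_tab is not None and len(anc_tab):
            anc_key = pd.MultiIndex.from_frame(anc_tab[["pos", "alt"]])
            key = pd.MultiIndex.from_frame(cand[["pos", "alt"]])
            keep = ~key.isin(anc_key)
            cand, freq = cand[keep], freq[keep]
        alt_reads = np.round(freq * cand["depth"])
        cand = cand[
            (freq >= filters.mito_min_frequency)
            & (alt_reads >= filters.mito_min_alt_reads)
        ]
        if len(cand):
            frames.append(
                cand.assign(
                    line_id=line_id,
                    f_i=cand["allele_frequency"].fillna(1.0),
                )
            )
    if not frames:
        return _empty_mutations()
    out = pd.concat(frames, ignore_index=True).assign(
        partition=cio.MITO, collapsed_class=None, context=None
    )
    out["collapsed_class"] = [
        collapse_substitution(r, a) for r, a in zip(out["ref"], out["alt"])
    ]
    out = out[MUTATION_COLUMNS].sort_values(["line_id", "contig", "pos"])
    return out.reset_index(drop=True)


def cluster_positions(positions: Sequence[int], max_gap: int) -> list[list[int]]:
    """Single-linkage clustering of sorted positions with gap <= max_gap."""
    pos = sorted(int(p) for p in positions)
    if not pos:
        return []
    clusters = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def detect_conversion_tracts(
    ancestors: Mapping[str, AncestralState],
    calls: Mapping[str, pd.DataFrame],
    records: Sequence[MALineRecord],
    reference: ReferenceGenome,
    max_gap: int = 10_000,
    filters: FilterConfig | None = None,
    genotype_of_line: Mapping[str, str] | None = None,
    line_masks: Mapping[str, Mapping[str, np.ndarray]] | None = None,
) -> list[ConversionTract]:
    """Gene-conversion (LOH) tracts per line.

    Candidate sites are ancestral het sites genotyped homozygous in the
    focal line (hom-alt requires the ancestral alternate allele), callable
    in both, passing quality and the hemizygous-deletion depth guard.
    Candidates are clustered into tracts by single-linkage with gap
    <= ``max_gap``.
    """
    filters = filters or FilterConfig()
    rec_by_line = _records_by_line(records)
    nuclear = set(reference.nuclear_contigs())
    tracts: list[ConversionTract] = []
    for line_id in sorted(calls):
        if line_id not in rec_by_line:
            raise DetectionError(f"line {line_id!r} absent from metadata")
        genotype_id = (
            genotype_of_line[line_id]
            if genotype_of_line is not None
            else rec_by_line[line_id].genotype_id
        )
        anc = ancestors.get(genotype_id)
        if anc is None or anc.n_het == 0:
            continue
        table = calls[line_id]
        nuc = table[table["contig"].isin(nuclear)]
        mean_depth = _line_mean_depth(table, nuclear)
        merged = anc.het_sites.merge(
            nuc,
            on=["contig", "pos"],
            how="inner",
            suffixes=("_anc", ""),
        )
        is_loh = (merged["genotype"] == cio.GT_HOM_REF) | (
            (merged["genotype"] == cio.GT_HOM_ALT)
            & (merged["alt"] == merged["alt_anc"])
        )
        cand = merged[is_loh]
        if not len(cand):
            continue
        ok = _callable_at(
            reference,
            None if line_masks is None else line_masks.get(line_id),
            cand["contig"],
            cand["pos"],
        )
        cand = cand[ok]
        cand = cand[
            (cand["quality"] >= filters.min_quality)
            & (cand["depth"] >= filters.min_depth)
            & (cand["depth"] >= filters.lod_depth_ratio_min * mean_depth)
        ]
        if not len(cand):
            continue
        direction_at = {
            (c, int(p)): ("to_ref" if g == cio.GT_HOM_REF else "to_alt")
            for c, p, g in zip(cand["contig"], cand["pos"], cand["genotype"])
        }
        for contig in sorted(cand["contig"].unique()):
            positions = cand.loc[cand["contig"] == contig, "pos"].tolist()
            for cluster in cluster_positions(positions, max_gap):
                tracts.append(
                    ConversionTract(
                        line_id=line_id,
                        contig=contig,
                        positions=tuple(cluster),
                        directions=tuple(
                            direction_at[(contig, p)] for p in cluster
                        ),
                    )
                )
    return tracts


def tract_site_counts(tracts: Sequence[ConversionTract]) -> pd.Series:
    """Converted-site count (x_g) per line."""
    counts: dict[str, int] = {}
    for t in tracts:
        counts[t.line_id] = counts.get(t.line_id, 0) + t.n_sites
    return pd.Series(counts, dtype=np.int64)


def compare_ma_vs_controls(rate_table: pd.DataFrame) -> float:
    """Ratio of the pooled MA rate to the pooled control rate.

    *rate_table* needs columns ``role``, ``events`` and ``exposure``; the
    two control roles are pooled together.  Returns ``inf`` (with a
    warning) when the control rate is zero and the MA rate is not, and
    ``nan`` when both are zero.
    """
    for col in ("role", "events", "exposure"):
        if col not in rate_table.columns:
            raise DetectionError(f"rate table missing column {col!r}")
    roles = set(rate_table["role"])
    if "MA" not in roles:
        raise DetectionError("no MA lines in rate table")
    if not roles & {"starting_control", "extant_control"}:
        raise DetectionError("no control lines in rate table")
    ma = rate_table[rate_table["role"] == "MA"]
    ctrl = rate_table[rate_table["role"] != "MA"]
    ma_rate = ma["events"].sum() / ma["exposure"].sum()
    ctrl_rate = ctrl["events"].sum() / ctrl["exposure"].sum()
    if ctrl_rate == 0:
        if ma_rate == 0:
            return np.nan
        warnings.warn("control rate is zero; MA:control ratio undefined (inf)")
        return np.inf
    return float(ma_rate / ctrl_rate)


def detect_all(
    bundle: CallsetBundle,
    filters: FilterConfig | None = None,
    max_gap: int = 10_000,
    genotype_of_line: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ConversionTract]]:
    """Run all three detectors on a harmonised bundle."""
    nuc = call_nuclear_mutations(
        bundle.ancestors,
        bundle.calls,
        bundle.records,
        bundle.reference,
        filters,
        genotype_of_line,
        bundle.line_masks,
    )
    mito = call_mito_mutations(
        None,
        bundle.calls,
        bundle.records,
        bundle.reference,
        filters,
        genotype_of_line,
    )
    tracts = detect_conversion_tracts(
        bundle.ancestors,
        bundle.calls,
        bundle.records,
        bundle.reference,
        max_gap,
        filters,
        genotype_of_line,
        bundle.line_masks,
    )
    return nuc, mito, tracts
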