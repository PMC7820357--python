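"""Readers, writers and the harmonised in-memory model for MA call sets.

A mutation-accumulation (MA) analysis starts from per-line genotype call
sets (VCF), a reference genome (FASTA), callable-site masks (BED) and a
line metadata table (TSV).  This module loads those into a small set of
plain containers that every downstream stage consumes.

Coordinate conventions
----------------------
All positions exposed by this package are 1-based and closed (the VCF
convention).  BED input/output is 0-based half-open and converted at the
boundary.  Callable masks are stored internally as boolean numpy arrays
indexed ``pos - 1``.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEAR = "nuclear"
MITO = "mito"

GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GENOTYPES = (GT_HOM_REF, GT_HET, GT_HOM_ALT)

ROLES = ("MA", "starting_control", "extant_control")

#: Column layout of a per-line variant-call table.
CALL_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "genotype",
    "allele_frequency",
    "depth",
    "quality",
]

METADATA_COLUMNS = [
    "line_id",
    "genotype_id",
    "population_id",
    "generations",
    "generation_time_days",
    "role",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# byte -> base code (A=0, C=1, G=2, T=3, anything else 4)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

#: The 32 strand-collapsed trinucleotide contexts (central base A or C).
CONTEXTS = [l + c + r for l in "ACGT" for c in "AC" for r in "ACGT"]

BASE_CLASSES = ("A:T", "C:G")


class CallsetError(ValueError):
    """Raised on malformed or inconsistent call-set inputs."""


def seq_codes(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclasses.dataclass
class ReferenceGenome:
    """Reference sequences with partition tags, circularity and masks.

    Parameters
    ----------
    contigs
        Mapping of contig name to its base string over ``{A,C,G,T,N}``.
    partition
        ``"nuclear"`` or ``"mito"`` per contig.  At most one mito contig.
    circular
        Circularity flag per contig (the mitochondrial genome is circular).
    callable_mask
        Boolean array per contig (True = callable), same length as the
        sequence.  Defaults to all-callable.
    """

    contigs: dict[str, str]
    partition: dict[str, str] = dataclasses.field(default_factory=dict)
    circular: dict[str, bool] = dataclasses.field(default_factory=dict)
    callable_mask: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if len(seq) == 0:
                raise CallsetError(f"contig {name!r} has zero length")
            self.partition.setdefault(name, NUCLEAR)
            self.circular.setdefault(name, self.partition[name] == MITO)
            mask = self.callable_mask.get(name)
            if mask is None:
                mask = np.ones(len(seq), dtype=bool)
            else:
                mask = np.asarray(mask, dtype=bool)
                if mask.shape != (len(seq),):
                    raise CallsetError(
                        f"mask length {mask.shape} != sequence length for {name!r}"
                    )
            self.callable_mask[name] = mask
        mito = [n for n, p in self.partition.items() if p == MITO]
        if len(mito) > 1:
            raise CallsetError(f"more than one mito contig: {mito}")

    @property
    def mito_contig(self) -> str | None:
        for name, p in self.partition.items():
            if p == MITO:
                return name
        return None

    def nuclear_contigs(self) -> list[str]:
        return [n for n, p in self.partition.items() if p == NUCLEAR]

    def base(self, contig: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.contigs[contig][pos - 1]

    def is_callable(self, contig: str, pos: int) -> bool:
        return bool(self.callable_mask[contig][pos - 1])


@dataclasses.dataclass
class AncestralState:
    """Diploid state of one ancestral genotype relative to the reference.

    Sites absent from ``het_sites`` are ancestrally homozygous for the
    reference allele.  ``het_sites`` is a frame with columns
    ``contig, pos, ref, alt`` (one row per ancestrally heterozygous site).
    """

    genotype_id: str
    het_sites: pd.DataFrame

    def __post_init__(self) -> None:
        cols = ["contig", "pos", "ref", "alt"]
        if list(self.het_sites.columns) != cols:
            self.het_sites = self.het_sites.reindex(columns=cols)
        self.het_sites = self.het_sites.sort_values(["contig", "pos"]).reset_index(
            drop=True
        )
        bad = self.het_sites["ref"] == self.het_sites["alt"]
        if bad.any():
            raise CallsetError("ancestral het site with ref == alt")

    @property
    def n_het(self) -> int:
        return len(self.het_sites)

    @property
    def het_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.het_sites[["contig", "pos"]])


@dataclasses.dataclass
class MALineRecord:
    """Metadata for one experimental line.

    ``g`` is the number of propagation generations, ``n_callable_nuclear``
    the haploid number of callable nuclear sites (the rate denominator uses
    2n diploid bases), and ``role`` distinguishes MA lines from the
    large-population controls sequenced alongside them.
    """

    line_id: str
    genotype_id: str
    population_id: str
    g: int
    generation_time_days: float
    n_callable_nuclear: int
    n_callable_mito: int
    role: str = "MA"

    def __post_init__(self) -> None:
        if self.g < 1:
            raise CallsetError(f"line {self.line_id}: generations must be >= 1")
        if self.generation_time_days <= 0:
            raise CallsetError(f"line {self.line_id}: generation time must be > 0")
        if self.n_callable_nuclear < 0 or self.n_callable_mito < 0:
            raise CallsetError(f"line {self.line_id}: negative callable exposure")
        if self.role not in ROLES:
            raise CallsetError(
                f"line {self.line_id}: role {self.role!r} not in {ROLES}"
            )


@dataclasses.dataclass
class CallsetBundle:
    """Everything one analysis run consumes, harmonised."""

    reference: ReferenceGenome
    ancestors: dict[str, AncestralState]
    records: list[MALineRecord]
    calls: dict[str, pd.DataFrame]
    line_masks: dict[str, dict[str, np.ndarray]] | None = None

    def record(self, line_id: str) -> MALineRecord:
        for rec in self.records:
            if rec.line_id == line_id:
                return rec
        raise CallsetError(f"no metadata for line {line_id!r}")


def empty_calls() -> pd.DataFrame:
    """An empty variant-call table with the canonical columns."""
    return pd.DataFrame(
        {
            "contig": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=object),
            "alt": pd.Series(dtype=object),
            "genotype": pd.Series(dtype=object),
            "allele_frequency": pd.Series(dtype=float),
            "depth": pd.Series(dtype=np.int64),
            "quality": pd.Series(dtype=float),
        }
    )


def sort_calls(calls: pd.DataFrame, reference: ReferenceGenome) -> pd.DataFrame:
    order = {name: i for i, name in enumerate(reference.contigs)}
    key = calls["contig"].map(order)
    return (
        calls.assign(_k=key)
        .sort_values(["_k", "pos"], kind="stable")
        .drop(columns="_k")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# BED masks
# ---------------------------------------------------------------------------

def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """True-runs of a boolean mask as 0-based half-open (start, end) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def intervals_to_mask(intervals: Sequence[tuple[int, int]], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        if start < 0 or end > length or start > end:
            raise CallsetError(f"interval ({start}, {end}) outside contig of length {length}")
        mask[start:end] = True
    return mask


def write_bed(path: Path | str, masks: Mapping[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for contig, mask in masks.items():
            for start, end in mask_to_intervals(mask):
                fh.write(f"{contig}\t{start}\t{end}\n")


def read_bed(path: Path | str, reference: ReferenceGenome) -> dict[str, np.ndarray]:
    """Read a BED mask, returning a boolean array per contig in *reference*."""
    masks = {name: np.zeros(len(seq), dtype=bool) for name, seq in reference.contigs.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end"],
        usecols=[0, 1, 2], comment="#", dtype={0: str},
    )
    for row in df.itertuples(index=False):
        if row.contig not in masks:
            raise CallsetError(f"BED contig {row.contig!r} not in reference")
        length = len(reference.contigs[row.contig])
        if not (0 <= row.start <= row.end <= length):
            raise CallsetError(f"BED interval {row.contig}:{row.start}-{row.end} out of range")
        masks[row.contig][row.start : row.end] = True
    return masks


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_reference_fasta(path: Path | str, reference: ReferenceGenome) -> None:
    records = []
    for name, seq in reference.contigs.items():
        desc = (
            f"partition={reference.partition[name]} "
            f"circular={'true' if reference.circular[name] else 'false'}"
        )
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path: Path | str) -> ReferenceGenome:
    contigs: dict[str, str] = {}
    partition: dict[str, str] = {}
    circular: dict[str, bool] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs[rec.id] = str(rec.seq).upper()
        tokens = dict(
            t.split("=", 1) for t in rec.description.split() if "=" in t
        )
        partition[rec.id] = tokens.get("partition", NUCLEAR)
        circular[rec.id] = tokens.get("circular", "false").lower() == "true"
    if not contigs:
        raise CallsetError(f"no sequences in FASTA {path}")
    return ReferenceGenome(contigs=contigs, partition=partition, circular=circular)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_TO_TUPLE = {GT_HOM_REF: (0, 0), GT_HET: (0, 1), GT_HOM_ALT: (1, 1)}
_TUPLE_TO_GT = {v: k for k, v in _GT_TO_TUPLE.items()}


def _vcf_header(reference: ReferenceGenome, sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, seq in reference.contigs.items():
        header.contigs.add(name, length=len(seq))
    header.info.add("AF", "A", "Float", "Alternate allele frequency (heteroplasmy)")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample)
    return header


def write_vcf(
    path: Path | str,
    reference: ReferenceGenome,
    calls: pd.DataFrame,
    sample: str,
) -> None:
    """Write one line's call table as a single-sample VCF v4.2 file."""
    header = _vcf_header(reference, sample)
    calls = sort_calls(calls, reference)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in calls.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.contig, start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            rec.qual = float(row.quality)
            rec.samples[sample]["GT"] = _GT_TO_TUPLE[row.genotype]
            rec.samples[sample]["DP"] = int(row.depth)
            if pd.notna(row.allele_frequency):
                rec.info["AF"] = (round(float(row.allele_frequency), 6),)
            vcf.write(rec)


def read_vcf(path: Path | str) -> tuple[str, pd.DataFrame]:
    """Read a single-sample VCF into (sample name, call table).

    Multi-allelic records are split into bi-allelic calls, one row per
    alternate allele carried by the sample.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise CallsetError(f"{path}: expected exactly one sample, got {samples}")
        sample = samples[0]
        for rec in vcf:
            gt = rec.samples[sample].get("GT")
            dp = rec.samples[sample].get("DP")
            af = rec.info.get("AF")
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                if gt is None or None in gt:
                    raise CallsetError(f"{path}: missing genotype at {rec.contig}:{rec.pos}")
                # project the multi-allelic genotype onto this alt
                n_alt = sum(1 for a in gt if a == ai)
                if n_alt == 0 and len(alts) > 1:
                    continue
                proj = {0: GT_HOM_REF, 1: GT_HET, 2: GT_HOM_ALT}[n_alt]
                freq = np.nan
                if af is not None:
                    freq = round(float(af[ai - 1]), 6)
                rows.append(
                    (
                        rec.contig,
                        rec.pos,
                        rec.ref,
                        alt,
                        proj,
                        freq,
                        int(dp) if dp is not None else 0,
                        float(rec.qual) if rec.qual is not None else np.nan,
                    )
                )
    if not rows:
        return sample, empty_calls()
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return sample, df


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def write_metadata(path: Path | str, records: Sequence[MALineRecord]) -> None:
    df = pd.DataFrame(
        [
            (
                r.line_id,
                r.genotype_id,
                r.population_id,
                r.g,
                r.generation_time_days,
                r.role,
                r.n_callable_nuclear,
                r.n_callable_mito,
            )
            for r in records
        ],
        columns=METADATA_COLUMNS + ["n_callable_nuclear", "n_callable_mito"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise CallsetError(f"metadata {path}: missing required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Assembling a bundle
# ---------------------------------------------------------------------------

def _callable_intersection(
    reference: ReferenceGenome,
    line_mask: Mapping[str, np.ndarray] | None,
    partition: str,
) -> int:
    total = 0
    for name in reference.contigs:
        if reference.partition[name] != partition:
            continue
        mask = reference.callable_mask[name]
        if line_mask is not None and name in line_mask:
            mask = mask & line_mask[name]
        total += int(mask.sum())
    return total


def read_callsets(
    vcf_paths: Mapping[str, Path | str],
    fasta_path: Path | str,
    bed_paths: Mapping[str, Path | str] | None,
    metadata_path: Path | str,
    ancestor_vcf_paths: Mapping[str, Path | str] | None = None,
) -> CallsetBundle:
    """Load and harmonise a full experiment.

    Parameters
    ----------
    vcf_paths
        Mapping line_id -> per-line VCF path.
    fasta_path
        Reference FASTA; contig descriptions may carry ``partition=`` and
        ``circular=`` tags.
    bed_paths
        Optional mapping of mask BED paths.  The key ``"reference"`` sets
        the genome-level (ancestor) mask; line_id keys set per-line masks.
        Missing masks default to all-callable.
    metadata_path
        Line metadata TSV with columns line_id, genotype_id, population_id,
        generations, generation_time_days, role.
    ancestor_vcf_paths
        Mapping genotype_id -> ancestor VCF (het records define the
        ancestral heterozygous site index).
    """
    reference = read_reference_fasta(fasta_path)
    bed_paths = dict(bed_paths or {})
    if "reference" in bed_paths:
        reference.callable_mask.update(read_bed(bed_paths.pop("reference"), reference))

    meta = read_metadata(metadata_path)
    line_masks: dict[str, dict[str, np.ndarray]] = {}
    for line_id, path in bed_paths.items():
        line_masks[line_id] = read_bed(path, reference)

    records: list[MALineRecord] = []
    for row in meta.itertuples(index=False):
        if row.line_id not in vcf_paths:
            raise CallsetError(f"metadata line {row.line_id!r} has no VCF")
        records.append(
            MALineRecord(
                line_id=str(row.line_id),
                genotype_id=str(row.genotype_id),
                population_id=str(row.population_id),
                g=int(row.generations),
                generation_time_days=float(row.generation_time_days),
                n_callable_nuclear=_callable_intersection(
                    reference, line_masks.get(str(row.line_id)), NUCLEAR
                ),
                n_callable_mito=_callable_intersection(
                    reference, line_masks.get(str(row.line_id)), MITO
                ),
                role=str(row.role),
            )
        )

    calls: dict[str, pd.DataFrame] = {}
    for line_id, path in vcf_paths.items():
        sample, table = read_vcf(path)
        for contig in table["contig"].unique():
            if contig not in reference.contigs:
                raise CallsetError(f"{path}: contig {contig!r} not in reference")
        calls[str(line_id)] = table

    ancestors: dict[str, AncestralState] = {}
    for genotype_id, path in (ancestor_vcf_paths or {}).items():
        _, table = read_vcf(path)
        hets = table.loc[table["genotype"] == GT_HET, ["contig", "pos", "ref", "alt"]]
        ancestors[str(genotype_id)] = AncestralState(
            genotype_id=str(genotype_id), het_sites=hets.reset_index(drop=True)
        )

    return CallsetBundle(
        reference=reference,
        ancestors=ancestors,
        records=records,
        calls=calls,
        line_masks=line_masks or None,
    )


# ---------------------------------------------------------------------------
# Callable-site counting
# ---------------------------------------------------------------------------

def _context_codes(codes: np.ndarray, circular: bool) -> tuple[np.ndarray, np.ndarray]:
    """Collapsed 3-mer context code per site and validity flags.

    Context code = 8*left + 4*(central is C) + right on the collapsed
    strand (central base A or C).  Sites with N anywhere in the window, or
    whose window leaves a linear contig, are invalid.
    """
    left = np.roll(codes, 1)
    right = np.roll(codes, -1)
    valid = (codes < 4) & (left < 4) & (right < 4)
    if not circular:
        valid[0] = False
        valid[-1] = False
    flip = codes >= 2  # central G or T: take the reverse complement strand
    cl = np.where(flip, 3 - right, left)
    cc = np.where(flip, 3 - codes, codes)
    cr = np.where(flip, 3 - left, right)
    ctx = cl.astype(np.int64) * 8 + (cc == 1) * 4 + cr
    return ctx, valid


def count_callable_sites(
    reference: ReferenceGenome,
    by: str = "total",
    mask: Mapping[str, np.ndarray] | None = None,
    partition: str = NUCLEAR,
):
    """Count callable sites, optionally stratified.

    Parameters
    ----------
    by
        ``"total"`` -> int; ``"central_base_class"`` -> Series over
        ``("A:T", "C:G")``; ``"trinucleotide_context"`` -> Series over the
        32 collapsed contexts.  Context counting excludes sites whose 3-bp
        window contains N or falls off a linear contig end (circular
        contigs wrap), so the context total can be smaller than ``total``.
    mask
        Extra mask intersected with the reference callable mask (e.g. a
        line mask).
    partition
        Which genomic partition to count (default nuclear).
    """
    total = 0
    class_counts = pd.Series(0, index=list(BASE_CLASSES), dtype=np.int64)
    ctx_counts = np.zeros(32, dtype=np.int64)
    for name, seq in reference.contigs.items():
        if reference.partition[name] != partition:
            continue
        m = reference.callable_mask[name]
        if mask is not None and name in mask:
            m = m & mask[name]
        codes = seq_codes(seq)
        known = codes < 4
        mm = m & known
        total += int(mm.sum())
        if by == "central_base_class":
            is_cg = (codes == 1) | (codes == 2)
            class_counts["C:G"] += int((mm & is_cg).sum())
            class_counts["A:T"] += int((mm & ~is_cg).sum())
        elif by == "trinucleotide_context":
            ctx, valid = _context_codes(codes, reference.circular[name])
            sel = m & valid
            ctx_counts += np.bincount(ctx[sel], minlength=32)
    if by == "total":
        return total
    if by == "central_base_class":
        return class_counts
    if by == "trinucleotide_context":
        return pd.Series(ctx_counts, index=CONTEXTS, dtype=np.int64)
    raise ValueError(f"unknown stratification {by!r}")


def write_truth_json(path: Path | str, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth_json(path: Path | str) -> dict:
    with open(path) as fh:
        return json.load(fh)
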