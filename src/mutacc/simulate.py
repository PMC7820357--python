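"""Forward simulator of a mutation-accumulation (MA) experiment.

Generates a reference genome (diploid nuclear partition plus a circular
mitochondrial contig), ancestral heterozygosity per starting genotype,
and per-line call sets carrying three classes of planted events:

* de novo nuclear base substitutions (Poisson over diploid
  site-generations, class drawn from a six-class spectrum),
* gene-conversion tracts at ancestral heterozygous sites (per-generation
  initiation with geometric tract extent, fair-coin donor homolog),
* mitochondrial heteroplasmies under neutral Wright-Fisher drift of N
  genome copies per generation.

Every planted event is recorded in a ground-truth ledger so detection and
estimation can be validated by exact round trips.

All randomness derives from a single integer seed through named
``numpy.random.SeedSequence`` substreams (reference, per-genotype
heterozygosity, per-line mutation/conversion/mito/error draws), so a
simulation is reproducible from its configuration alone.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from . import callset_io as cio
from .callset_io import (
    AncestralState,
    CallsetBundle,
    MALineRecord,
    ReferenceGenome,
    empty_calls,
)
from .spectrum import CLASSES

_POPULATION_IDS = ("P1", "P2", "P3")


class SimulationError(ValueError):
    pass


def _default_spectrum() -> dict[str, float]:
    # Transition-biased spectrum (Ts:Tv = 1.54) with C:G>T:A the most
    # common class, the pattern typical of invertebrate nuclear genomes.
    return {
        "A:T>C:G": 0.08,
        "A:T>G:C": 0.2263,
        "A:T>T:A": 0.10,
        "C:G>A:T": 0.13,
        "C:G>G:C": 0.0837,
        "C:G>T:A": 0.38,
    }


@dataclasses.dataclass
class SimulationConfig:
    """Shape and parameters of a simulated MA experiment.

    Defaults mirror a nine-genotype, 66-line Daphnia-style design run for
    g = 30 generations, with the species-wide nuclear substitution rate
    8.96e-9 /bp/generation (per diploid site), gene conversion at
    6.13e-7 /heterozygous site/generation, and a mitochondrial per-copy
    rate of 8.7e-7 /bp/generation over an N = 100 copy bottleneck.
    """

    n_genotypes: int = 9
    lines_per_genotype: int | Sequence[int] = (8, 8, 8, 7, 7, 7, 7, 7, 7)
    generations_per_line: int = 30
    nuclear_length: int = 10_000_000
    mito_length: int = 15_000
    gc_content: float = 0.41
    ancestral_het_density: float = 0.005
    true_mu_bs: float = 8.96e-9
    true_mu_gc: float = 6.13e-7
    tract_length_mean: float = 500.0
    spectrum: dict[str, float] = dataclasses.field(default_factory=_default_spectrum)
    mito_mu: float = 8.7e-7
    mito_copy_number: int = 100
    genotype_error_rate: float = 0.0
    uncallable_fraction: float = 0.0
    mean_depth: float = 30.0
    generation_time_days: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.lines_per_genotype, int):
            self.lines_per_genotype = (self.lines_per_genotype,) * self.n_genotypes
        self.lines_per_genotype = tuple(int(x) for x in self.lines_per_genotype)
        if len(self.lines_per_genotype) != self.n_genotypes:
            raise SimulationError(
                "lines_per_genotype length must equal n_genotypes"
            )
        if self.nuclear_length <= 0 or self.mito_length <= 0:
            raise SimulationError("genome lengths must be positive")
        if not 0 <= self.gc_content <= 1:
            raise SimulationError("gc_content must be in [0, 1]")
        if not 0 <= self.ancestral_het_density < 1:
            raise SimulationError("ancestral_het_density must be in [0, 1)")
        for name in ("true_mu_bs", "true_mu_gc", "mito_mu", "genotype_error_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.generations_per_line < 1:
            raise SimulationError("generations_per_line must be >= 1")
        if self.mito_copy_number < 1:
            raise SimulationError("mito_copy_number must be >= 1")
        if self.tract_length_mean < 1:
            raise SimulationError("tract_length_mean must be >= 1 bp")
        weights = np.array([self.spectrum.get(c, 0.0) for c in CLASSES])
        if set(self.spectrum) - set(CLASSES):
            raise SimulationError(
                f"unknown spectrum classes {set(self.spectrum) - set(CLASSES)}"
            )
        if abs(weights.sum() - 1.0) > 1e-9:
            raise SimulationError("spectrum weights must sum to 1")

    @property
    def n_lines(self) -> int:
        return int(sum(self.lines_per_genotype))

    @property
    def class_weights(self) -> np.ndarray:
        return np.array([self.spectrum.get(c, 0.0) for c in CLASSES])


@dataclasses.dataclass
class SimulationTruth:
    """Ground-truth ledger of every planted event.

    ``nuclear_mutations``: frame (line_id, contig, pos, ref, alt).
    ``conversion_tracts``: list of dicts with line_id, contig, positions,
    direction (``to_ref`` / ``to_alt``).
    ``mito_events``: frame (line_id, contig, pos, ref, alt, frequency).
    ``exposures``: line_id -> (n_callable_nuclear, n_callable_mito).
    """

    nuclear_mutations: pd.DataFrame
    conversion_tracts: list[dict]
    mito_events: pd.DataFrame
    exposures: dict[str, tuple[int, int]]

    def to_json(self) -> dict:
        return {
            "nuclear_mutations": self.nuclear_mutations.to_dict(orient="records"),
            "conversion_tracts": self.conversion_tracts,
            "mito_events": (
                self.mito_events.assign(
                    frequency=self.mito_events["frequency"].astype(float).round(6)
                )
                if len(self.mito_events)
                else self.mito_events
            ).to_dict(orient="records"),
            "exposures": {k: list(v) for k, v in self.exposures.items()},
        }

    @classmethod
    def from_json(cls, payload: dict) -> "SimulationTruth":
        nuc = pd.DataFrame(
            payload["nuclear_mutations"],
            columns=["line_id", "contig", "pos", "ref", "alt"],
        )
        mito = pd.DataFrame(
            payload["mito_events"],
            columns=["line_id", "contig", "pos", "ref", "alt", "frequency"],
        )
        tracts = [
            {**t, "positions": list(t["positions"])}
            for t in payload["conversion_tracts"]
        ]
        return cls(
            nuclear_mutations=nuc.astype({"pos": np.int64}, errors="ignore"),
            conversion_tracts=tracts,
            mito_events=mito.astype({"pos": np.int64}, errors="ignore"),
            exposures={k: (int(a), int(b)) for k, (a, b) in payload["exposures"].items()},
        )


@dataclasses.dataclass
class MAExperiment:
    """A simulated experiment: call sets plus the truth ledger."""

    config: SimulationConfig
    reference: ReferenceGenome
    ancestors: dict[str, AncestralState]
    records: list[MALineRecord]
    calls: dict[str, pd.DataFrame]
    truth: SimulationTruth
    genotype_of_line: dict[str, str]

    def bundle(self) -> CallsetBundle:
        return CallsetBundle(
            reference=self.reference,
            ancestors=self.ancestors,
            records=self.records,
            calls=self.calls,
        )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_reference(
    nuclear_length: int,
    mito_length: int,
    gc_content: float,
    seed: int = 0,
    nuclear_contig: str = "chr1",
    mito_contig: str = "mtDNA",
) -> ReferenceGenome:
    """I.i.d. reference with P(G) + P(C) = gc_content; mito circular."""
    if nuclear_length <= 0 or mito_length <= 0:
        raise SimulationError("contig lengths must be positive")
    if not 0 <= gc_content <= 1:
        raise SimulationError("gc_content must be in [0, 1]")
    rng = _rng(seed, 0)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    contigs = {}
    for name, length in ((nuclear_contig, nuclear_length), (mito_contig, mito_length)):
        codes = rng.choice(4, size=length, p=p)
        contigs[name] = _BASES[codes].tobytes().decode("ascii")
    return ReferenceGenome(
        contigs=contigs,
        partition={nuclear_contig: cio.NUCLEAR, mito_contig: cio.MITO},
        circular={nuclear_contig: False, mito_contig: True},
    )


def plant_ancestral_heterozygosity(
    reference: ReferenceGenome,
    het_density: float,
    seed: int = 0,
    genotype_id: str = "G1",
) -> AncestralState:
    """Bernoulli(het_density) heterozygous sites on callable nuclear sites.

    Each het site receives an alternate allele drawn uniformly from the
    three bases differing from the reference.
    """
    if not 0 <= het_density < 1:
        raise SimulationError("het_density must be in [0, 1)")
    rng = _rng(seed, 1)
    frames = []
    for name in reference.nuclear_contigs():
        mask = reference.callable_mask[name]
        codes = cio.seq_codes(reference.contigs[name])
        eligible = np.flatnonzero(mask & (codes < 4))
        if het_density > 0 and eligible.size:
            hits = eligible[rng.random(eligible.size) < het_density]
        else:
            hits = np.array([], dtype=np.int64)
        ref_codes = codes[hits]
        alt_codes = (ref_codes + rng.integers(1, 4, size=hits.size)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "contig": name,
                    "pos": hits + 1,
                    "ref": [b.decode() for b in _BASES[ref_codes]],
                    "alt": [b.decode() for b in _BASES[alt_codes]],
                }
            )
        )
    het = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["contig", "pos", "ref", "alt"])
    )
    return AncestralState(genotype_id=genotype_id, het_sites=het)


def simulate_mito_heteroplasmy(
    mito_mu: float,
    n_sites: int,
    g: int,
    N: int,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, float]]:
    """Neutral heteroplasmy frequencies after g generations of drift.

    Each generation, new per-copy mutations arise Poisson(mu * n_sites * N)
    at frequency 1/N at uniform positions; every segregating frequency then
    drifts by binomial resampling of the N copies.  Returns (1-based
    position, frequency) pairs with frequency > 0 at generation g.  The
    estimator property E[sum f] = mu * g * n_sites holds because drift is
    a martingale.
    """
    if N < 1:
        raise SimulationError("mito copy number N must be >= 1")
    if g < 1:
        raise SimulationError("g must be >= 1")
    if mito_mu < 0:
        raise SimulationError("mito_mu must be >= 0")
    if rng is None:
        rng = _rng(seed, 2)
    freqs: dict[int, float] = {}
    for _ in range(g):
        n_new = rng.poisson(mito_mu * n_sites * N)
        for _ in range(n_new):
            pos = int(rng.integers(1, n_sites + 1))
            freqs[pos] = min(freqs.get(pos, 0.0) + 1.0 / N, 1.0)
        for pos in list(freqs):
            copies = rng.binomial(N, freqs[pos])
            if copies == 0:
                del freqs[pos]
            else:
                freqs[pos] = copies / N
    return sorted(freqs.items())


def _apply_uncallable(reference: ReferenceGenome, fraction: float, rng) -> None:
    """Mark random 1 kb windows uncallable until *fraction* is reached."""
    if fraction <= 0:
        return
    for name, mask in reference.callable_mask.items():
        target = int(fraction * mask.size)
        removed = 0
        while removed < target:
            start = int(rng.integers(0, mask.size))
            end = min(start + 1000, mask.size)
            removed += int(mask[start:end].sum())
            mask[start:end] = False


# class label -> (ref pair string, alt pair string)
_CLASS_PAIRS = {c: (c.split(">")[0], c.split(">")[1]) for c in CLASSES}


def _alt_for_class(ref_base: str, cls: str) -> str:
    ref_pair, alt_pair = _CLASS_PAIRS[cls]
    if ref_base == ref_pair[0]:
        return alt_pair[0]
    if ref_base == ref_pair[2]:
        return alt_pair[2]
    raise SimulationError(f"base {ref_base!r} incompatible with class {cls!r}")


def simulate_ma_experiment(config: SimulationConfig) -> MAExperiment:
    """Simulate the full experiment described by *config*.

    Per line, the nuclear mutation count is Poisson(mu_bs * g * 2n) over
    ancestrally homozygous callable sites; conversion tracts initiate at
    ancestral het sites at a per-generation rate chosen so the expected
    per-het-site conversion rate equals ``true_mu_gc``; mitochondrial
    heteroplasmies come from :func:`simulate_mito_heteroplasmy`.
    """
    cfg = config
    reference = simulate_reference(
        cfg.nuclear_length, cfg.mito_length, cfg.gc_content, seed=cfg.seed
    )
    mask_rng = _rng(cfg.seed, 3)
    _apply_uncallable(reference, cfg.uncallable_fraction, mask_rng)

    nuc_contig = reference.nuclear_contigs()[0]
    mito_contig = reference.mito_contig
    nuc_seq = reference.contigs[nuc_contig]
    nuc_codes = cio.seq_codes(nuc_seq)
    nuc_mask = reference.callable_mask[nuc_contig]
    n_callable_nuc = int((nuc_mask & (nuc_codes < 4)).sum())
    n_callable_mito = int(reference.callable_mask[mito_contig].sum())

    ancestors: dict[str, AncestralState] = {}
    records: list[MALineRecord] = []
    calls: dict[str, pd.DataFrame] = {}
    genotype_of_line: dict[str, str] = {}
    truth_nuc_rows: list[tuple] = []
    truth_tracts: list[dict] = []
    truth_mito_rows: list[tuple] = []
    exposures: dict[str, tuple[int, int]] = {}

    # mean het sites found inside one conversion tract; used to convert the
    # per-site conversion rate into a tract initiation rate
    e_sites_per_tract = 1.0 + (cfg.tract_length_mean - 1.0) * cfg.ancestral_het_density

    for gi in range(cfg.n_genotypes):
        pop = _POPULATION_IDS[min(gi * 3 // max(cfg.n_genotypes, 1), 2)]
        genotype_id = f"{pop}G{gi + 1}"
        anc = plant_ancestral_heterozygosity(
            reference, cfg.ancestral_het_density, seed=cfg.seed + 7919 * (gi + 1),
            genotype_id=genotype_id,
        )
        ancestors[genotype_id] = anc
        het = anc.het_sites
        het_pos = het["pos"].to_numpy()
        het_set = set(het_pos.tolist())
        n_het = len(het_pos)

        for li in range(cfg.lines_per_genotype[gi]):
            line_id = f"{genotype_id}_L{li + 1}"
            genotype_of_line[line_id] = genotype_id
            g = cfg.generations_per_line
            rng = _rng(cfg.seed, 4, gi, li)

            # --- start from the ancestral genotype at its het sites
            line_rows = het.assign(
                genotype=cio.GT_HET, allele_frequency=np.nan
            )

            # --- gene-conversion tracts
            tract_sites: dict[int, str] = {}
            if cfg.true_mu_gc > 0 and n_het > 0:
                lam = cfg.true_mu_gc * g * n_het / e_sites_per_tract
                n_tracts = rng.poisson(lam)
                for _ in range(n_tracts):
                    start = int(het_pos[rng.integers(n_het)])
                    length = int(rng.geometric(1.0 / cfg.tract_length_mean))
                    direction = "to_ref" if rng.random() < 0.5 else "to_alt"
                    members = [
                        int(p)
                        for p in het_pos[(het_pos >= start) & (het_pos <= start + length - 1)]
                        if int(p) not in tract_sites
                    ]
                    if not members:
                        continue
                    for p in members:
                        tract_sites[p] = direction
                    truth_tracts.append(
                        {
                            "line_id": line_id,
                            "contig": nuc_contig,
                            "positions": members,
                            "direction": direction,
                        }
                    )
            if tract_sites:
                conv = line_rows["pos"].map(tract_sites)
                line_rows.loc[conv == "to_ref", "genotype"] = cio.GT_HOM_REF
                line_rows.loc[conv == "to_alt", "genotype"] = cio.GT_HOM_ALT

            # --- de novo nuclear substitutions at hom callable sites
            n_mut = rng.poisson(cfg.true_mu_bs * g * 2 * n_callable_nuc)
            mut_rows = []
            used: set[int] = set()
            expected = cfg.true_mu_bs * g * 2 * n_callable_nuc
            if expected > 0.25 * n_callable_nuc:
                raise SimulationError(
                    "expected mutations exceed a quarter of callable sites; "
                    "enlarge nuclear_length or reduce true_mu_bs"
                )
            classes = rng.choice(len(CLASSES), size=n_mut, p=cfg.class_weights)
            for ci in classes:
                cls = CLASSES[ci]
                ref_pair = _CLASS_PAIRS[cls][0]
                want = {ref_pair[0], ref_pair[2]}
                for _attempt in range(10_000):
                    pos = int(rng.integers(1, len(nuc_seq) + 1))
                    if (
                        nuc_mask[pos - 1]
                        and nuc_seq[pos - 1] in want
                        and pos not in het_set
                        and pos not in used
                    ):
                        break
                else:  # pragma: no cover - pathological configurations only
                    raise SimulationError(
                        "could not place mutation; genome too small or saturated"
                    )
                used.add(pos)
                ref = nuc_seq[pos - 1]
                alt = _alt_for_class(ref, cls)
                mut_rows.append((nuc_contig, pos, ref, alt))
                truth_nuc_rows.append((line_id, nuc_contig, pos, ref, alt))
            if mut_rows:
                line_rows = pd.concat(
                    [
                        line_rows,
                        pd.DataFrame(
                            mut_rows, columns=["contig", "pos", "ref", "alt"]
                        ).assign(genotype=cio.GT_HET, allele_frequency=np.nan),
                    ],
                    ignore_index=True,
                )

            # --- mitochondrial heteroplasmies
            if cfg.mito_mu > 0:
                events = simulate_mito_heteroplasmy(
                    cfg.mito_mu,
                    cfg.mito_length,
                    g,
                    cfg.mito_copy_number,
                    rng=rng,
                )
                mito_rows = []
                for pos, f in events:
                    ref = reference.contigs[mito_contig][pos - 1]
                    alt_choices = [b for b in "ACGT" if b != ref]
                    alt = alt_choices[int(rng.integers(3))]
                    mito_rows.append((mito_contig, pos, ref, alt, f))
                    truth_mito_rows.append((line_id, mito_contig, pos, ref, alt, f))
                if mito_rows:
                    line_rows = pd.concat(
                        [
                            line_rows,
                            pd.DataFrame(
                                mito_rows,
                                columns=["contig", "pos", "ref", "alt", "allele_frequency"],
                            ).assign(genotype=cio.GT_HET),
                        ],
                        ignore_index=True,
                    )

            # --- symmetric het<->hom genotyping errors
            if cfg.genotype_error_rate > 0:
                n_err = rng.poisson(cfg.genotype_error_rate * n_callable_nuc)
                site_of_row = dict(zip(line_rows["pos"], line_rows.index))
                err_rows = []
                for _ in range(n_err):
                    pos = int(rng.integers(1, len(nuc_seq) + 1))
                    if not nuc_mask[pos - 1]:
                        continue
                    idx = site_of_row.get(pos)
                    if idx is not None and line_rows.at[idx, "contig"] == nuc_contig:
                        gt = line_rows.at[idx, "genotype"]
                        if gt == cio.GT_HET:
                            line_rows.at[idx, "genotype"] = (
                                cio.GT_HOM_REF if rng.random() < 0.5 else cio.GT_HOM_ALT
                            )
                        else:
                            line_rows.at[idx, "genotype"] = cio.GT_HET
                    else:
                        ref = nuc_seq[pos - 1]
                        if ref == "N":
                            continue
                        alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
                        err_rows.append((nuc_contig, pos, ref, alt))
                if err_rows:
                    line_rows = pd.concat(
                        [
                            line_rows,
                            pd.DataFrame(
                                err_rows, columns=["contig", "pos", "ref", "alt"]
                            ).assign(genotype=cio.GT_HET, allele_frequency=np.nan),
                        ],
                        ignore_index=True,
                    )

            depth = rng.poisson(cfg.mean_depth, size=len(line_rows))
            line_rows = line_rows.assign(
                depth=np.maximum(depth, 1), quality=99.0
            )
            line_rows = line_rows.reindex(columns=cio.CALL_COLUMNS)
            calls[line_id] = cio.sort_calls(line_rows, reference)
            records.append(
                MALineRecord(
                    line_id=line_id,
                    genotype_id=genotype_id,
                    population_id=pop,
                    g=g,
                    generation_time_days=cfg.generation_time_days,
                    n_callable_nuclear=n_callable_nuc,
                    n_callable_mito=n_callable_mito,
                    role="MA",
                )
            )
            exposures[line_id] = (n_callable_nuc, n_callable_mito)

    truth = SimulationTruth(
        nuclear_mutations=pd.DataFrame(
            truth_nuc_rows, columns=["line_id", "contig", "pos", "ref", "alt"]
        ),
        conversion_tracts=truth_tracts,
        mito_events=pd.DataFrame(
            truth_mito_rows,
            columns=["line_id", "contig", "pos", "ref", "alt", "frequency"],
        ),
        exposures=exposures,
    )
    return MAExperiment(
        config=cfg,
        reference=reference,
        ancestors=ancestors,
        records=records,
        calls=calls,
        truth=truth,
        genotype_of_line=genotype_of_line,
    )


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------

def write_fixture(experiment: MAExperiment, out_dir: Path | str) -> dict[str, Path]:
    """Write an experiment as FASTA + per-line VCF + BED + TSV + truth JSON.

    Re-reading with :func:`read_fixture` reproduces the in-memory objects.
    """
    out = Path(out_dir)
    (out / "lines").mkdir(parents=True, exist_ok=True)
    (out / "ancestors").mkdir(exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)

    paths: dict[str, Path] = {}
    ref_path = out / "reference.fa"
    cio.write_reference_fasta(ref_path, experiment.reference)
    paths["reference"] = ref_path

    mask_path = out / "masks" / "reference.bed"
    cio.write_bed(mask_path, experiment.reference.callable_mask)
    paths["reference_mask"] = mask_path

    for genotype_id, anc in experiment.ancestors.items():
        p = out / "ancestors" / f"{genotype_id}.vcf"
        table = anc.het_sites.assign(
            genotype=cio.GT_HET,
            allele_frequency=np.nan,
            depth=0,
            quality=99.0,
        ).reindex(columns=cio.CALL_COLUMNS)
        cio.write_vcf(p, experiment.reference, table, sample=genotype_id)
        paths[f"ancestor:{genotype_id}"] = p

    for line_id, table in experiment.calls.items():
        p = out / "lines" / f"{line_id}.vcf"
        cio.write_vcf(p, experiment.reference, table, sample=line_id)
        paths[f"line:{line_id}"] = p

    meta_path = out / "metadata.tsv"
    cio.write_metadata(meta_path, experiment.records)
    paths["metadata"] = meta_path

    truth_path = out / "truth.json"
    payload = experiment.truth.to_json()
    payload["genotype_of_line"] = experiment.genotype_of_line
    payload["config"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(experiment.config).items()
    }
    cio.write_truth_json(truth_path, payload)
    paths["truth"] = truth_path
    return paths


def read_fixture(out_dir: Path | str) -> MAExperiment:
    """Re-read a fixture written by :func:`write_fixture`."""
    out = Path(out_dir)
    payload = cio.read_truth_json(out / "truth.json")
    cfg_raw = dict(payload["config"])
    cfg_raw["lines_per_genotype"] = tuple(cfg_raw["lines_per_genotype"])
    config = SimulationConfig(**cfg_raw)
    truth = SimulationTruth.from_json(payload)
    genotype_of_line = dict(payload["genotype_of_line"])

    vcf_paths = {p.stem: p for p in sorted((out / "lines").glob("*.vcf"))}
    ancestor_paths = {p.stem: p for p in sorted((out / "ancestors").glob("*.vcf"))}
    bundle = cio.read_callsets(
        vcf_paths=vcf_paths,
        fasta_path=out / "reference.fa",
        bed_paths={"reference": out / "masks" / "reference.bed"},
        metadata_path=out / "metadata.tsv",
        ancestor_vcf_paths=ancestor_paths,
    )
    return MAExperiment(
        config=config,
        reference=bundle.reference,
        ancestors=bundle.ancestors,
        records=bundle.records,
        calls=bundle.calls,
        truth=truth,
        genotype_of_line=genotype_of_line,
    )
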