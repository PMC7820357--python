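# Methods

## Scope and data model

`mutacc` starts from genotype call sets, not reads: a reference FASTA
(nuclear contigs plus one circular mitochondrial contig), one VCF per
line, callable-site masks in BED, and a line metadata table (line id,
genotype, population, generations `g`, generation time, role). All
internal coordinates are 1-based closed (VCF convention); BED's 0-based
half-open intervals are converted at the boundary and never used
internally, which removes the usual off-by-one surface. A line's callable
exposure is the intersection of the genome-level mask and its per-line
mask. Sites whose reference base is N are never callable.

Each starting genotype has an `AncestralState`: the index of its
ancestrally heterozygous sites (position, ref, alt). Sites absent from
the index are ancestrally homozygous-reference. Line call sets are
expected to carry explicit genotyped records at every ancestral
heterozygous position (as a joint-genotyping pipeline emits), which is
what lets the loss-of-heterozygosity detector evaluate depth at candidate
sites; a position missing from a line's call set is never an LOH
candidate.

## Detection

**Nuclear substitutions.** A candidate is a het or hom-alt genotype at an
ancestrally homozygous position, callable in both ancestor and line.
Filters: depth within `[min_depth, max_depth_factor × line mean depth]`
(defaults 10 and 2.0 — low-depth genotypes are unreliable, high-depth ones
sit in collapsed repeats), quality ≥ 30, and a uniqueness filter on by
default: a variant observed in more than one independently propagated
line cannot be de novo and is treated as shared ancestral polymorphism or
systematic artifact. Tightening any filter can only remove calls
(monotonicity, property-tested).

**Heteroplasmies.** A mitochondrial variant absent from the ancestor is
accepted when its allele frequency is ≥ `mito_min_frequency` (default
0.05, a conventional heteroplasmy-calling floor) and its implied
alternate-read count (frequency × depth) is ≥ 2. The frequency `f_i` is
retained for the frequency-sum estimator.

**Gene conversion.** Candidates are ancestral het sites genotyped
homozygous in the focal line (hom-alt only if the allele matches the
ancestral alternate). A hemizygous deletion also produces apparent LOH
but halves local depth, so candidates with depth below
`lod_depth_ratio_min × line mean depth` (default 0.5) are excluded.
Surviving sites are clustered into tracts by single-linkage with gap
≤ `max_gap` (default 10 kb, configurable; the clustering is verified
against an all-pairs union-find oracle). `x_g` counts member **sites**,
not tracts, matching the conversion-rate denominator (per heterozygous
site).

Detection is a pure function of (call sets, filters): reruns are
byte-identical.

## Rate estimation

Per line: `μ_n,bs = x_bs/(g·2n)`, `μ_m,bs = Σf_i/(g·n)`,
`μ_n,g = x_g/(g·n_het)`. Aggregation to genotype, population and species
offers two schemes. `pooled` (default) divides summed events by summed
exposures and therefore equals the exposure-weighted mean of line rates;
`mean_of_means` averages the next level down unweighted (genotype = mean
of line rates, population = mean of genotype values, species = mean of
population values). Published species-level values in this literature are
generally exposure-weighted, which is why pooled is the default, but both
schemes are always emitted and labelled since conventions differ between
studies.

Confidence intervals are percentile bootstrap (default B=1000, 2.5/97.5
percentiles), resampling **lines** with replacement — the line is the
independent experimental unit; resampling mutations would ignore
between-line heterogeneity. BCa corrections are deliberately not applied:
with ≤ tens of lines the plain percentile interval is transparent and its
~94–95% empirical coverage is verified in the suite. A single line yields
a degenerate CI and a warning.

Unit conversions: per-genome/generation multiplies by the diploid genome
size (2 × mean haploid callable length unless supplied); per-bp/day
divides by the per-line generation time in days.

## Spectrum

Substitutions collapse to six strand-symmetric classes (e.g. G→A ≡ C→T ≡
`C:G>T:A`); trinucleotide contexts collapse so the central base is A or C
(32 contexts). Context windows wrap on the circular mitochondrial contig
and are undefined at linear contig ends or across Ns. Conditional rates
divide counts by the callable opportunity of the matching class or
context — `rate = count/(Σg · 2 · denominator)` — which removes base
composition bias; class denominators are the central-base marginals of
the context denominators. Ts:Tv defaults to raw counts with a
conditional-rate variant exposed, since both conventions appear in the
literature. A site is CpG when, in the collapsed representation, the
central C is followed by G; the definition is strand-symmetric. The CpG
contrast is a paired t-test across genotypes of (mean CpG − mean non-CpG
central-C) conditional rates, df = genotypes − 1. The spectrum
homogeneity test is a χ² goodness of fit of the six class counts against
expectation proportional to each class's site opportunity (df = 5).

## Derived quantities

* Equilibrium GC content: `α/(α+β)` with α the per-A:T-site rate of
  AT→GC changes and β the per-C:G-site rate of GC→AT changes; invariant
  to rescaling all rates.
* Equilibrium heterozygosity under mutation–conversion balance:
  `μ_bs/(μ_bs+μ_g)`.
* Effective population size from neutral diversity: `Ne = π_s/(4μ)`.
  π_s is an external scalar input (it comes from population resequencing,
  not from an MA experiment) and is never bundled.
* Heritability of the rate as a trait: one-way random-effects
  decomposition of line-level rates by genotype via expected mean
  squares, with `n₀ = (N − Σnᵢ²/N)/(k−1)` for unbalanced designs.
  Negative method-of-moments `V_G` is truncated to 0 and flagged.
  "Evolvability" is reported under **two** labelled conventions —
  mean-squared-scaled `I_G = V_G/x̄²` and mean-scaled `V_G/x̄` — because
  usage in the literature is ambiguous; callers pick explicitly.
* Spearman correlation with `t = ρ√((n−2)/(1−ρ²))`, df = n−2; one-way
  ANOVA (optionally on log10 rates, since rate distributions are strongly
  right-skewed) with Tukey HSD pairwise flags when groups are replicated.

## The simulator

The simulator produces experiments with the statistical structure the
analysis assumes, plus a complete truth ledger.

* **Reference**: i.i.d. bases with P(G)+P(C) = `gc_content` (default
  0.41, a typical arthropod nuclear composition), one linear nuclear
  contig and one circular 15 kb mitochondrial contig.
* **Ancestral heterozygosity**: Bernoulli per callable site (default
  density 0.005/bp), alt allele uniform over the three non-reference
  bases.
* **Nuclear mutations**: per line, count ~ Poisson(μ_bs·g·2n) placed at
  ancestrally homozygous callable sites; class drawn from a six-class
  spectrum (default transition-biased with Ts:Tv = 1.54 and `C:G>T:A`
  the largest class, the common invertebrate pattern); alt determined by
  class and strand.
* **Gene conversion**: tracts initiate at ancestral het sites at a
  per-generation rate chosen so the expected per-het-site conversion rate
  equals `true_mu_gc`; tract extent is geometric (default mean 500 bp,
  set so a tract covers ~2–3 het sites at the default density, the scale
  seen in direct tract observations); donor homolog is a fair coin, and
  all member sites convert in that direction (homologs are phased
  ref/alt). Because sites arrive in tracts, the converted-site count is
  compound-Poisson: its variance is λ·E[S²], not the Poisson mean —
  recovery tests use the matching Monte-Carlo SE (estimated by the sum of
  squared tract sizes).
* **Heteroplasmy**: per generation, new per-copy mutations arise
  Poisson(μ·n·N) at frequency 1/N (default bottleneck N=100 mtDNA copies,
  the simplest neutral Wright–Fisher model consistent with the
  frequency-sum estimator), then every segregating frequency drifts by
  binomial resampling of N copies. Drift is a martingale, so
  E[Σf] = μ·g·n and the estimator is unbiased — verified against a
  200-line Monte-Carlo oracle.
* **Noise**: optional symmetric het↔hom genotype flips at rate
  `genotype_error_rate` (default 0) to exercise the filters; optional
  random uncallable windows. Depth is Poisson(30) per record.
* **Seeding**: one integer seed; every stage draws from a named
  `SeedSequence` substream, so simulations are bit-reproducible from the
  config alone.

Defaults mirror a nine-genotype, 66-line design (8,8,8,7,…,7 lines per
genotype) run for g = 30 generations with species-scale rates
(μ_bs = 8.96×10⁻⁹, μ_g = 6.13×10⁻⁷, μ_m = 8.7×10⁻⁷).

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: read-level error (genotypes are right or
flipped wholesale, never probabilistically miscalled from pileups),
mapping artifacts and repeat-driven excess depth, indels/TEs/SVs,
selection during propagation, shared polymorphism between genotypes,
site-specific mutation-rate heterogeneity beyond the 6-class spectrum,
and mitochondrial recombination or selection. Recovery of a planted rate
therefore validates the estimators and filters, not the upstream variant
calling a real study depends on.

## Numerical and design choices

* Fixture VCFs store heteroplasmy frequencies in INFO/AF, a float32
  field; frequencies are rounded to six decimals on write and read so the
  round trip is exact for frequencies that are multiples of 1/N.
* Problem sizes in the test-suite recovery checks are the full 66-line
  design for the three headline analyses and reduced genomes (100–500 kb,
  scaled-up rates) elsewhere, chosen to keep per-test event counts in the
  tens-to-hundreds so Monte-Carlo bands are tight.
* Tract clustering ties: single-linkage on sorted positions; a gap
  exactly equal to `max_gap` merges.
* `compare_ma_vs_controls` returns ∞ (with a warning) when the control
  rate is zero and NaN when both rates are zero.
* Zero-variance degenerate cases are flagged rather than erroring:
  identical bootstrap lines give a zero-width CI, an all-zero paired CpG
  difference gives t = 0, zero total variance gives undefined H².

## Known limitations

* The detectors assume bi-allelic sites after splitting; genuinely
  multi-allelic de novo events at one position in one line are counted as
  separate calls.
* LOH detection requires genotyped records at ancestral het positions;
  call sets that omit hom-ref records will silently under-detect
  conversion (tract candidates need depth evidence).
* The uniqueness filter removes genuinely recurrent de novo mutations;
  at realistic rates this loss is negligible (expected collisions ≪ 1 per
  experiment) but it is a bias at very high simulated rates.
* Heritability uses line-level rates as the trait value; measurement
  (Poisson) noise in those rates inflates V_E and deflates H² relative to
  a design with within-line replication.
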