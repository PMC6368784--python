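# Methods

This note documents the models implemented in `mgsim`, the defaults and
why, the numerical choices, and what the synthetic fixtures do and do
not emulate.

## Community design from a taxonomic profile

The input profile is a list of (taxon id, abundance ≥ 0) pairs, read
from a BIOM 1.0 JSON table whose observation ids are free-text names.
Name resolution is a four-step cascade — exact scientific name, exact
synonym, case-insensitive match, genus fallback on the first whitespace
token — with each step logged and unresolvable names excluded with a
machine-greppable warning (`NAME-UNRESOLVED`). The cascade is a design
choice: it is deterministic, each decision is explainable from the log,
and the genus fallback covers the common case of binomials whose species
epithet is absent from the reference taxonomy.

For each profile taxon the lineage is projected onto the fixed rank list
R = (species, genus, family, order, class, phylum, superkingdom) and
walked upward from species to the configured highest search rank r_max
(default family). At the first rank whose taxon has genomes in the
lineage index, the strain count X is drawn and abundance is split. Taxa
with no genomes at any searched rank are excluded with a
`TAXON-EXCLUDED` warning; an entirely empty community is an error.

Only genomes tagged `complete` are indexed by default; `scaffold` and
`contig` assemblies are opt-in. Genomes selected for one profile taxon
are by default removed from the whole index so no genome is used twice;
with reuse enabled, duplicate rows are merged by summing at emission.

**Truncated geometric strain count.** With m the maximum strains per
taxon and μ = m/2, the pmf p(k) ∝ (1 − 1/μ)^k / μ is renormalized over
k ∈ {0..m−1} and the returned count is X = k + 1. Mapping the support to
{1..m} is deliberate: a matched taxon must contribute at least one
genome, and m = 1 (μ = 1/2, where the raw pmf is undefined) then
degenerates cleanly to X = 1. m = 2 is likewise degenerate (all mass at
X = 1).

**Abundance split.** Weights Y_i ~ Lognormal(μ=1, σ=2) (parameters on
the underlying normal); shares are normalized before scaling by ab_t,
so Σ ab_i = ab_t holds to float precision by construction, not
approximately. σ = 0 gives equal shares. Input abundances are never
pre-normalized; the community profile is normalized only when emitted,
which keeps the conservation law testable.

## De novo design

Genomes are drawn balanced over novelty categories (how distant a genome
is from public references — relevant when benchmarking reference-based
tools). Quotas start as an even split of g_real; categories short of
their quota contribute everything and the deficit is redistributed over
categories with spare genomes until the total is exact. Within a
category, sampling is uniform without replacement.

Simulated strains are added source genome by source genome in a seeded
random order: the count per source is geometric on {1, 2, ...} with
success probability 0.3 (mean 1/0.3 ≈ 3.33), capped at m − 1 and at the
remaining g_sim budget. The trials-counting geometric (support starting
at 1) was chosen because its mean is exactly 1/p and a selected OTU
always receives at least one strain. Each evolved genome records its
source, OTU and target ANI in a provenance table.

The per-strain target ANI is drawn uniformly from a configurable
interval, default 0.95–0.999 — the within-species band (95% ANI is the
conventional bacterial species boundary). The uniform choice is a
package decision; nothing in the strain model depends on it.

## Strain evolution and ANI

Evolution is substitution-only: no indels or rearrangements. This keeps
source and strain the same length, so ANI is exactly the fraction of
identical columns and needs no aligner. To hit target ANI a on a
sequence with L_e unambiguous (ACGT) positions, exactly
round((1 − a)·L_e) positions are drawn uniformly without replacement and
substituted with a uniformly chosen different base (an offset of 1–3 in
the ACGT ring). `round` is Python's half-to-even. Ambiguous bases are
never mutated. Measured ANI therefore differs from the target by at most
1/(2L) from rounding — the sweep test asserts ≤ 1/L.

The relatedness sweep helper defaults to targets 0.900–0.995 in steps of
0.005 (20 values), the standard band for studying strain-resolution
behaviour of assemblers.

## Sample modes

All modes build on Lognormal(μ=1, σ=2); σ = 0 degenerates to a uniform
community. Replicates add N(0, noise_sd) (default 1) to one base draw;
time series either add the same Gaussian term to the previous sample or
apply the damped form D_i = (D_{i−1} + Lognormal)/2, whose expectation
converges geometrically to the lognormal mean.

Additive Gaussian noise can produce negative values; these are clamped
to 0 (genome absent in that sample). A `log_space` switch instead adds
the noise to ln D, which preserves positivity; the linear form is the
default. Whether noise should act on the linear or log scale is a
genuinely open modelling question; both are provided.

In profile mode, the designed community vector is used directly as the
single sample and as the base D_0 for replicates/time series (on the
profile's own scale, so noise_sd should be read relative to it);
differential mode redraws abundances per sample by definition — the
conditions changed — so the profile contributes only the genome set.

Per-sample noise draws use per-sample derived generators, so sample i is
bit-reproducible regardless of how many samples a run requests.

## Read engine

Reads per genome: n_t = n · ab_t·s_t / Σ ab_i·s_i, with
n = floor(total_bases / read_length) rounded down to even. Counts are
rounded by largest remainder over *pairs*, so every n_t is even and
Σ n_t = n exactly.

Genome preparation splits contigs at maximal runs of ≥ 2 non-ACGT
characters (the run removed), so no read spans a scaffold gap; isolated
single ambiguities are replaced by a random concrete base and logged.
Pieces shorter than one fragment are kept but never sampled.

Per pair: a contig is chosen with probability proportional to its number
of valid fragment start positions; fragment length is
round(N(insert_mean, insert_sd)) clipped to [2·read_length, contig
length]; placement is uniform; strand is uniform. Mates are cut from the
fragment ends in forward/reverse orientation. Defaults:
read_length 150, insert_mean 2·read_length + 120, insert_sd 10% of the
mean — unremarkable short-insert Illumina-like values, all configurable.

Sequencing errors are i.i.d. per-base substitutions at rate ε to a
uniformly chosen different base, implemented as a Binomial(L, ε) count
per mate plus a uniform choice of distinct positions — distributionally
identical to per-base Bernoulli draws, and it records the error
positions for free. Base qualities are constant (default Q40). This is
deliberately a uniform-error model: trained instrument error profiles,
indel errors and long-read models are out of scope; external simulators
could be attached behind the same (FASTQ + truth) contract.

Subsampling keeps each pair atomically with probability f, so eight 50%
steps from a 512× read set leave each pair alive with probability 2⁻⁸ —
kept counts are exactly Binomial(n_pairs, 2⁻⁸), which is the tolerance
basis used in the tests.

Truth is emitted as SAM (one record per mate, MAPQ 255, full-length
match CIGAR, proper-pair and reverse flags, reference-strand sequence);
BAM conversion is left to samtools.

## Gold standards

Perfect (co-)assembly: per reference contig, the maximal unions of mate
truth intervals are extracted error-free. Two implementations exist —
the production interval-merge and a per-base coverage-array oracle — and
are asserted equal on random instances; for exact truth coordinates the
two are provably equivalent, which is why no external pileup is needed.
Touching intervals merge (coverage is contiguous across the boundary).
The insert interior between mates is *not* counted as covered; each mate
covers exactly its own interval.

Binning truth is a headered 3-column TSV (sequence id, genome id, taxon
id) in a CAMI-exchange-like layout (`@`-prefixed header lines,
`@@SEQUENCEID	BINID	TAXID`). Profiling truth reports percentages per
rank from strain (genome) to superkingdom; mass with no defined taxon at
a rank is emitted as `unassigned`, so every rank column sums to 100.

Anonymization replaces ids with serial `PREFIX<n>` ids after a seeded
shuffle and writes the bijective map; reads are anonymized at pair level
so the R1/R2 pairing survives. Truth SAM keeps the original ids; the map
links the two.

## Seeding and determinism

One master seed; every stage derives its generator as
SHA-256(master, stage token, …) truncated to 31 bits. Consequences:
reruns are byte-identical (gzip members are written with mtime 0), and
changing one stage's inputs (e.g. the number of samples) does not
perturb another stage's stream. The audit copy of the config and the log
are the only non-reproducible-by-checksum files (paths/timestamps).

## Synthetic fixtures: what they are and are not

The fixture generator builds a toy taxonomy (k families × genera ×
species under one superkingdom), i.i.d. random ACGT genomes (uniform or
GC-biased, optionally with planted ambiguities), matching metadata/OTU
tables, and BIOM profiles (dense or sparse, optionally with planted
unresolvable names). This exercises every code path offline, but random
genomes have no repeats, no shared homology between species, no real
codon or k-mer structure, and uniform composition; passing tests
demonstrate the correctness of the samplers, conservation laws,
coordinate bookkeeping and formats — not biological realism of the
sequences. Test and acceptance problem sizes (100-kb genomes, ≤ 10⁶-base
read sets, 12-genome communities) were chosen so the whole suite runs in
minutes on one CPU; all quantities checked are size-stable.

## Known limitations

- Uniform substitution errors only; no indel or instrument-profile
  error models; no long-read simulation.
- Substitution-only strain evolution; ANI is undefined here for
  unequal-length sequences.
- BIOM support is the minimal 1.0 JSON dialect (no HDF5).
- The taxonomy loader expects the two-file TSV layout; real NCBI dump
  archives (merged/delnodes handling) are out of scope.
- No built-in evaluation metrics; this package produces the truth,
  benchmarking tools consume it.
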