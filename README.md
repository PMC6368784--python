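# mgsim

A microbial community and shotgun metagenome simulator that produces the
exact ground truth ("gold standards") needed to benchmark metagenome
assemblers, genome/taxonomic binners and taxonomic profilers.

Developers of metagenome analysis tools need datasets where the right
answer is known. `mgsim` designs a microbial community — either by
resolving a real taxonomic profile against a genome collection, or de
novo with simulated strain-level diversity — simulates paired-end
shotgun reads from it, and derives, from the exact read coordinates it
kept, the perfect assembly, the true genome/taxon assignment of every
sequence, and the true taxonomic profile at every rank.

## The models

**Community design from a profile.** An input profile is a set of pairs
(t, ab_t) of taxon ids and abundances. For each taxon the lineage is
walked from *species* up to a highest search rank r_max (default
*family*); at the first rank with genomes available, the number of
strains X ∈ {1..m} to include is drawn from a truncated geometric
distribution with mean μ = m/2,

    P(X = k+1) ∝ (1 − 1/μ)^k · 1/μ,   k = 0..m−1,

and the taxon's abundance is split across the chosen genomes with
lognormal weights Y_i ~ Lognormal(μ, σ), ab_i = Y_i/ΣY_j · ab_t, so the
per-taxon mass is conserved exactly. By default no genome is used twice.

**De novo design.** g_real genomes are sampled balanced over novelty
categories; simulated strain genomes are then evolved (substitutions
only, to a target average nucleotide identity) OTU by OTU — the count
per source genome geometric with mean 1/0.3, capped at m−1 — until the
community holds g_tot genomes.

**Sample modes.** Per-sample abundances follow a lognormal base model
(defaults μ=1, σ=2 on the log scale; σ=0 gives a uniform community):
*single*, *differential* (n independent draws), *replicates*
(D_i = D_0 + N(0,1)) and *timeseries* (Markov chain, Gaussian or damped
lognormal increments).

**Read engine.** Reads per genome follow
n_t = n · ab_t·s_t / Σ ab_i·s_i with n = total bases / read length.
The built-in engine is wgsim-like: normal fragment lengths, uniform
placement, 2×150 bp mates in forward/reverse orientation, i.i.d. uniform
substitution errors at a configurable rate, constant base qualities, and
a truth record (coordinates + error positions) per mate. Pair-preserving
subsampling supports coverage ladders (512×, 256×, … 2×).

**Gold standards.** The perfect (co-)assembly extracts every maximal
reference region with coverage ≥ 1 as an error-free contig; binning
truth assigns each read/contig its genome and taxon; profiling truth
reports per-rank percentages from strain to superkingdom. All outputs
can be anonymized and shuffled with a reversible, seeded mapping.

## Worked example

```bash
python examples/04_reads_and_gold.py
```

```
total reads n = 4000; per-genome n_t = {'gA': 2666, 'gB': 1334}
  (equal abundance, 2:1 genome size -> 2:1 reads: weight is ab x size)
  gA: mean coverage 10.00x
  gB: mean coverage 10.01x
observed error rate: 0.0200 (configured 0.02)

perfect assembly: 2 gold contigs, 59817 bp
  (high coverage -> nearly every reference base is covered)
```

Two genomes at equal abundance but 2:1 size receive reads 2:1 — the
allocation weighs abundance × genome size, so both end up at the same
10× coverage. The observed per-base mismatch rate against the truth
coordinates reproduces the configured 2%, and the perfect assembly
recovers nearly the whole reference (59 817 of 60 000 bp) as error-free
gold contigs. The other scripts in `examples/` walk through profile
resolution, de novo strain evolution, the four sample modes, and a full
config-driven run.

## Command line

```bash
mgsim fixture -o fx --seed 42        # synthetic taxonomy/genomes/profile/config
mgsim run -c fx/config.ini           # full pipeline
mgsim design -c fx/config.ini        # community design only
mgsim goldstandard --sam truth.sam --reference ref.fasta -o gold.fasta.gz
```

Runs are driven by an INI config (sections `[general]`, `[community]`,
`[samples]`, `[reads]`, `[output]`); one master seed fixes every stage.

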