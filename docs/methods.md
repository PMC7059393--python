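# Methods

This note documents the models behind each stage of clonotrace, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Barcode extraction

The barcode cassette is a 31-nt insert — 15 color-specific nucleotides
followed by 16 random nucleotides (the UMI) — flanked by the fixed primers
`ACCATCTAGA` and `CTCGAGACTG`.

**Linked-delimiter trimming.** `trim_linked` finds the ordered pair of
primer placements minimising total edit distance, allowing
`floor(max_error_rate x primer_length)` edits *per primer* (2 each for the
10-mers at the default rate 0.2); substitutions and indels both count, the
convention of standard linked-adapter trimmers. The implementation runs two
semi-global edit-distance DPs (one per primer, the right one on the
reversed read), then scans inner-start positions against suffix minima of
the right-primer start scores — O(primer x read) per read, with an exact
`str.find` fast path that is provably optimal whenever both primers occur
verbatim in order. Ties among equal-score placements are broken by smallest
inner start, then shortest inner; this makes trimming idempotent (re-trimming
a trimmed insert with primers re-attached returns it unchanged) and fully
deterministic. Absence of either delimiter is a `None` return, not an
error. Reverse-orientation mates are reverse-complemented before matching;
with paired input, mate 2 is consulted only for read ids that yielded no
barcode from mate 1.

**Color calling** uses Hamming (not edit) distance on the fixed 15-nt
prefix, tolerance 2 mismatches by default. Tag sets must be pairwise
separated by more than twice the tolerance, which guarantees at most one
tag can match; the bundled default tags are generator-invented compliant
sequences (pairwise Hamming ≥ 12) because real color-tag sequences are
construct-specific configuration — supply your own via a `name<TAB>sequence`
TSV. The UMI is taken verbatim from insert positions 16–31 (1-based); reads
whose insert is shorter than 31 nt, or whose prefix matches no tag, are
counted `unassigned_color`. Extraction statistics partition the input
exactly: `trimmed + no_barcode = total`, `assigned + unassigned_color =
trimmed`.

## Clone tables and diversity

A clone is a (color, UMI) pair. Fractions are percentages of *assigned*
barcode reads. Optional **directional UMI collapse** merges clone `a` into
`b` when they share a color, `Hamming(umi_a, umi_b) <= 1` and
`count_a <= 0.1 x count_b` (counts as observed); parents are visited from
most to least abundant, and an absorbed clone is inert afterwards. Both
knobs are configurable; collapse is off when raw barcode strings are
wanted. The defaults mirror common UMI practice: a 10:1 count ratio makes
it very unlikely that a genuine small clone is swallowed by a coincidental
single-mismatch neighbour, while sequencing-error satellites (which are
rare per-variant) are absorbed. Collapse conserves total reads and never
increases richness.

Diversity per sample: Shannon `H = -Σ p_i ln p_i` (natural log; the log
base is a parameter), richness, Pielou evenness `H/ln(richness)` (defined
as 1 for a single clone), and top-k share (k = 3 by default, matching the
usual "top three barcodes" dominance summaries). One Shannon implementation
is shared between clone tables and methylation-pattern tables.
`trajectory` emits a long-format table with a row for every clone at every
passage (zero-filled), so per-passage fractions sum to 100 and the output
feeds area plots directly.

## Limiting-dilution statistics

Under the single-hit Poisson model a well at nominal dose `d` is negative
with probability `exp(-f d)`; the nominal dose is interpreted as the
Poisson mean of cells actually seeded, which is what lets 1-cell/well doses
make sense. The log likelihood over dilution groups,

```
l(f) = Σ_g [ neg_g (-f d_g) + pos_g ln(1 - e^(-f d_g)) ],
```

is concave in `f`, so the MLE is found as the root of the score function by
bracketed root-finding (xtol 1e-14); single-group designs agree with the
closed form `-ln(neg/tested)/d` to better than 1e-8 by construction, and
tests verify the optimum against a 1e5-point grid search and an independent
binomial GLM with complementary-log-log link and log-dose offset. The 95%
CI is the profile-likelihood set `{f : 2[l(f_hat) - l(f)] <= 3.841}`
(chi-square(1) at 0.95). Degenerate designs are handled explicitly rather
than raised: all-negative gives `f_hat = 0` with a one-sided upper bound;
all-positive gives a boundary estimate at the parameter maximum flagged
`converged = False` (such plates do occur at high frequencies).

Monoclonality of a positive well is the zero-truncated Poisson mass at one,
`p1(λ) = λ e^(-λ)/(1 - e^(-λ))` with `λ = f d`, computed via `expm1` for
stability and returning the limit 1 at `λ = 0`. The dose filter passes on
strict `p1 > 0.5`. Differentiation scoring uses strict thresholds —
adipogenic positive iff the fat-droplet cell fraction exceeds 0.10,
osteogenic positive iff background-normalised absorbance exceeds 0.4 — and
summaries always report their denominators; an empty monoclonal subset is
flagged, never silently NaN.

## Methylation patterns

Input is per-read binary CpG state strings (alignment and CpG calling are
upstream of this package). Pattern identity requires complete strings, so
reads with missing calls (`.`) are dropped by default (imputation to a
fixed state is available). Default amplicons: GRM7 (22 CpGs), CASR (7),
PDE4C (26). `pattern_dominance` compares an early and a late sample of one
amplicon and flags a dominance event when the late top pattern's share
strictly exceeds a threshold **and** has increased since the early sample.
The 25% default threshold is a pipeline convention — there is no canonical
quantitative criterion for a pattern "becoming dominant" — and should be
read as such.

## The synthetic-data generator

The generator reproduces the statistical structure the analysis assumes:

* **Labeling**: integration counts per cell are Poisson(MOI); selection
  removes the zero class (zero-truncated Poisson copy number), colors are
  uniform per integration, UMIs uniform over 4^16. Survivor count is
  therefore Binomial(n_cells, 1 - e^(-MOI)) in expectation. Optional clone
  fitness is lognormal with log-sd `fitness_sd` (exactly 1 when 0) — the
  simplest strictly positive growth-weight model; the generator supports
  both neutral drift and fitness-driven outgrowth and asserts neither as
  the cause of dominance.
* **Passaging**: deterministic fitness-weighted growth followed by a
  multinomial draw of `bottleneck_size` cells (Wright–Fisher resampling).
  Neutral expected heterozygosity decays by `(1 - 1/N)` per passage, which
  the tests verify by Monte-Carlo; `bottleneck_size=None` is the
  no-resampling limit that preserves fractions exactly.
* **Differentiation bottleneck**: `n_recruited` cells drawn without
  replacement (multivariate hypergeometric) seed the derived population.
* **Sequencing**: each read is flank + primer + tag + UMI + primer + flank
  (random 20-nt flanks) with i.i.d. substitutions at `seq_error_rate` per
  base; reads are allocated to integrations proportionally to clone cell
  count, each integration of a multi-copy founder contributing its own
  amplifiable barcode. A truth table maps every read id to its founder and
  integration. Base qualities are a constant placeholder; the pipeline
  never reads them.
* **Dilution assays**: positives per dose are
  Binomial(wells, 1 - e^(-f d)) — the same single-hit model the estimator
  assumes. Default design: doses 30/10/3/1 cells per well, 96 wells each.
* **Methylation**: each founder gets a random binary pattern; a read
  samples a clone by abundance and reports the founder pattern after
  independent per-CpG flips. With per-passage flip probability `r`
  accumulated over `t` passages, a CpG differs from the founder state with
  probability `(1 - (1-2r)^t)/2` (two-state Markov chain), approaching 1/2
  as epimutations saturate.

Everything is driven by explicit seeds; identical configurations produce
byte-identical FASTQ and tables. What the generator does **not** emulate:
PCR duplicates and chimeras, quality-score-dependent error profiles,
indels in reads (substitution-only by default, so the 31 barcode positions
stay well defined), fluorophore gene silencing, and cell-cycle or
senescence structure. Passing tests therefore demonstrate correctness of
the analysis under the stated generative model, not robustness to every
artefact of real libraries.

## The demonstration and the replicated experiments

`clonotrace demo` simulates three arms from one global seed (per-stage
child seeds are derived as `SeedSequence(seed, spawn_key=(crc32(stage),))`,
reduced below 2^31, so stages can be rerun stably):

* MSC-like: bottleneck 500, 6 passages;
* iPSC-like: bottleneck 2000, 10 passages;
* iMSC-like: the iPSC population at passage 3, squeezed to 3 recruited
  founders, then 5 passages at bottleneck 500 — the arm's trajectory starts
  with the pre-bottleneck state so the one-passage diversity drop is
  visible.

Labeling uses 30 000 cells at MOI 0.01 (~300 founders, ≥99% single
integration). The low-MOI regime is chosen deliberately: with one
integration per founder, barcode clones coincide with cell clones, so a
3-founder recruitment yields a top-3 barcode share of exactly 100% and the
per-arm Shannon series measures cell clonality directly. Demo sequencing is
error-free (3000 reads per passage); the error-collapse path is exercised
by its own experiments rather than by the demo. These are documented
modelling assumptions, not estimates of any particular experiment — MOI and
transduction efficiency vary between protocols.

`clonotrace.experiments` packages the replicated studies used by the test
suite and the acceptance script, at these problem sizes:

* `dilution_recovery`: 2000 simulated four-dose assays per frequency
  (0.058, 0.207, 0.20, 0.382). 2000 replicates keep the Monte-Carlo SE of
  the coverage estimate near 0.5 points, small against the 93–97%
  acceptance band; median relative bias of the MLE is below 1% at all four
  frequencies.
* `headline_contrast`: 100 seeded replicates of the passaging vs
  bottleneck arms, diversity computed on the populations themselves.
* `methylation_concordance`: 100 runs per condition; 50 single-integration
  founders with distinct random 7-CpG patterns, neutral passaging
  (bottleneck 1000) to passage 2 (early sample), then either a bottleneck
  to 2 cells plus two passages or neutral continuation (control), 2000
  pattern reads per sample. The 7-CpG amplicon is the deliberate choice
  here: at flip rate 0.01 accumulated over four passages a 7-CpG pattern
  survives intact with probability ~0.76, so clonal dominance is visible in
  the top-pattern share, whereas a 22-CpG pattern survives with probability
  ~0.3 and would hide even complete clonality below any sensible dominance
  threshold. At flip rate 0.2 patterns randomise and the flag rate
  collapses — quantifying why epiallele dominance is an unreliable
  surrogate for clonal dominance under high epimutation noise.

## Numerical conventions and edge cases

* Coordinates are 0-based half-open internally; report files state 1-based
  positions where positions appear.
* Deterministic orderings throughout: clones and patterns sort by
  descending count then lexicographic label; equal-score trim placements by
  leftmost inner start then shortest inner.
* Fractions sum to 100 within 1e-9 before and after collapse; totals are
  conserved exactly (integer arithmetic).
* `N` bases in reads are kept verbatim; they simply count as mismatches or
  edits where compared.
* An extinct simulated population raises an error carrying the passage
  index; an empty population cannot be sequenced.

## Known limitations

* The collapse rule is single-link from parents only (no transitive
  chains), so UMIs at Hamming distance 2 from their true parent survive as
  spurious singletons; at 1% per-base error this leaves ~1% of reads in
  satellite clones (Jensen–Shannon divergence from truth ~0.004 at 10^4
  reads).
* The profile-likelihood CI assumes the single-hit model holds; real plates
  with cooperative growth or cross-feeding violate it in ways the package
  does not detect.
* Pattern dominance is descriptive; no significance test is attached, and
  the threshold is a convention.
* Paired-end handling is id-based deduplication, not read merging; overlap
  consensus is out of scope.
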