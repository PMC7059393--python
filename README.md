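# clonotrace

Clonal tracking for **multicolor (RGB) lentiviral genetic barcoding** of
cultured cells — primary mesenchymal stromal cells (MSCs), induced
pluripotent stem cells (iPSCs) and iPSC-derived MSCs (iMSCs) — with the
statistics that go with such experiments: barcode extraction from amplicon
sequencing reads, clone-abundance and Shannon-diversity trajectories across
passages, single-hit Poisson limiting-dilution analysis of colony-forming
(CFU-f) frequency and monoclonality, and per-read DNA-methylation-pattern
(epiallele) dominance analysis. A synthetic-data generator emulates the
whole experimental design, so every stage can be validated against known
ground truth.

It is intended for labs running barcoded culture-expansion experiments who
need a tested, scriptable alternative to one-off processing scripts, and for
methodologists studying how clonal composition measures behave under drift,
bottlenecks and sequencing noise.

## The data model and the statistics

Each lentiviral construct carries a cassette flanked by fixed PCR primers:

```
... ACCATCTAGA [15-nt color tag][16-nt random UMI] CTCGAGACTG ...
```

The color tag identifies the fluorophore vector (mCherry, Venus or
Cerulean); the 16-nt random stretch (UMI, 4^16 possibilities) makes every
integration unique. A **clone label is the (color, UMI) pair**, and a
clone's abundance in a sample is the percentage of barcode reads carrying
its label.

* **Extraction.** Reads are trimmed by locating the best ordered placement
  of both primers under an edit-distance allowance of
  `floor(rate x primer_length)` per primer (2 edits for the 10-mers at the
  default rate 0.2, substitutions and indels both counted — the linked-
  adapter convention). The color is called by Hamming distance on the first
  15 nt of the insert; the UMI is positions 16–31. Reads without both
  delimiters are discarded as barcode-free.
* **Diversity.** For clone proportions `p_i`, the Shannon index is
  `H = -Σ p_i ln p_i`, with richness, Pielou evenness `H / ln(richness)`
  and the cumulative share of the top-k clones (default k = 3).
  Near-duplicate UMIs arising from sequencing errors can be merged by
  directional collapse (Hamming ≤ 1 into a ≥10x more abundant parent of the
  same color).
* **Limiting dilution.** With `d` cells seeded per well and clonogenic
  frequency `f`, a well is negative with probability `exp(-f·d)` (single-hit
  Poisson). `f` is estimated by maximum likelihood over all dilution steps
  with a profile-likelihood 95% CI. The probability that a positive well is
  single-cell derived is the zero-truncated Poisson mass
  `f·d·e^(-f·d) / (1 - e^(-f·d))`; wells are scored for adipogenic
  (> 10% fat-droplet cells) and osteogenic (absorbance > 0.4)
  differentiation only at doses where that probability exceeds 50%.
* **Methylation patterns.** Bisulfite amplicon reads are reduced to binary
  CpG state strings (defaults: GRM7 22 CpGs, CASR 7, PDE4C 26); the package
  tabulates exact-pattern frequencies, per-CpG mean methylation, and flags
  early-to-late pattern *dominance* — a proxy for clonal dominance whose
  reliability degrades as the epimutation rate rises.

## Worked example

Fit a CFU-f frequency from one dilution step (96 wells at 10 cells/well,
60 positive):

```python
>>> import clonotrace as ct
>>> est = ct.fit_frequency(ct.DilutionDesign.from_counts([10], [96], [60]))
>>> round(est.f_hat, 5), round(est.ci_low, 5), round(est.ci_high, 5)
(0.09808, 0.07461, 0.12645)
```

The point estimate equals the closed form `-ln(36/96)/10`: about 9.8% of
seeded cells form colonies, with a 95% profile-likelihood CI of 7.5–12.6%.
At that frequency a 1-cell/well dose is probably monoclonal
(`ct.monoclonality_probability(0.09808, 1)` ≈ 0.952 > 0.5) while
30 cells/well is not (≈ 0.164).

The one-command demonstration simulates the three culture arms from a
single seed and runs the full pipeline on the synthetic reads:

```bash
clonotrace demo --seed 1 --out-dir demo_out
```

`demo_out/summary.json` (seed 1) contains, among others:

| arm  | initial H | final H | decline | top-3 share at end |
|------|-----------|---------|---------|--------------------|
| MSC  | 5.667     | 4.479   | 21.0%   | 9.1%               |
| iPSC | 5.702     | 4.974   | 12.8%   | 7.1%               |
| iMSC | 5.425     | 1.094   | 79.8%   | 100.0%             |

The serially passaged arms lose diversity gradually (Wright–Fisher drift
through a per-passage bottleneck), while the iMSC arm — seeded from only
three recruited founder cells at differentiation — collapses to an
oligoclonal population in a single step: the headline contrast between
culture expansion and differentiation bottlenecks. The directory also holds
area-plot-ready trajectory TSVs, per-passage diversity tables, a
limiting-dilution fit (true frequency 5.8%, recovered 5.95% [5.0, 7.1]) and
an early-vs-late methylation-pattern dominance report.

All stages are also available individually (`clonotrace extract | clones |
diversity | dilution | methylation | simulate`) on TSV/FASTQ/JSON
interfaces; see `clonotrace <cmd> --help`.

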