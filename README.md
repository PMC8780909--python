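# ttkin — mRNA half-life inference from 4SU/TT-seq metabolic labeling

`ttkin` analyzes transient-transcriptome sequencing (TT-seq) experiments in
which cells are pulsed with 4-thiouridine (4SU) so that newly transcribed
RNA can be purified and sequenced alongside total RNA. It was built for the
kind of study that asks how an RNA-binding-protein knockout (e.g. of the
m6A reader YTHDF1) changes mRNA stability genome-wide: estimate per-gene
half-lives in both conditions, classify which transcripts are stabilized,
test the shift over m6A-modified genes, and relate the changes to
m6A/YTHDF1/AGO2 binding along transcripts.

## The model

Under first-order decay with rate *k*, a 4SU pulse of length *t<sub>L</sub>*
labels the fraction

&nbsp;&nbsp;&nbsp;&nbsp;*R* = 1 − e<sup>−k·t<sub>L</sub></sup>

of a gene's steady-state mRNA pool, so the half-life follows from the
spike-in-normalized nascent/total count ratio:

&nbsp;&nbsp;&nbsp;&nbsp;*t*<sub>½</sub> = ln 2 / *k* = −*t<sub>L</sub>* · ln 2 / ln(1 − *R*)

Around this transform the package provides:

- **`simulate`** — a generative model of the whole experiment (steady-state
  abundances, labeled fractions, exogenous spike-ins, per-sample depth
  distortions, negative-binomial counts, planted target genes and
  m6A/YTHDF1/AGO2 peak sets) so every stage is testable by parameter
  recovery against known truth.
- **`normalization`** — DESeq2-style median-of-ratios size factors computed
  on spike-in genes only (the spike-in is 4SU-labeled, hence present in
  both assays, anchoring the nascent/total ratio).
- **`kinetics`** — the ratio→half-life transform with QC flags (no silent
  clamping of out-of-range ratios), 1.5× prolonged/shortened change calls,
  and log-linear fitting of transcription-shutoff (actinomycin D) decay
  curves.
- **`stats`** — a Wilcoxon signed-rank test (exact by rank-sum convolution
  for n ≤ 15 including ties, Edgeworth-corrected normal approximation
  otherwise) and the resampled comparison: 10,000 iterations each averaging
  the half-lives of 10 randomly drawn eligible genes per condition.
- **`genomics`** — BED peak sets, midpoint region assignment on 5′UTR/CDS/
  3′UTR transcript models (strand-aware, 0-based half-open), three-set Venn
  partitions, reader/AGO2 co-binding fractions, and metagene density
  profiles on the [0,3) axis.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(from the repository root, in order):

```sh
python analysis/01_simulate_experiment.py
python analysis/02_estimate_halflives.py
python analysis/03_compare_conditions.py
python analysis/04_peak_landscape.py
python analysis/05_decay_curves.py
```

`01` writes a default experiment — 2,000 genes + 50 spike-ins, 2 replicates
× {nascent, total} × {WT, KO} at 2×10⁶ expected reads, 25% target genes
whose half-life doubles in the KO — under `results/synthetic/`. `02` then
prints:

```
size factors recover per-sample depth scales to 2.14% (worst sample)
QC: {'ok': 3799, 'ratio_out_of_range': 162, 'low_count': 39}
WT: median |log2(est/true)| = 0.061 over 1742 well-covered genes
KO: median |log2(est/true)| = 0.061 over 1718 well-covered genes
```

i.e. half-lives are recovered with a typical error of ~4% for genes with
≥50 mean total counts. `03` classifies changes and runs the comparison:

```
of 1841 called genes: 477 prolonged (>=1.5x), 50 shortened, 1314 unchanged; 1072 with KO/WT > 1
target recovery: 92.5% of callable targets (95.6% callable)
resampled comparison over 478 m6A genes: mean t1/2 149.3 -> 293.2 min, p = 0 (gene-level p = 0)
null calibration (20 fresh no-effect experiments):
  p > 0.05 in 14/20 seeds — the iteration-level p-value over-rejects under the null (see docs/methods.md)
```

The planted twofold stabilization of target genes is detected with 92.5%
sensitivity at the 1.5× threshold, and the resampled comparison is
overwhelmingly significant; the null-calibration lines illustrate a real
limitation of the resampling procedure that is discussed in
`docs/methods.md`. `04` reports that 92.0% of YTHDF1-bound mRNAs are also
AGO2-occupied, that prolonged mRNAs are dominated by the triple-bound set
(Venn `abc: 430` of 1072), and that all three peak sets concentrate in the
3′UTR of the metagene profile. `05` fits shutoff decay curves, recovering
e.g. a 45-min transcript to within 0.5% at 5% measurement noise.

The same stages are available as subcommands of the `ttkin` CLI
(`simulate`, `normalize`, `halflife`, `compare`, `overlap`, `metagene`,
`decayfit`, `run-all`); `ttkin run-all` executes everything end to end from
a YAML config, writing a deterministic `summary.json`.

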