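# Methods

## Kinetic model

Each gene is modeled as synthesized at constant rate *s* (arbitrary
units·min⁻¹) and degraded first-order with rate *k* (min⁻¹), so the
steady-state abundance is *s/k* and the half-life is *t*½ = ln 2/*k*.
During a 4SU pulse of length *t*L (default 60 min, the standard one-hour
labeling), the newly made — hence 4SU-labeled — fraction of the pool is
*R* = 1 − e^(−k·tL), giving

    t½ = −tL · ln 2 / ln(1 − R),

with *R* estimated per gene as (mean normalized nascent count across
replicates) / (mean normalized total count). The model assumes steady
state during labeling (no synthesis or decay change within the pulse),
uniform 4SU capture across transcripts, and a single decay rate per gene.
Multi-exponential decay, incorporation bias, and synthesis–degradation
joint modeling are out of scope.

Quality control: genes whose mean raw total count falls below `min_count`
(default 10; *R* is a ratio of means and unstable at low depth) are flagged
`low_count`; genes with *R* outside the open interval (0, 1) are flagged
`ratio_out_of_range`. Flagged genes carry no half-life and receive no
change call. Ratios are never clamped: truncating *R* at 1 − ε would
fabricate arbitrarily short half-lives for exactly the genes the data say
least about. Note the transform's sensitivity d ln t½/d ln R =
R/((1−R)·|ln(1−R)|), which is ≈1.4 at R = 0.5 but ≈15 at R = 0.98: with a
60-min pulse, half-lives much shorter than ~20 min (or much longer than
~10 h) are intrinsically poorly determined, whatever the sequencing depth.
A related floating-point fact: for t½ ≲ 2.5 min at tL = 60, R is
indistinguishable from 1 in double precision, so such ratios are rejected
rather than round-tripped.

## Spike-in normalization

Exogenous 4SU-labeled spike-in RNA is added in a fixed amount per sample
and therefore appears in both the nascent and the total library; its counts
identify each library's depth. Size factors are the median-of-ratios
statistic restricted to spike-in genes: per spike-in gene a geometric-mean
reference across samples (genes with any zero count are dropped from the
reference, the standard convention), per sample the median count/reference
ratio. One factor set serves both assays — precisely what the
nascent/total ratio requires. Factors are not rescaled to geometric mean 1;
only ratios of factors matter downstream. With *m* spike-ins at *r* reads
each, the factor error is ≈ 1.25·√((1 + 1/n_samples)/r)/√m (median
asymptotics), i.e. ~0.9% at 50 spike-ins × 400 reads — an error floor that
matters for the comparison's null behavior (below). No latent-factor
(RUV-style) correction is applied: spike-ins alone identify depth, and the
half-life formula needs only relative nascent/total scaling.

## Change classification

Per gene, the half-life ratio KO/WT is called `prolonged` when ≥ the fold
threshold (default 1.5, boundary inclusive, matching "at least 1.5×"),
`shortened` when ≤ its reciprocal, `unchanged` otherwise; genes flagged in
either condition are refused a call. Recovery statistics therefore report
sensitivity among callable genes together with the callable fraction, plus
the all-target figure, so the two are never conflated.

## Resampled comparison

To summarize the condition-level shift over m6A-modified genes, each of
10,000 iterations draws 10 eligible genes per condition without replacement
and records the two panel-mean half-lives; the 10,000 paired iteration
means then feed one two-sided Wilcoxon signed-rank test. Panels are drawn
independently per condition by default ("selected randomly from wild type
cells and knockout cells respectively"); a shared-panel variant
(`mode="paired"`) is available.

**Caveat (by construction):** the 10,000 pairs resample one finite gene
pool and are not independent, so the test's n vastly overstates the
information present and the p-value is anti-conservative. Concretely, any
realized nonzero offset of the pool mean — from per-gene estimation noise
(heavy-tailed: absolute error grows ≈ t^1.5 beyond the pulse length) and,
irreducibly, from the ~1% coherent size-factor error that shifts every KO
half-life together — is amplified into arbitrarily small p-values as
iterations grow. In no-effect simulations the procedure rejects at
p < 0.05 in roughly 25–30% of experiments rather than 5%. The
implementation is kept faithful to the described procedure, and a
plain gene-level signed-rank test over the eligible pool (one pair per
gene) is always reported alongside as the honest secondary statistic.
Readers should treat the iteration-level p-value as a descriptive summary
of the resampling, not as a calibrated error rate.

## Wilcoxon signed-rank test

Zero differences are discarded; tied |differences| get average ranks; the
statistic is W = min(positive, negative rank sum). For n ≤ 15 non-zero
differences the two-sided p is exact: the full null distribution of the
rank sum is built by dynamic-programming convolution over the doubled
(hence integral) ranks, which handles ties, and p = P(min tail ≤ W).
Beyond that, a normal approximation with moments computed directly from
the average ranks (mean Σr/2, variance Σr²/4 — the tie correction falls
out automatically), a 0.5 continuity correction, and an Edgeworth kurtosis
term (the null is symmetric, so the skewness term vanishes; the fourth
cumulant of Σ rᵢ·Bernoulli(½) is −Σrᵢ⁴/8). The kurtosis term brings the
n = 13–15 approximation within ~10⁻³ of exact; without it mid-range
p-values are off by ~0.01. All-zero differences return p = 1 with a
degenerate flag.

## Peak genomics

Coordinates are 0-based half-open throughout; BED6 is read and written
unchanged. A transcript model is three ordered exonic block lists (5′UTR,
CDS, 3′UTR) in transcript orientation. Peaks are reduced to their midpoint
base; the midpoint's region is decided by half-open block membership, so a
region boundary belongs to the downstream region, and intronic or outside
midpoints map to none. Metagene coordinates rescale the position within
the containing region to unit length, offset 0/1/2 for 5′UTR/CDS/3′UTR;
profiles are density-normalized histograms over [0, 3). A "bound" mRNA is
by default a gene with any exonic peak (configurable to 3′UTR-only, the
stricter definition used for m6A). When a midpoint falls in several genes'
models, every such gene counts. Liftover between assemblies is out of
scope; all inputs must share one coordinate system.

## Decay-curve fitting

Shutoff time courses (relative abundance after transcription inhibition)
are fitted by ordinary least squares of ln(abundance) on time; t½ =
−ln 2/slope. Log-space fitting matches the single-rate model exactly, is
deterministic, and weights multiplicative noise correctly. A non-negative
slope is reported as non-decaying (flagged, t½ = NaN) rather than as a
negative half-life. At least 3 timepoints and strictly positive abundances
are required.

## The synthetic-data generator

The generator emulates the measurement process the analysis assumes, with
known ground truth recorded for every quantity the pipeline estimates:

- **Kinetics.** WT half-lives log-uniform on 10–600 min (a deliberately
  wide desk-scale range spanning unstable to stable transcripts; the upper
  decade is intentionally hard for a 60-min pulse). Synthesis rates
  log-normal (σ = 1). A `target_fraction` (default 25%) of genes has its
  KO decay slowed `ko_halflife_fold`-fold (default 2); all other genes and
  all spike-ins are condition-invariant.
- **Assays.** Total abundance ∝ s/k; nascent abundance = total ×
  (1 − e^(−k·tL)) × capture efficiency (default 1; the parameter exists
  for sensitivity tests, and because the spike-in is also 4SU-labeled a
  uniform capture loss cancels after normalization). Spike-ins (default 50,
  1% of library mass) have equal expected abundance in every sample.
- **Depth.** Each sample's expected depth is `library_size` × a log-normal
  distortion (σ = 0.2), giving normalization something real to correct;
  the exact per-sample expected scale is recorded.
- **Counts.** Marginally negative binomial with shared dispersion (default
  0.05; Poisson when 0). The overdispersion enters as a per-(gene,
  condition, replicate) gamma factor shared between the nascent and total
  libraries of that replicate — in the TT-seq protocol both are prepared
  from one RNA extraction, so biological replicate variability is common
  to them — with Poisson counting noise on top. Spike-ins receive counting
  noise only: the spiked pool is the same in every tube. These two choices
  are what make ratio-based half-life recovery and 2%-level size-factor
  recovery possible at all; fully independent per-sample noise would put a
  ~23% floor on the ratio error at dispersion 0.05.
- **Structures and peaks.** One single-block-per-region transcript per
  gene on a synthetic chromosome (random strand, 5′UTR 100–300, CDS
  600–3000, 3′UTR 200–1200 nt). m6A and YTHDF1 peaks are placed uniformly
  in the 3′UTR of each target gene (one per factor per gene); AGO2 peaks
  cover a configurable fraction (default 92%) of the YTHDF1 targets plus a
  10% background of non-targets, so reader/AGO2 co-binding and
  Venn-partition logic can be validated against planted truth.
- **Determinism.** A single RNG stream keyed by `seed`; identical
  parameters give bit-identical outputs.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: isoform mixtures and intron signal,
positional/sequence bias, 4SU incorporation toxicity and dose effects,
cross-contamination between nascent and total fractions, batch structure
beyond scalar depth, and peak-calling noise (peaks are planted, not
called). Results on real data additionally depend on annotation quality
and on the labeling-time choice relative to the half-life range of
interest.

## Problem sizes and numerical choices

Default analyses and tests run at 2,000 genes × 8 samples × 2×10⁶ reads —
small enough for interactive runs, large enough that per-gene counts
(~1,000) put recovery in the regime the estimator targets. High-depth
consistency checks use fewer genes at ≥10⁷ counts/gene. The resampled
comparison uses its full 10,000 iterations everywhere. Spike-in-recovery
checks run at a 5% spike-in mass fraction (~2,000 reads/spike-in), where
the median-of-ratios sampling floor (~1.3% max over samples) sits safely
under the 2% tolerance being verified; at 400 reads/spike-in the floor
itself is ~2.6%. Exact-test checks enumerate all 2ⁿ sign assignments up to
n = 12 as an independent oracle. Tie-breaks and degenerate inputs: zero
differences are discarded (classic Wilcoxon, not Pratt); a zero-length
eligible pool or a pool smaller than the panel size is an error, never a
silent fallback; empty peak sets yield empty gene sets and zero-density
profiles with the mapped-peak count reported.
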