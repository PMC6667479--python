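# Methods

chronosplice implements a desk-scale version of a circadian transcriptomics
pipeline: calling oscillating genes in short expression time courses,
testing for time-dependent alternative splicing from probe-level signals,
and asking whether two labelled gene sets (splicing factors and
clock-regulated genes) interact on a protein–protein network more often
than random sets would. A synthetic-data generator provides
ground-truth-annotated inputs with the statistical structure these analyses
assume, so every stage is testable without external downloads.

## Rhythm detection

### Model

Each gene's log2 expression series y(t) is fitted with the three-parameter
cosinor

    y(t) = m + a·cos(ωt) + b·sin(ωt),    ω = 2π/T

by ordinary least squares at a fixed candidate period T. The derived
quantities are the mesor m (rhythm-adjusted mean), amplitude
A = √(a² + b²), and acrophase φ = atan2(b, a), reported in hours as
φ_h = (φ/2π)·T mod T so that φ_h is the clock time of the model peak
(cosine convention: y = m + A·cos(2π(t − φ_h)/T)). Significance is the
F-test of (a, b) = (0, 0) against the intercept-only model with
(2, n − 3) degrees of freedom; with Gaussian noise this null distribution
is exact, and the implementation reproduces noiseless cosinor inputs to
machine precision (verified to 1e-8 in the test suite).

Degenerate inputs are handled explicitly: a constant series returns
A = 0, F = 0, p = 1 (the null model is exact); a perfect fit returns
p = 0; sampling times that alias the candidate period (singular design)
raise a conditioning error; fewer than 4 points raise an
insufficient-data error.

### Period scan and oscillation calling

`scan_periods` evaluates a period grid and returns the fit with the
smallest p, breaking ties toward the lower period. Two grids are used by
convention: 21–27 h for calling oscillators in array-style data, and
14–27 h in 0.1 h steps for reporting fitted qPCR rhythms. With 9 samples
spanning 24 h the cosinor designs at nearby periods are almost collinear,
so the scan step has essentially no effect on calling behaviour.

`detect_oscillating` combines two per-gene p-values by Fisher's method
(−2Σln p ~ χ²₄): the harmonic F-test p at the best period of the scan,
and a nonparametric companion test at that period. The companion test
computes Kendall's τ between the observed series and a cosine reference
evaluated at `phase_grid` acrophases spanning one cycle, takes the
minimal one-sided exact-τ p, and Bonferroni-corrects it for the number of
phases; anti-phase signals are caught by the phase grid itself, and a
constant series returns p = 1. The default `phase_grid` is 24, i.e. one
hour of phase resolution at circadian periods, chosen by a
null-calibration simulation (flat Gaussian genes) the way reference grids
of rank-based periodicity tests are conventionally set.

Two calibration caveats are deliberate and documented rather than hidden:

- The scan's minimum-p is not corrected for the size of the period grid,
  and the two combined tests are computed from the same data, so
  Fisher's independence assumption does not hold. The combined test is
  therefore mildly anticonservative: simulations at the default settings
  show a false-positive rate of roughly 0.07–0.10 at a nominal 0.05
  threshold. Raw-p thresholding reproduces the calling convention of the
  array analyses this emulates; a Benjamini–Hochberg option
  (`adjust="bh"`) is available for work that needs control across genes.
- A monotone trend is locally indistinguishable from a small arc of a
  much longer period, so testing periods far beyond the sampled span is
  not meaningful with either component test.

`acrophase_shift` reports the signed minimal circular difference of two
acrophases, mapped to (−T/2, T/2], with negative values meaning the
second condition peaks earlier. It requires the two fits to agree on
period within 10% because a phase difference is only defined at a shared
period.

## Differential splicing

### PSI estimation

A splicing event is quantified by two sets of probes measuring the
inclusion and exclusion paths. Per sample, PSI = I/(I + E) where I and E
are the medians of the linear-scale (2^x) probe intensities of each path.
The median (rather than mean) makes the estimate robust to a single
aberrant probe. PSI is undefined (an error, not a silent value) when both
paths are at linear zero.

### Binned contrasts

With one array per time point there are no biological replicates, so time
points are grouped into chronological bins of two and the two members of
a bin are treated as replicates of a bin condition; consecutive bins form
the contrasts. The default design drops the 18 h sample (an outlier in
the study this emulates) leaving four bins, (6,9) (12,15) (21,24)
(27,30), and three comparisons. The caveat is inherent and stated: the
temporal trend within a bin inflates the within-group variance, which
costs power (see the recovery numbers below) but never validity.

### Interaction test

For one event and one comparison, the model

    log2 intensity = μ + sample + path + path×bin

is fitted by least squares over all probes of both paths and the four
samples; the p-value is the F-test (1 df) of the path×bin interaction —
the term a change in isoform balance between bins loads. ΔPSI is
reported separately as mean PSI(later bin) − mean PSI(earlier bin).

Probe main effects are intentionally not modelled (the model is the
fully specified, oracle-verifiable replacement for a package-internal
contrast). Because the design is balanced, probe-affinity spread is
orthogonal to the interaction and only inflates the residual: with
heterogeneous affinities the test is conservative, never
anticonservative. Under shared affinities its null p-values are uniform
(KS ≈ 0.03–0.05 in the suite's 500-event null).

### Filtering and ranking

Two filters exist with deliberately different boundary conventions,
matching the two conventions of the analysis this reproduces:

- per-comparison: keep events with p < 0.01 AND |ΔPSI| > 0.1, both strict;
- recurrent intersection: events present at identical coordinates in all
  comparisons with p < 0.01 in every one and |ΔPSI| ≥ 0.1 in at least one.

Recurrent events are ranked by the sample variance (n − 1 denominator) of
their per-comparison ΔPSI values, descending, ties broken by event id for
determinism. On synthetic data (200 events with PSI = 0.5 + 0.3·cos(2πt/24)
against 200 constant-PSI decoys at the default noise settings) no decoy
survives the recurrent filter and the top quartile of the ranked list is
entirely composed of true temporal events; about 75–80% of the true
events pass the all-comparison p filter, the shortfall coming from the
two flanking contrasts of that sinusoid (|ΔPSI| = 0.15) in combination
with the within-bin trend noted above.

### Event classification

Event types are assigned from the genomic structure of the two paths
(0-based half-open intervals, genomic order, strand-aware): cassette exon
(one extra internal interval, shared flanks both sides), intron retention
(one interval spanning the other path's two plus the gap), alternative
donor/acceptor (one differing internal interval sharing one boundary;
donor vs acceptor decided by strand), alternative first/last exon
(divergence reaching an unflanked transcript end), and complex for
anything else. Identical paths are an annotation error.

## Network analysis

Networks are undirected and deduplicated; self-loops are dropped at load
and node identifiers are opaque strings (no namespace mapping). Cross-set
interaction counting is symmetric and counts an edge once even when both
endpoints carry both labels, which preserves the conservation identity
mean-degree(a)·|a| = mean-degree(b)·|b| = cross count.

The resampling null draws N (default 100) uniform node sets of the
observed set's size from the universe of all network nodes not in the
fixed set, counts each set's edges to the fixed set, and reports mean, SD
(n − 1) and the add-one empirical p = (1 + #{null ≥ observed})/(N + 1),
which is never zero. The sampling universe is a configurable choice; the
default (network nodes outside the fixed set) keeps the null
degree-realistic without external gene lists.

Communities are found per connected component by deterministic greedy
modularity maximization (CNM-style); cluster ids are ordered by size then
lexicographic smallest member, so output is reproducible without relying
on the seed. Over-representation uses the one-sided hypergeometric upper
tail P[X ≥ overlap] with sets intersected with the universe first, and
Benjamini–Hochberg adjustment across all tested sets (including
zero-overlap ones — the standard step-up definition).

## qPCR quantification

CT replicates are averaged per sample and gene; ΔCT subtracts the
reference gene's CT per sample; ΔΔCT subtracts the calibrator ΔCT — a
named control sample, or in time-course mode the per-gene mean ΔCT across
samples; relative expression is 2^−ΔΔCT with amplification efficiency
fixed at 2 (no efficiency correction). Rhythm fits run on −ΔΔCT (log2
relative expression) per gene and condition over the 14–27 h grid. The
reported acrophase shift refits the perturbed condition at the reference
condition's best period before comparing acrophases, because acrophases
at different periods are not commensurable.

## Synthetic data

The generator mirrors the emulated study design: 9 samples every 3 h from
6 h to 30 h after synchronization, one array per time point. Expression
noise is Gaussian on the log2 scale; oscillators follow
m + A·cos(2π(t − φ)/T) with T uniform on the configured band (default
21–27 h), acrophase uniform on [0, T), mesor N(8, 1) on a typical
microarray log2 scale. Oscillator assignment takes the first
⌈frac_osc·n⌉ genes after a seeded shuffle so the count is deterministic.
Defaults: 1000 genes, frac_osc 0.3, amplitude 1.0, noise SD 0.5
(amplitude-to-noise 2, the regime the recovery checks are run at).

Splicing events carry a PSI trajectory (constant, sinusoidal or step);
the inclusion path holds total_abundance·PSI(t) on the linear scale, the
exclusion path the complement, each probe multiplies its path by a fixed
log-normal affinity (σ = 0.2 log2 units by default, a realistic spread
for short oligo probes) and log2-domain Gaussian noise (default SD 0.1)
is added. A PSI of exactly 0 or 1 leaves the silent path at linear zero.

Labelled networks connect within-label pairs at p_within, SF×NCRG pairs
at p_cross·enrichment, and a background node group (default 500 nodes,
labelled ASG) to everything at the unenriched p_cross. The background
group exists so the resampling null has a non-degenerate universe;
enrichment deliberately applies only to the SF×NCRG pair so planted
enrichment is detectable against unenriched random sets. The default
sizes and rates (251 SF, 130 NCRG, p_cross = 0.0057) reproduce the
published network's printed set sizes and its 186 expected cross edges.

qPCR tables derive target CTs from cosinor log2 expression via
CT(t) = CT_ref − log_eff(2^cosinor), with per-replicate Gaussian CT noise
(cycles) and triplicate measurements.

What the generator does not emulate — probe-level microarray artifacts,
RMA normalization residue, batch effects, heteroskedastic counts — bounds
what the passing tests show: they validate the statistics under their own
assumptions (Gaussian log2 noise, fixed probe affinities), not microarray
preprocessing. Noise magnitudes are fixtures chosen at realistic levels,
not estimates of any deposited dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run each stage at the scale of
the emulated study or a size chosen for a stable property check: 1000
genes for calling and null calibration, 500 events for splicing
calibration, 400 events (200 true/200 decoy) for recovery, 100-resample
nulls with 50 repeats for calibration, exhaustive hypergeometric checks
for all universes up to 25 genes. Sums of squares below a relative 1e-24
are treated as exact zeros; p-values are floored at 1e-300 inside
Fisher's combination; empirical p-values use the add-one rule and cannot
be zero.

## Known limitations

- Oscillation calling is mildly anticonservative at the default raw-p
  threshold (see above); use the BH option when error control across
  genes matters.
- With one array per time point, within-bin temporal trends reduce the
  splicing test's power; bins are a signal-to-noise compromise inherited
  from the emulated design.
- The probe-level ANOVA omits probe main effects by specification; with
  heterogeneous probe affinities it is conservative.
- The network null's universe is the network itself, not the genome;
  empirical p-values are relative to that choice.
- Correlations over 8–9 time points have wide sampling variability; they
  are reported at full precision but should be read as descriptive.
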