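# chronosplice

Detection of circadian gene-expression rhythms, time-dependent
alternative splicing, and clock/splicing-factor network enrichment in
short expression time courses.

## The problem

Cells keep ~24 h time. Beyond driving rhythmic transcription, the clock
appears to modulate post-transcriptional steps: if splicing factors (SF)
are themselves clock-controlled, the isoform balance of their target
genes should change across the day. Testing this in a typical time-course
experiment — nine arrays taken every 3 h over 24 h, one array per time
point — requires three pieces of statistics, all provided here as a
reusable, tested library for computational biologists:

1. **Rhythm calling** (`chronosplice.rhythms`). Cosinor (harmonic)
   regression per gene,

   y(t) = m + a·cos(ωt) + b·sin(ωt),  amplitude A = √(a²+b²),
   acrophase φ = atan2(b, a),

   F-tested against the flat model and scanned over a circadian period
   band (21–27 h); a Kendall-τ rank test against phase-shifted cosine
   references serves as a nonparametric companion, and the two p-values
   are combined by Fisher's method.

2. **Differential splicing** (`chronosplice.splicing`). Per sample,
   PSI = I/(I+E) from the linear-scale medians of inclusion- and
   exclusion-path probes. Time points are paired into chronological bins
   (the 18 h outlier excluded by default), consecutive bins are
   contrasted with a probe-level ANOVA F-test of the path×bin
   interaction, events are filtered (p < 0.01, |ΔPSI| > 0.1), intersected
   across comparisons at identical coordinates, and ranked by ΔPSI
   variance. Events are classified (cassette exon, intron retention,
   alt 5'/3' splice site, alt first/last exon) from their genomic paths.

3. **Network enrichment** (`chronosplice.network`). Direct interactions
   between labelled node sets (SF vs clock-regulated genes) are counted
   on a protein-interaction network and calibrated against random node
   sets of the same size (add-one empirical p over 100 resamples), with
   degree summaries, greedy-modularity communities, and hypergeometric
   over-representation tests with Benjamini–Hochberg correction.

`chronosplice.downstream` adds Pearson/Spearman correlation of gene sets
across time and qPCR quantification by the 2^−ΔΔCT method feeding the
same rhythm fits; `chronosplice.simulate` generates
ground-truth-annotated synthetic inputs (expression matrices, probe-level
event signals, labelled networks, CT tables) so every stage is testable
offline. See `docs/methods.md` for models, assumptions and limitations.

## Worked example

```python
import numpy as np
from chronosplice import simulate, rhythms

matrix, truths = simulate.simulate_rhythmic_matrix(n_genes=500, frac_osc=0.3, seed=42)
calls = rhythms.detect_oscillating(matrix, period_range_h=(21.0, 27.0), alpha=0.05)

n_called = sum(c.is_oscillating for c in calls)
truth = {t.gene_id: t.is_oscillating for t in truths}
tp = sum(1 for c in calls if c.is_oscillating and truth[c.gene_id])
print(f"called {n_called} of 500 genes oscillating ({tp} of 150 true oscillators)")
top = calls[0]
print(f"top call: {top.gene_id}  T={top.best_period_h:.1f} h  "
      f"A={top.fit.amplitude:.2f}  phase={top.fit.acrophase_h:.1f} h  "
      f"combined p={top.combined_p:.2e}")
```

prints

```
called 158 of 500 genes oscillating (125 of 150 true oscillators)
top call: G00330  T=22.4 h  A=1.54  phase=2.8 h  combined p=2.63e-07
```

500 genes were simulated on the 6–30 h grid with 150 true oscillators at
amplitude-to-noise 2; the caller flags 158 genes at α = 0.05, recovering
125 true oscillators (sensitivity 0.83) with 33 false calls. The top call
is a true oscillator whose fitted period (22.4 h) and peak time (2.8 h
after synchronization) sit close to the generating truth (22.6 h, 3.5 h);
the amplitude is overestimated, as expected for the best-p gene of a
scan. Calls are sorted by combined p, so `calls[0]` is the strongest.

The same stages are available as a CLI for shell pipelines —
`chronosplice simulate | rhythms | splicing | network | correlate | qpcr`
— each accepting a YAML config (`--config`) and writing a JSON run-log
sidecar with version, seed and parameters.

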