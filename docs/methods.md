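# Methods

## Model

A rhythmic gene's expression over one circadian cycle is approximated by an
ideal cosine, baseline + amplitude · cos(2πt/T − φ), with period T fixed
(24 h by default; the package estimates phase, not period or amplitude).
The phase φ is estimated on a discrete grid: 2k templates at φ_i = iπ/k,
whose peak times θ_i = iT/(2k) are exactly the sampling times when the
sampling interval is T/(2k) (4 h at the defaults, k = 3). The estimate is
the peak time of the template with the largest Pearson correlation to the
series. Pearson is the default because correlation against a cosine
template with Pearson's normalisation is invariant to the gene's baseline
and amplitude — the same invariance a cosinor fit has; Spearman is exposed
as an option for heavy-tailed data. Arg-max ties are broken toward the
smallest phase, deterministically.

Peak-time bins G_i are centred on the template peaks with width T/(2k),
so G0 = [−2, 2], …, G5 = [18, 22] at defaults. A gene is *confidently
assigned* to G_i only when its whole bootstrap CI lies inside G_i; a CI
that straddles a bin boundary is the method's signal that the peak falls
ambiguously between sampling times.

## Maximum entropy bootstrap

Replicates are drawn from a maximum-entropy density constructed on the
intervals between consecutive order statistics x_(1) ≤ … ≤ x_(n):

- interval boundaries z_t = (x_(t) + x_(t+1))/2, extended by tail limits
  z_0 = x_(1) − m_trm and z_n = x_(n) + m_trm, where m_trm is the trimmed
  mean (default trim 0.10 from each end, the established convention) of the
  sorted-order spacings;
- probability mass 1/n uniformly on each interval, giving a piecewise-linear
  quantile function through (t/n, z_t);
- desired interval means m_1 = 0.75x_(1) + 0.25x_(2),
  m_t = 0.25x_(t−1) + 0.5x_(t) + 0.25x_(t+1),
  m_n = 0.25x_(n−1) + 0.75x_(n). For interior intervals these equal the
  interval midpoints, so the mean-preserving constraint is satisfied by the
  plain piecewise-linear quantile with no shift. The two tail intervals are
  interpolated straight to z_0/z_n (reachable-bounds convention), which
  offsets their conditional means by ∓m_trm/2; the offsets cancel, so the
  density mean is Σm_t/n exactly. Tests verify this against brute-force
  numeric inversion of the density.

Each replicate sorts n uniform draws' quantiles and rearranges them into the
original series' rank order (stable sort; ties keep original positions), so
every replicate has the original's shape and stays within [z_0, z_n]. A
constant series is a fixed point. Draws come from one seeded PCG64 stream
per gene, consumed as R blocks of n; the ensemble is generated as a single
(R, n) matrix — results are identical to sequential generation and
reproducible given the seed. In dataset runs each gene's stream is seeded by
(master seed, sha256(gene id)), so results do not depend on row order or on
which subset of genes is analysed.

## Inference

- **p-value**: p̂ = (1 + #{ρ*_j > ρ̂})/(1 + R), strict inequality, bounded
  in [1/(R+1), 1]. The statistic is the maximum template correlation.
- **CI**: percentile interval from the bootstrap peak times. When R·α is an
  integer the bounds are the (R·α)-th and (R·(1−α))-th order statistics;
  otherwise the ⌊(R+1)α⌋-th and (R+1−⌊(R+1)α⌋)-th. For R = 999, α = 0.025
  (where R·α = 24.975) this selects the 25th and 975th ordered values.
  CI endpoints are sample members, hence lie on the template peak grid.
- **Assignment**: containment of the closed CI in a closed bin. The
  zero-centred bin is additionally tested circularly (endpoints near T map
  by h → h − T, with ~1-ulp slack for the modulo); a CI endpoint exactly on
  a shared boundary is resolved toward the bin containing θ̂, then toward
  the lower bin index. Order statistics are taken on the linear scale, so a
  fine-grid gene peaking near 0 whose bootstrap peaks wrap past midnight
  can produce an uninformatively wide linear CI — a documented limitation;
  at the default grid (θ* ∈ {0,…,20}) the case cannot occur.
- **Multiplicity**: per-gene p ≤ α (default 0.05) with no correction, as the
  method is normally applied; Benjamini–Hochberg is available behind a flag.

## Conservatism of the rhythmicity test

The replicates are *deliberately* close to the observed series — that is
what makes resampling a 12-point dependent series possible at all. The cost
is that ρ* is positively coupled to ρ̂, compressing the p-value distribution
toward its centre: on pure Gaussian noise the fraction of genes flagged at
α = 0.05 is about 0.01, not 0.05, and at moderate noise
(sd = 0.3 × amplitude) only a minority of genuinely rhythmic on-grid genes
pass the gate (~13% confidently assigned, versus ~1% for genes peaking
between sampling times, and 100% in the noise-free limit). The test is
therefore a high-specificity filter for genes whose peak can be pinned to a
sampling time, not a general rhythmicity detector; users wanting discovery
power should screen with a dedicated rhythmicity test first and use this
package to qualify the phases of the hits.

## Synthetic data

The generator emulates the reference design: 12 timepoints at 4-h spacing,
rhythmic genes = baseline + amplitude·cos(2πt/T − φ) + noise, non-rhythmic
genes = baseline + noise. Defaults: baseline 5 (arbitrary expression units),
amplitude 1, Gaussian noise sd 0.3 — a clearly rhythmic but non-trivial
signal-to-noise ratio typical of normalised microarray profiles; a
log-normal (multiplicative) noise option adds realism for raw-scale
intensities. Ground truth (phase, peak hour, rhythmic flag) is returned
alongside. The generator does not model platform artifacts, damped or
ultradian oscillation, or inter-gene correlation, so a green synthetic test
establishes correct recovery behaviour under the model's own assumptions,
not performance on any particular platform.

## Numerical conventions

- Correlations are clipped to [−1, 1] after the normalised inner product.
- Zero-variance (constant) series raise a degenerate-series error per gene;
  dataset runs record the failure and continue.
- R·α integrality is decided with 1e−9 tolerance to absorb binary
  representation of decimals like 0.025.
- All randomness flows from numpy PCG64 generators; the generator name is
  recorded in the run metadata.
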