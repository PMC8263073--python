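# Methods

This note documents the models, defaults, and numerical choices behind
`gaersnet`, and what the synthetic study data does and does not emulate.

## Preprocessing

**Stable-epoch selection.** A run qualifies at window start *s* if, within
the window of `epoch_length` volumes, the peak-to-peak excursion of every
translation axis stays strictly below 0.2 mm and of every rotation axis
strictly below 0.3°. Peak-to-peak was chosen as the strictest simple
window statistic consistent with per-axis thresholds; the earliest
qualifying window is returned, so a fully stable run yields its first
`epoch_length` volumes. A run with no qualifying window returns an
explicit no-epoch result rather than raising, so batch callers can drop it.

**Low-pass filter.** The 0.1 Hz filter is a literal discrete Fourier mask:
rFFT bins strictly above the cutoff are zeroed and the series inverted.
This makes the operator exactly linear and idempotent and preserves the
mean, at the cost of possible ringing at sharp transients (Gibbs); for
slow hemodynamic signals this is immaterial, and the choice is the most
direct reading of a "Fourier filter".

**Order of operations.** Epoch selection → smoothing → low-pass → ROI
extraction → global-signal regression. Global-signal regression is applied
to the ROI series rather than voxel-wise; since ROI extraction is a label
mean and regression is linear in the data, the two orders agree, and the
ROI-level form is directly testable against the normal equations.
Registration is out of scope: the pipeline requires a subject-space label
map.

**Smoothing** uses a 3×3-pixel truncated Gaussian at FWHM 0.6 mm,
normalized to unit sum (unit DC gain), applied per slice with zero
padding, so the image sum is preserved up to boundary truncation.

## Connectivity

Negative Pearson coefficients are zeroed at matrix construction, before
any averaging — the strictest reading of a positive-only analysis.
Fisher averaging operates edge-wise (z = atanh r, arithmetic mean, tanh
back); zero edges participate as z = 0, and off-diagonal r = 1 is clipped
to 1 − 1e−7 with a warning. When several runs per animal exist, average
per animal first, then across animals; both steps use the same
`fisher_average`.

Edge significance converts r to t = r·√((n−2)/(1−r²)) with n − 2 degrees
of freedom, two-sided, with BH-FDR across all unique edges of the matrix
(2556 for 72 regions). The nominal post-filtering T is used for n; no
autocorrelation correction is applied, and this is deliberate — the
pipeline mirrors common practice for this analysis family, and the
synthetic AR(1) coefficient (0.3) is mild. The BH step-up itself is a
small vectorized in-package routine (the NBS permutation loop calls it
thousands of times); it is verified in the tests against statsmodels and
against hand enumeration.

## Graph construction and metrics

Thresholding keeps exactly ⌊R·k/2⌋ strongest positive edges; ties at the
cutoff break deterministically by lexicographic node order. Edge sets nest
across densities.

C and L are binary: C is the mean local clustering coefficient, L the mean
shortest hop count over ordered pairs. Strength is the only weighted
metric — defining strength separately as a weight sum implies the rest are
binary. For disconnected graphs L falls back to the largest component with
an explicit flag; the analysis density (k = 10) is chosen precisely so
networks are fully connected, making this a guarded fallback.

The null model is Erdős–Rényi G(n, m) with identical node and edge counts
— the literal "same number of nodes and edges" — with disconnected draws
resampled (and counted) so that λ retains a uniform definition;
degree-preserving rewiring was considered and rejected as the default
because the normalization target is explicitly the matched-size random
graph. γ = C/C_rand, λ = L/L_rand, σ = γ/λ, with C_rand, L_rand the null
means (default 1000 nulls).

The hub score is the equal-weight mean of within-network z-scores of
degree, betweenness centrality, and negative average path length. The
combining rule is recorded in the result's metadata (`attrs["formula"]`)
so alternative composites remain comparable. Metrics whose within-network
variance is zero (up to floating-point jitter on symmetric graphs)
contribute 0.

## Communities

Louvain-style two-phase modularity optimization on the *weighted*
thresholded graph (community structure is conventionally drawn with
weighted edges), resolution default 1.0, node-sweep order randomized per
restart from a master seed, best of 10 restarts by Q. Modularity is the
standard Newman–Girvan form with the resolution scaling the null term;
community ids are renumbered densely by first appearance in node order so
partitions are deterministic and comparable.

## Network-based statistics

Edge tests are pooled-variance two-sample t-tests on subjects' z-values;
zero-variance edges get t = 0 and are flagged. The primary threshold is
the BH-FDR-adjusted edge p < α — a deliberately conservative variant of
NBS (classic NBS thresholds raw |t|; that mode is available via
`primary="t"`). Components are extracted separately per contrast
direction; their size statistic is the edge count, with node counts
reported alongside.

The permutation null relabels subjects without pairing (unpaired design),
re-applies the identical thresholding rule per permutation (recomputing
the FDR step, preserving exchangeability; a fixed-edge-set variant was
considered and rejected as non-exchangeable), and takes the maximal
component size across both directions. p = (1 + #{null ≥ observed}) /
(n_perm + 1), so probabilities are bounded below by 1/(n_perm + 1). A
consequence of the FDR-based primary threshold is that under the null most
permutations have no supra-threshold edges at all, so any observed
component tends to be either absent or clearly significant; singleton
components should be read as FDR-stage edge discoveries rather than
topological clusters.

## Group statistics

The Mann–Whitney comparison takes as samples the nonzero unique edges of
each group-average z-matrix (the "total number of connections" framing);
pooling per-subject edges instead is possible by calling the test on
per-subject matrices. The two-factor ANOVA (group × region with
interaction) uses OLS with Type-II sums of squares, appropriate for the
unbalanced group sizes of animal studies (e.g. 9/8/7); with one region it
collapses to the two-sample t-test (F = t²). Post-hoc per-region t-tests
report uncorrected p (the study convention for exploratory node maps) and
always emit a BH-adjusted column alongside.

## Synthetic study data

The generator defines the study conditions under which the pipeline is
validated:

- **Atlas**: 72 regions, 36 per hemisphere, mirrored `_L`/`_R` pairs, in
  five functional groups (per hemisphere: 8 sensorimotor, 6 association
  cortex, 9 limbic, 8 thalamus, 5 basal ganglia).
- **Time series**: T = 900 volumes at TR = 1 s (a 15-minute run), zero-mean
  Gaussian with population correlation equal to the repaired target via
  the Cholesky factor, plus AR(1) temporal smoothing (coefficient 0.3) to
  mimic hemodynamic autocorrelation — AR filtering applied identically to
  all regions leaves cross-regional correlations unchanged.
- **Correlation targets**: homotopic pairs 0.60; within-group 0.40
  (thalamus 0.50); structured between-group coupling — thalamus to
  sensorimotor/association/limbic 0.30 (the diffuse thalamo-cortical and
  thalamo-limbic projections), sensorimotor–association 0.30,
  basal-ganglia–limbic 0.28 — over a 0.15 baseline; per-edge
  heterogeneity of SD 0.08 (seeded separately and shared across groups, so
  it acts as fixed "anatomy"). The heterogeneity term gives the continuous
  edge-weight distribution real connectomes show; without it the top-360
  graph would decompose into the five blocks, whereas the emulated data
  are fully connected at k = 10. These magnitudes are calibration choices
  of this package, not empirical values.
- **PSD repair**: block targets plus jitter and deltas need not be a valid
  correlation matrix; eigenvalues are clipped at 1e−8 and the matrix
  renormalized to unit diagonal. The repair is deterministic and its
  maximal absolute adjustment is reported, bounding |target − achieved|.
- **Group effects**: additive deltas on all edges between two named
  functional groups (e.g. +0.25 on thalamus–thalamus), applied before
  repair, giving known ground truth for NBS power checks.
- **Ca²⁺ traces**: a slow 1/f-shaped background rolled off above 2 Hz
  (preseizure fluorescence is dominated by slow fluctuations) plus 10%
  broadband measurement noise, and spike-and-wave bursts — an asymmetric
  sawtooth at 6 Hz with a small second-harmonic spike component, amplitude
  3× the background SD — alternating with rest epochs (mean burst length
  5 s, ±20% jitter) at the requested duty. Ground-truth intervals are
  returned. Sampling (default 100 Hz) must be ≥ 10× the SWD frequency.

What the generator does **not** emulate: hemodynamic forward dynamics,
scanner artifacts beyond AR(1) noise, anesthesia effects, spatial
smoothness of maps, or spike–wave waveform morphology beyond the 6 Hz
fundamental. Passing tests therefore demonstrate correctness of the
analysis operators and their statistical calibration under a controlled
process, not robustness to every property of real animal data.

## SWD detection

The band-ratio classifier computes, per 2-s sliding window (50% overlap,
Hann taper), the fraction of non-DC power in 4–8 Hz. Windows above the
ratio threshold mark their central 1-s hop as SWD; marks merge into
segments and segments shorter than 1 s are dropped. The default threshold
0.5 was fixed by one calibration pass on the simulator: preseizure window
ratios stay below ~0.26 (so false-positive segments are essentially
absent, well under the 5% design budget), while a window more than half
covered by a burst exceeds 0.5, keeping detected segment edges close to
the true burst boundaries. Marking the central hop, rather than the whole
window, removes most of the edge bias a 2-s window would otherwise add to
each burst; the residual over-count (~0.1 at 50% duty) reflects the
detector's temporal resolution. The trace-level label is "seizure" iff at
least one SWD segment remains.

## Problem sizes and determinism

Everything is seeded: generators and permutation/null loops take explicit
integer seeds, and identical seeds reproduce outputs bit for bit. Tests
and the acceptance script run the full 72-region pipeline with moderate
replicate counts (e.g. 9–20 subjects, 200–1000 permutations or nulls,
T = 200–900), sizes at which each check's sampling error is comfortably
inside its tolerance while the whole suite stays desk-scale on one CPU.
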