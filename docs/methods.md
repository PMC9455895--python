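# Methods

## Scope and data model

`infoflow` analyses frame-synchronous, multi-ROI fluorescence time series.
An ROI is a static, axis-aligned pixel rectangle (0-based indices,
half-open extents, default 100×100 px); its trace is the arithmetic mean
of pixel intensities inside the rectangle at each frame. Mean is used
rather than median or sum because it is the standard statistic for
fluorescence traces; the three differ only by monotone transformations
irrelevant after thresholding in all but heavy-tailed cases. Channels
(e.g. a calcium reporter and an actin reporter) are one stack per channel
and must agree in frame count; cross-channel alignment is assumed from
acquisition. ROI tracking is out of scope: ROIs that cells move out of
should be discarded upstream.

## Binarization

Each trace is thresholded independently: state 1 where the value strictly
exceeds the threshold, else 0. Methods:

- `mean` (default): the trace's arithmetic mean, the conventional cutoff
  between signal and noise for slowly varying fluorescence;
- `median`: robust alternative for skewed traces;
- `fixed`: a user-supplied level;
- `otsu`: the inter-class-variance-maximizing split, computed exactly on
  the empirical value distribution (one histogram bin per distinct value)
  rather than a fixed-width histogram — fixed-width binning misplaces
  boundary values on 60-frame traces.

Ties map to 0, which makes the constant trace deterministic (all zeros);
constant traces are flagged `degenerate` rather than raising, because a
dead ROI is data, not an error. Per-trace thresholds (not per-channel)
keep ROIs with different baselines comparable; this is configurable only
by pre-scaling the traces.

Binarization to a single on/off state per frame is a deliberate
coarse-graining: it discards amplitude information in exchange for
well-sampled discrete distributions at T ≈ 60. Continuous (kernel/KSG)
estimators are explicitly out of scope.

## Estimators

All series metrics are maximum-likelihood plug-in estimates on empirical
counts, base-2 logarithms, with 0·log 0 ≡ 0 and empty conditional cells
contributing 0. Pooling runs over every frame with a complete history
window; there is no circular wrapping, which would fabricate transitions.
Negative values arising from floating-point cancellation are clamped at 0.

Embedding defaults are history k = 1, source embedding l = 1, delay u = 1.
With T ≈ 60 frames the joint alphabet for transfer entropy has
2^(k+l+1) cells; k = l = 1 (8 cells) is the longest embedding that is not
severely undersampled, so larger embeddings are accepted but emit an
`UndersampledEmbeddingWarning` when the cell count exceeds T/3. No bias
correction is applied — the surrogate null absorbs the plug-in bias, and
an analytic correction would double-count it.

Effective information operates on an explicit row-stochastic transition
model, not on traces: the intervention distribution is uniform over
states (maximum-entropy noise injection) by default, with an optional
user-supplied distribution. Building transition models from data is out
of scope.

Every estimator is verified, for all binary series up to length 12 and
embeddings up to 2, against an independent brute-force implementation
that materializes full joint count tables by explicit enumeration
(agreement to 1e-12); effective information is additionally checked
against a Monte-Carlo interventional sampler.

## Surrogate significance

The null model is whole-series frame permutation: surrogates preserve
each trace's marginal exactly (surrogate entropy equals observed entropy
replicate-for-replicate) while destroying all temporal and joint
structure. Per-cell p-values are one-sided empirical with the
Davison–Hinkley +1 correction, p = (1 + #{surrogate ≥ observed})/(1 + n),
so p ∈ [1/(n+1), 1] and never 0; one-sided because all metrics are
non-negative and only excess over chance is flagged. The default ensemble
size is 1000 and the default flagging level α = 0.05. Block and
phase-randomized surrogates are out of scope, so the null tests *any*
temporal structure, not structure beyond autocorrelation.

Two caveats are deliberate properties of the design rather than bugs:

- No multiple-testing correction is applied across table cells. A 9-ROI
  TE table has 72 cells; at α = 0.05 about 3–4 false flags per null table
  are expected. Cells are exploratory; confirmatory claims should use the
  group-level Mann–Whitney comparison (`rank_sum_compare`, exact
  enumeration for both groups ≤ 8 without ties, tie-corrected normal
  approximation otherwise).
- The permutation test is slightly conservative: the discrete metric
  distribution produces ties, so the realized rejection rate at α = 0.05
  sits near 3–4% for 60-frame traces (verified by the calibration test).

All randomness flows through seeded NumPy generators; per-cell seeds are
derived from the run seed with `SeedSequence`, so any table or pipeline
run is reproducible bit-for-bit from its manifest.

## Synthetic regimes

The generator emulates the nominal acquisition — 9 ROIs, 60 frames at one
frame per minute — and produces each qualitative regime the estimator
suite must tell apart:

- `iid`: independent Bernoulli activity; the null fixture.
- `oscillator`: square waves (default period 2) with independent random
  phases and optional flip noise. Two noiseless in-phase oscillators give
  1 bit of lag-1 delayed MI with zero transfer entropy — the
  delayed-correlation false positive that motivates TE.
- `coupled_chain`: ROI j+1 copies ROI j one frame later with fidelity
  `coupling_eps` (flip probability (1−eps)/2). Genuine directed flow;
  used for directionality-recovery checks at eps = 0.8.
- `common_driver`: two ROIs copy a hidden maximum-entropy driver at equal
  lag. The driver is a uniformly random arrangement of exactly T/2 active
  frames (rather than i.i.d. coin flips) so that the noiseless pair shows
  exactly 1 bit of MI; with i.i.d. flips the value would fluctuate with
  the realized marginal. TE is structurally zero either way.
- `bleaching`: intensity traces, independent Gaussian noise on a shared
  exponential decay (default rate 0.05/frame, i.e. ~95% signal loss over
  the hour). After mean-thresholding, every ROI becomes nearly the same
  step function, producing strong spurious MI — the photobleaching
  artifact users must screen for. At drift 0 the regime reduces to
  independent noise.
- `two_channel_model`: an invented validation mechanism, *consistent
  with* but not derived from the gate/conduit interpretation of coupled
  actin–calcium dynamics. Channel A is a persistent per-ROI Markov chain
  (stay probability 0.95, activation 0.15, stationary activity 0.75) —
  slow pulsing with high active information storage and no inter-ROI
  coupling. Channel B copies its ring neighbour's previous state with
  probability 0.9 *when the ROI's A state is active*, tracks its own
  ROI's A state with probability 0.45, and is otherwise a fresh coin
  flip. The designed signatures — AIS(A) > AIS(B), inter-ROI transfer
  significant in B but not A, within-ROI transfer A→B but not B→A — are
  what the estimator suite must recover; the generator records its
  ground-truth couplings in the output. The mechanism parameters were
  chosen once so that each signature is detectable at the 60-frame,
  9-ROI scale from a channel-level statistic (mean over ROIs or ROI
  pairs), mirroring how group-level claims are made from per-cell values.

What the generators do **not** emulate: spatial structure beyond ROI
identity, reaction–diffusion or mechanical coupling, photon shot noise,
baseline drift other than exponential decay, asymmetric or burst-like
noise (all noise is i.i.d. symmetric bit-flipping), and cell motion.
Passing the recovery suite therefore shows the estimators and the
significance machinery behave correctly on data with known structure; it
does not validate biological conclusions drawn from any particular real
dataset.

## Problem sizes and numerical choices

Recovery and calibration checks run at deliberately chosen scales:
qualitative regime examples at the nominal 60-frame length;
directionality recovery at T = 600 over 200 seeds (60-frame plug-in TE is
too noisy for a sharp per-pair ordering, and the lengthened series
isolates estimator behaviour from acquisition noise); null calibration
at T = 60 with 200 surrogates and 500 repetitions; channel-level
significance in the two-channel model with 100-surrogate ensembles over
200 seeds. Exact-value tests use odd or balanced-length constructions
where a textbook value (1 bit) requires exactly balanced empirical
marginals.

Degenerate inputs: constant traces yield zero for every self-metric and
p = 1 under any surrogate test (all permutations are identical);
zero-probability transition-matrix cells contribute zero to EI; ROI
rectangles are validated against image bounds before any extraction.

## Known limitations

- Plug-in estimates at T = 60 are biased upward by several hundredths of
  a bit; only surrogate-calibrated comparisons are meaningful at that
  scale, never raw values.
- k = l = 1 embeddings detect only first-order history effects; slow
  dynamics spanning several frames (e.g. long refractory periods) leak
  into the "beyond history" term of TE.
- Frame-permutation nulls destroy autocorrelation, so a significant cell
  means "temporally structured", which includes shared artifacts such as
  bleaching; the `bleaching` regime exists precisely to demonstrate this
  failure mode.
- The Mann–Whitney group comparison treats cells as exchangeable and
  independent, which ROI pairs within one specimen are not; it matches
  standard practice but its p-values are approximate under within-specimen
  correlation.
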