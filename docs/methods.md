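# Methods

## Model and estimation procedure

`elstim` models the probability that a single neuron fires a short-latency
(direct) spike to one biphasic multi-electrode current pulse as a
linear–nonlinear cascade. The stimulus is a vector **s** of signed per-electrode
amplitudes in μA (positive = anodic-first). Estimation proceeds in stages:

1. **Subspace identification.** The spike-triggered stimuli S_D (rows of the
   full ensemble S_T that elicited a short-latency response) are summarized by
   their covariance C_s = cov(S_D), taken about the spike-triggered mean with
   the unbiased (n−1) denominator and restricted to operational electrodes.
   Because the raw ensemble is white with per-electrode variance ≈ σ²,
   eigenvalues of C_s above (below) σ² mark stimulus directions along which
   spiking increased (decreased) the ensemble variance — excitatory
   (suppressive) components.

2. **Significance testing.** The null distribution of extreme eigenvalues is
   built by circularly shifting the binary response vector relative to the
   stimulus sequence by a uniform offset in [1, n−1] (preserving both the
   spike count and all stimulus statistics) and recomputing the largest and
   smallest eigenvalue per shuffle. If the observed largest (smallest)
   eigenvalue exceeds the shuffled-maxima mean + 2 SD (falls below the
   shuffled-minima mean − 2 SD), the axis is recorded and the data are
   deflated onto its orthogonal complement (dropping the dimension), the null
   regenerated, and the test repeated. When both extremes are outside their
   bounds in one iteration, the one with the larger z-score is taken first.
   The strength ratio G = |e₁ − ē_rnd| / |e₂ − ē_rnd| uses the mean of the
   full shuffled eigenvalue distribution from the first iteration; e₁ and e₂
   are the observed eigenvalues with the largest and second-largest deviation
   from that mean.

3. **Polarity-split ERFs.** S_D is split by the sign of its projection onto
   the first significant component v₁ (zero projections — measure-zero for
   continuous stimuli — count on the positive side); w⁺ and w⁻ are the means
   of the two halves. Electrode significance compares |w±| per electrode with
   the RMS over shuffles of ERFs recomputed from each shuffle's time-shifted
   response split by that shuffle's own first eigenvector. The ERF spatial
   extent D± is the |w|-weighted mean cell-to-electrode distance (absolute
   weights — signed weights can make a spread negative or unstable when they
   nearly cancel).

4. **Nonlinearity.** All stimuli on each polarity side are projected onto the
   unit-normalized ERF of that side and binned so every bin holds an equal
   number of spike-eliciting stimuli (15 bins per side); the per-bin
   probability is spikes/stimuli and the bin abscissa is the mean projection
   of all stimuli in the bin. One-sided sigmoids
   N+(x) = a⁺/(1+exp(−b⁺(x−c⁺))) and N−(x) = a⁻ − a⁻/(1+exp(−b⁻(x−c⁻))) are
   fit per side by unweighted nonlinear least squares (initialization:
   a = max bin probability, c = bin center nearest a/2, b = 4a/span; five
   restarts jittering b log-normally; bounds a ∈ (0,1], b > 0). r² pools all
   bins of both sides. A joint both-sides refinement was evaluated and changed
   the recovered thresholds by under 0.1%, so the simpler per-side fit is the
   only shipped path.

5. **Prediction and validation.** P(spike|s) = N+(ŵ⁺·s) + N−(ŵ⁻·s) + p₀,
   clipped to [0,1]; p₀ (spontaneous-rate term) defaults to 0. A `piecewise`
   mode evaluating only the matching side's term is available; with the axis
   orientation below, the two modes differ only by the off-side floor
   (≤ ~0.01 at the defaults). Validation splits *distinct stimuli* 80/20 (all
   repeats of a stimulus stay together, preventing leakage of statistically
   dependent presentations), bins test presentations into B = 10 equal-width
   segments of predicted probability, and reports
   E_RMS = sqrt(mean over retained bins of (P̂ᵢ − Pᵢ)²), omitting empty bins
   and (for the 2-D model) presentations in unsupported surface regions.

### Sign and orientation conventions

Eigenvector signs are fixed so the largest-magnitude component is positive.
The negative-side projection axis is the unit vector along w⁻ *oriented to
have positive dot product with v₁*. With this convention net anodic-first
stimuli always project positively and net cathodic-first stimuli negatively
on both axes, the fitted thresholds come out c⁺ > 0 > c⁻ as conventionally
reported, and the summed two-term predictor is well behaved arbitrarily far
from threshold (each term decays to its floor on the other side's half-space;
no asymptote leakage).

## Tunable parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| pulse phase / gap / rate / limit | 500 / 50 μs, 10 Hz, ±300 μA | — | standard biphasic charge-balanced pulse train; the limit truncates the Gaussian amplitude distribution (rejection resampling, not clipping, so the ensemble stays truncated-normal) |
| σ calibration grid | 50–250 μA, step 50 | μA | five short trains; σ chosen where a fitted saturating sigmoid reaches half its saturation |
| repeats per distinct stimulus | 3 | — | each presentation is one Bernoulli trial; repeats stay together across the train/test split |
| n_shuffles / n_sd | 1000 / 2 | — | mean ± 2 SD on the extreme-eigenvalue null; per-extreme false-positive ≈ 2.5% nominal |
| bins per polarity side | 15 | — | 30 bins total; equal spike counts make the probability SE roughly uniform across bins |
| B (validation bins) | 10 | — | equal-width probability segments of [0,1] |
| 2-D grid / min_count | 15×15 / 20 | — | histogram surface with cubic-spline interpolation; cells under min_count are unsupported and fall back (flagged) to the 1-D model |
| k (latency clusters) | silhouette heuristic | — | k=2 if its silhouette ≥ 0.6 else 1 — above the ~0.55 that k-means scores when bisecting a single 1-D Gaussian — overridable since cluster counts are a judgement call |
| latency windows | cluster mean ± 2 SD | ms | the calibration response window (5 ms) is a separate, explicit parameter |

## The synthetic ground truth

`synthetic_rgc` builds a 20-electrode staggered array (400 μm discs, 1 mm
vertical pitch, ~3.5 × 3.5 mm) and cells whose true positive ERF loads the
1–3 operational electrodes nearest the soma with exponentially
distance-decaying, seed-jittered weights (decay scale 2.0 mm, so
neighbouring-electrode weights stay within one order of magnitude, as in
multi-electrode ERFs with several significant electrodes). The default
nonlinearity is a⁺ = 0.9, b⁺ = 0.03/μA, c⁺ = 150 μA, mirrored on the
cathodic side (w⁻ = −w⁺, c⁻ = −150 μA); an asymmetric-threshold mode
(c⁻ ≠ −c⁺) probes robustness to polarity-dependent thresholds, and an
optional suppressive axis multiplies the probability by a Gaussian bump
penalty along a second stimulus direction to create genuinely 2-D cells.
Short-latency responses are Bernoulli draws from the LN probability with
normal latencies (1.75 ± 0.3 ms, truncated at 0); long-latency (network)
responses are an independent Bernoulli (default 0.1) with their own latency
distribution (11 ± 2 ms) — phenomenological, sufficient to exercise latency
clustering and re-running the pipeline on long-latency labels.

What the simulator does *not* emulate: spike-history and refractory effects,
stimulation-frequency interactions, electrode impedance variation,
drift/nonstationarity over a recording session, and extracellular spike-sorting
errors. Passing recovery tests therefore demonstrates correctness of the
estimator under its own model class, not robustness to those real-data
effects.

## Problem sizes and observed behaviour

The standard study condition used throughout the tests and the acceptance
script is 2000 distinct stimuli × 3 repeats = 6000 presentations at the
calibrated σ (≈ 100 μA for the default cell, giving a spike rate ≈ 0.17),
with 200–1000 shuffles depending on the check. Under these conditions, over
25-seed populations: cosine(ŵ⁺, w⁺_true) ≈ 0.98 (≥ 0.95 in ≥ 90% of runs),
|ĉ⁺ − c⁺|/c⁺ median ≈ 0.04, the significant-electrode set is exactly
recovered in > 90% of runs, corr(ŵ⁺, ŵ⁻) ≈ −0.97 for symmetric cells, and
the median strength ratio G ≈ 5.

Two behaviours worth knowing:

* **Held-out E_RMS has a heavy tail.** The binned calibration error weights
  all B = 10 bins equally, and at 6000 presentations with a ~0.17 spike rate
  the upper probability bins can hold only a handful of presentations (often
  a single distinct stimulus and its repeats). A perfectly calibrated model
  then still draws E_RMS > 0.1 in a few percent of runs purely from bin
  noise. The 95th percentile over 25 runs is typically ≈ 0.10–0.13.
* **Truncation-induced suppressive components.** With σ ≈ limit/3 or larger,
  conditioning on a spike concentrates the loaded electrodes near their
  truncation limits, slightly *reducing* spike-triggered variance in
  directions overlapping them; the significance test then occasionally
  reports a genuine (but small) suppressive component even for a 1-D cell.
  Sensitivity statements are therefore about "exactly one *excitatory*
  component".

The efficiency analysis equates power with the squared Euclidean norm of the
stimulus vector (identical electrode geometries). For simulator cells, whose
ERFs load the nearest electrodes fairly evenly, the best naive strategy is
nearly parallel to w⁺ and the threshold ratio is only slightly below 1
(≈ 0.99); real cells with more uneven ERFs benefit more. The ratio ≤ 1 bound
itself is exact (Cauchy–Schwarz), with equality iff the best naive direction
is parallel to w⁺.

## Numerical choices and degenerate inputs

* Truncated-Gaussian sampling uses rejection resampling; σ = 0 yields exactly
  zero amplitudes.
* Plateaus in spike detection resolve to the first maximal sample
  (deterministic); artefact blanking substitutes the last pre-window sample,
  since the onset sample itself may already be contaminated.
* Latencies are measured from stimulus *offset*; offset = onset + 2·phase +
  gap when only onsets are available. Spikes before the first offset are
  dropped and counted.
* k-means uses 10 restarts with a fixed seed; clusters are relabelled by
  ascending mean. Overlapping 2-SD short/long windows can label a
  presentation both ways — surfaced, not resolved.
* Equal-spike bin edges are quantiles of the spike-eliciting projections;
  outer edges are widened to ±∞ within each side so every stimulus lands in a
  bin. All-identical projections collapse to one bin whose probability is the
  overall spike rate.
* The 2-D surface interpolates bin-center probabilities with a cubic spline
  (s = 0, degree capped by grid size); unsupported cells are filled with the
  overall rate purely to condition the spline and are flagged at prediction
  time.
* G is ∞ when the second-largest deviation from the null mean is exactly 0.
* An all-zero or all-one response vector, all-masked arrays, sub-minimum spike
  counts, non-convergent fits, and undefined extents raise typed errors
  (`elstim.errors`).

## Known limitations

* The estimator assumes per-pulse independence (no spike history); at 10 Hz
  pulse rates this is a standard assumption but it is untested here at higher
  rates.
* The shuffle null assumes exchangeability of the response sequence up to
  rotation; strong slow drift in excitability would violate it.
* The 2-D nonlinearity is a histogram + spline, not a parametric surface; at
  a few thousand training presentations its variance can exceed the bias it
  removes, so a 2-D model is only worth it when the second component is
  strong and correlated with the first.
* Morphological classification consumes terminal-depth measurements; image
  segmentation and 3-D reconstruction are out of scope.
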