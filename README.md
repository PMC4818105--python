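# elstim

Linear–nonlinear modelling of single-neuron responses to concurrent
multi-electrode electrical stimulation, with a ground-truth simulator for
validating every estimation stage by parameter recovery.

## The problem

Neural prostheses (retinal, cochlear, cortical) usually stimulate one
electrode at a time because the combinatorial space of multi-electrode
stimuli is too large to characterize by trial and error. If a neuron's
response to *arbitrary* current patterns can be predicted from a short
white-noise characterization, stimulation strategies such as current steering
become tractable. `elstim` implements that characterization for
retinal-ganglion-cell-style recordings: biphasic current pulses are delivered
simultaneously on all electrodes with i.i.d. Gaussian amplitudes (truncated
at the stimulator compliance limit), and the per-pulse spike/no-spike
responses are used to identify the low-dimensional stimulus subspace that
drives the cell.

## The model

For a stimulus vector **s** (one signed amplitude per electrode, μA;
positive = anodic-first), the spike probability is

```
P(spike | s) = N+(ŵ⁺ · s) + N−(ŵ⁻ · s) + p₀
```

where **w⁺**, **w⁻** are the *electrical receptive fields* (ERFs) for net
anodic-first and net cathodic-first stimuli — the means of the spike-triggered
stimuli with positive and negative projection onto the first significant
principal component **v₁** of the spike-triggered covariance
C_s = cov(S_D) — and the one-sided sigmoids are

```
N+(x) = a⁺ / (1 + exp(−b⁺ (x − c⁺)))
N−(x) = a⁻ − a⁻ / (1 + exp(−b⁻ (x − c⁻)))
```

with half-saturation thresholds c⁺ > 0 > c⁻ in μA. Subspace dimensionality is
decided by an iterative significance test against a null built by circularly
time-shifting the response vector (1000 shuffles, mean ± 2 SD bounds on the
extreme eigenvalues, deflation between iterations); the strength ratio
G = |e₁ − ē_rnd| / |e₂ − ē_rnd| summarizes how dominant the first component
is. Model quality is scored on a held-out 20% of distinct stimuli by the
binned calibration error E_RMS = sqrt(mean over B=10 probability bins of
(P̂ᵢ − Pᵢ)²). At fixed stimulus-vector norm (fixed power), the
half-saturation threshold along a unit direction **u** is
t = c⁺ / (ŵ⁺ · u), so ERF-proportional stimulation is provably at least as
efficient as equal-amplitude stimulation on the electrodes nearest the cell.

The package also covers the surrounding protocol: noise-amplitude calibration
(σ at half the fitted saturating response), spike detection with artefact
blanking, latency k-means for separating direct (short-latency) from
network-mediated (long-latency) responses, a 2-D nonlinearity over two
significant components, and dendritic-stratification ON/OFF classification.

## Worked example

```python
import numpy as np
import elstim as el

array = el.default_array()                       # 20 electrodes, 3.5 x 3.5 mm
cell  = el.make_cell(array, position=[1.75, 1.75], n_significant=3, seed=0)
ens   = el.sample_white_noise(2000, 20, sigma=101.0, repeats=3, seed=1)
rec   = el.simulate_responses(cell, ens, seed=2)

sens = el.SpikeTriggeredEnsemble(ens.amplitudes, rec.responses.short,
                                 mask=ens.mask, stimulus_ids=ens.stimulus_ids)
sig  = el.significance_test(sens, n_shuffles=500, seed=3)
erf  = el.electrode_significance(sens, sig, el.estimate_erfs(sens, sig.significant[0][0]))
train, test = el.split_data(sens, fraction=0.8, seed=4)
_, model    = el.fit_ln_model(train, sig.significant[0][0])
report      = el.validation_error(model, test, B=10)
```

Running `python examples/02_estimate_electrical_receptive_field.py` and
`python examples/03_fit_and_validate_ln_model.py` prints:

```
significant components: 1 ['excitatory'], strength ratio G = 4.79
significant electrodes (w+): [5, 9, 10]
true ERF electrodes:         [5, 9, 10]
cosine(estimated w+, true w+) = 0.9882
corr(w+, w-) = -0.973

anodic side:   a+=0.875  b+=0.0266/uA  c+=151.3 uA
cathodic side: a-=0.941  b-=0.0273/uA  c-=-157.9 uA
(ground truth: a=0.9, b=0.03/uA, c=+/-150 uA);  fit r2 = 0.971
held-out E_MS = 0.00370, E_RMS = 0.0608
```

One excitatory component with G ≈ 4.8 means the cell is effectively
one-dimensional in stimulus space; the three electrodes carrying its true ERF
are exactly the ones flagged significant; corr(w⁺, w⁻) ≈ −0.97 means the same
electrodes drive the cell with either pulse polarity; and the fitted
thresholds recover the ground truth within a few μA, giving a held-out
calibration error of ~6%.

The other examples cover σ calibration, current-steering efficiency,
latency clustering, and morphological classification. A thin CLI mirrors the
library (`elstim simulate | label | fit-subspace | run | validate | optimize`).

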