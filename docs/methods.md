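# Methods

This note documents the models, the calibrated sampling priors, the
estimators, the network, and the numerical choices made in `t2relax`, together
with known limitations.

## 1. Signal model

A spin-echo T2 relaxation experiment acquires the transverse magnetization at
echo times TE₁ < … < TEₙ. The noise-free magnitude follows a
mono-exponential decay

    S(TE) = S0 · exp(−TE / T2),

with proton-density-weighted amplitude `S0` (arbitrary units) and relaxation
time `T2` (milliseconds). An optional constant offset `c` extends the model to
`S0 · exp(−TE/T2) + c` for the offset estimator below.

### Rician magnitude noise

Magnitude MR images are computed as the modulus of a complex signal whose real
and imaginary channels carry independent Gaussian noise of standard deviation
σ. The resulting magnitude is Rice-distributed. `add_rician_noise` implements
exactly this construction: it adds one Gaussian draw to the (real) signal,
pairs it with a second pure-noise draw, and takes the modulus. σ = 0 is an
exact identity.

The expected magnitude given a true signal s is

    E[M] = σ √(π/2) · e^(−α) [ (1 + 2α) I₀(α) + 2α I₁(α) ],   α = s² / (4σ²),

with modified Bessel functions I₀, I₁. This expectation is the backbone of the
noise-corrected estimator: instead of fitting the decaying exponential to the
biased magnitudes, one fits the expectation of the Rician magnitude of the
exponential.

Numerics: the Bessel terms overflow for large α, so the implementation uses
the exponentially scaled functions `scipy.special.ive`, which fold `e^(−α)`
into the Bessel evaluation. `ive` itself loses validity near α ≈ 10⁹, so for
α ≥ 10⁶ the code switches to the asymptotic expansion
`E[M] ≈ s + σ²/(2s) − σ⁴/(8s³)`; at the switch point the two branches agree to
about 14 significant digits. The same expansion shows the well-known low-noise
behaviour: the magnitude bias approaches σ²/(2s) from above, which is why
uncorrected least squares overestimates T2 whenever the tail of the decay
drops toward the noise floor.

The defining expectation was cross-checked against direct numerical
quadrature of the Rice density (`scipy.stats.rice` + `scipy.integrate.quad`)
to 10⁻⁸ in the test suite, and against Monte-Carlo means of the noise
operation itself.

## 2. Sampling priors for synthetic decays

All training and evaluation data are synthetic. Parameters are drawn from
priors chosen to cover knee-cartilage-like tissue generously:

- **T2 ~ 5 ms + LogNormal(μ̂, σ̂²)** with mode 50 ms and P(T2 < 210 ms) = 0.95.
  Given the mode and quantile constraints, σ̂ solves the quadratic
  σ̂² + z₀.₉₅ σ̂ − ln(205/45) = 0 (z₀.₉₅ the standard normal 95 % quantile),
  giving σ̂ = 0.658361271596514 and μ̂ = ln 45 + σ̂² = 4.240102053708498. The
  implied tail mass P(T2 < 500 ms) ≈ 0.9986 keeps essentially all draws inside
  the fitting bounds.
- **S0 ~ ½ · U(0, 500) + ½ · (500 + Exp(scale β))** with β calibrated so that
  P(S0 ≤ 1700) = 0.95, i.e. β = 1200 / ln 10 ≈ 521.153. The implied
  P(S0 ≤ 2500) ≈ 0.989. Exact zeros are rejected (a zero-amplitude decay has
  no defined relative error).
- **σ ~ U(0, 300]** for heterogeneous training data; fixed-SNR evaluation sets
  instead set σ = S0 / SNR per sample (SNR = ∞ means σ = 0).
- **Echo trains:** first echo TE₁ ~ U(5, 15) ms, uniform spacing
  ΔTE ~ U(2, 15) ms, echo count n ~ U{5, …, 15}.

`PriorConfig` freezes the calibrated constants and exposes the analytic CDFs
used by the calibration tests.

## 3. Estimators

All three least-squares estimators use `scipy.optimize.least_squares`
(trust-region reflective), initial values (S0, T2) = (250, 50) (offset
c = 0 where present), and box bounds S0 ∈ [0, 2500], T2 ∈ [5, 500] ms,
c ∈ [0, 2500]. A solver failure returns the lower bounds with
`fallback=True`; this also covers underdetermined inputs (fewer echoes than
parameters).

- **LSE** — traditional fit of `S0 exp(−TE/T2)` to the magnitudes, analytic
  Jacobian. Biased upward at low SNR because the data sit above the true decay
  by the Rician floor.
- **OLSE** — offset fit of `S0 exp(−TE/T2) + c`. The constant absorbs the
  noise floor but over-corrects: the Rician bias is larger where the signal is
  small, which the constant cannot represent, so T2 is underestimated.
- **NCLSE** — fits the expected Rician magnitude of the mono-exponential
  model, given σ (scalar, per-sample, or per-voxel map). Jacobian by finite
  differences. With σ = 0 the expectation reduces to the identity, and the
  implementation delegates to the LSE path so both estimators agree exactly.
- **NN** — see below.

## 4. Neural network estimator

`T2Network` is a fully connected multilayer perceptron implemented directly in
NumPy (float32 forward/backward, Adam) — the evaluation environment provides
no deep-learning framework, and a six-layer MLP is small enough that hand-written
matrix code is both transparent and adequate on a CPU.

- **Input (30 values):** 15 magnitudes followed by 15 echo times; trains
  shorter than 15 echoes are padded with −1 in both halves, so the padding is
  distinguishable from real data (magnitudes and TEs are non-negative).
- **Architecture:** six weight layers — 30→512, four 512→512 hidden layers,
  and 512→2 output — totalling 1,067,522 parameters. Hidden activations are
  LeakyReLU (slope 0.01); the output activation is ReLU, so predicted
  (S0, T2) are non-negative by construction.
- **Output-head initialization:** with raw (unnormalized) magnitude inputs, a
  conventionally initialized output layer drives the T2 pre-activation far
  negative within a few optimizer steps, and the output ReLU then blocks all
  gradient flow permanently (a dead output unit). The package therefore scales
  the output-layer weights by 0.01 at initialization and sets the output
  biases to (250, 50) — the same typical-scale point used to initialize the
  least-squares fitters. This keeps early predictions in the plausible range
  and was the minimal intervention that made training on raw inputs reliable;
  it deliberately avoids input normalization so that a trained checkpoint
  consumes exactly the physical units produced by the simulator.
- **Training:** Huber (smooth-L1) loss with β = 1 on the (S0, T2) pair jointly,
  Adam with learning rate 10⁻³, batch size 512–1024, shuffled each epoch,
  seeded end to end. After every epoch the validation loss is evaluated and
  the parameters of the best epoch are kept (early-stopping by checkpoint
  selection). Samples with S0 = 0 are excluded from training.
- **Scale:** the package's standard training budget (used by the test suite)
  is 400,000 training samples for 8 epochs — about 3.2 million sample
  presentations — which fits in a few minutes on one CPU. Larger budgets
  reduce the low-SNR error further but with rapidly diminishing returns; the
  error levels quoted in the README were measured at this budget.

## 5. Evaluation protocol

Accuracy is summarized by the relative quantification error

    RQE  = (T2̂ − T2_ref) / T2_ref · 100 %        (signed)
    ARQE = |T2̂ − T2_ref| / T2_ref · 100 %        (absolute)

reported as medians with inter-quartile ranges and 2.5/97.5 percentiles
(`numpy.percentile`, linear interpolation). Medians are used throughout
because low-SNR error distributions are heavy-tailed and skewed.

Paired method comparisons use Mood's median test
(`scipy.stats.median_test` with `ties='below'`, no continuity correction);
with four methods there are three comparisons against a chosen reference, so
the working significance level is Bonferroni-corrected to α = 0.05/3.
Degenerate contingency tables (all values on one side of the grand median)
raise an error rather than returning a spurious p-value.

`build_error_table` drops samples whose reference T2 is non-finite and
records the count in the table metadata.

## 6. Image domain

`QuantMap` carries a multi-echo stack (rows × cols × echoes), echo times, a
boolean mask, and optional fitted maps. `fit_map` applies any of the four
estimators voxel-wise inside the mask; voxels outside the mask are NaN (the
no-data sentinel in all written maps). The NN path runs as a single batched
forward pass over the masked voxels. NCLSE accepts a global scalar σ or a
per-voxel σ map; estimating σ from the data themselves is out of scope.

`make_phantom` builds a synthetic cartilage-like test object: an annular band
(normalized radius 0.18–0.42) whose T2 increases linearly with radial depth
from 20 ms to 60 ms, with constant S0 = 500 and a 7-echo scheme
TE = 10, 20, …, 70 ms, optionally corrupted by Rician noise. It returns both
the noise-free truth and the observed stack, so image-domain pipelines can be
validated against exact ground truth.

I/O uses NIfTI-1 via nibabel with echo times in a JSON sidecar (NIfTI has no
TE field); round trips are bit-exact. `compare_to_reference` evaluates
RQE/ARQE maps voxel-wise against a reference map over the shared mask,
concatenating voxels across specimens; `timing_harness` reports mean wall-time
per method over repeated fits.

## 7. Limitations

- **Synthetic-only validation.** Everything here is validated against
  simulated data from the stated priors. Real acquisitions add effects the
  simulator does not model: stimulated echoes and B1 error in multi-echo
  trains, slice-profile effects, multi-compartment (non-mono-exponential)
  decay, motion, and spatially correlated or non-Rician noise from
  multi-channel reconstruction.
- **NN domain of validity.** The network is only trustworthy inside the prior
  ranges it was trained on (echo counts 5–15, the stated TE, S0, T2, σ
  ranges). Inputs outside that envelope degrade silently — there is no
  out-of-distribution flag.
- **σ must be supplied for NCLSE.** No noise estimator is included; a wrong σ
  biases NCLSE (claiming noise that is absent pushes T2 down, see the
  over-correction test).
- **Scaled-down budgets.** The package's standard training and evaluation
  sizes are chosen to run on a single CPU in minutes. They are large enough
  for stable medians at the reported precision, but rarer tail behaviour
  (e.g. 97.5-percentile errors at SNR 5) carries more Monte-Carlo noise.
- **2D maps.** The image pipeline treats each slice independently; there is no
  3D regularization or cross-slice modelling.
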