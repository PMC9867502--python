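# Methods

This note documents the models in `cpetml`, the assumptions behind them,
the defaults that matter, and what the synthetic data generator does and
does not emulate.

## Problem setting

An incremental cardiopulmonary exercise test (CPET) drives a subject
from rest to exhaustion while gas exchange is measured breath by breath:
oxygen uptake VO2 (ml/min), CO2 output VCO2 (ml/min), minute ventilation
VE (l/min), respiratory frequency Rf (breaths/min), end-tidal pressures
PetO2/PetCO2 (mmHg), heart rate, and workload.  Two ventilatory
thresholds partition the test into three exercise-intensity domains:

* **VT1** (gas-exchange / estimated lactate threshold): the first
  disproportionate rise of VCO2 against VO2 and of VE; VE/VO2 turns
  upward while VE/VCO2 stays flat and PetCO2 plateaus (isocapnic
  buffering begins).
* **VT2** (respiratory compensation point): the second disproportionate
  VE rise; VE/VCO2 turns upward and PetCO2 starts to fall.

Thresholds are conventionally reported as the VO2 (mlO2/min) at which
the transition occurs, not as a time.

## Shared preprocessing (`cpetio`)

All models consume the same representation: breath-domain records are
linearly interpolated onto a 1-s grid anchored at integer seconds (grid
from `ceil(t_first)` to `floor(t_last)`; the grid phase is a free choice
— integer anchoring keeps windows aligned across tests).  Ventilatory
equivalents are computed after unit harmonisation (VE is l/min, the gas
channels ml/min, hence VEVO2 = 1000·VE/VO2), and RER = VCO2/VO2.  The
six classifier channels (RER, VE, PetO2, PetCO2, VEVO2, VEVCO2) are
rescaled per test to [0, 1] with that test's own min/max, so the
classifier sees within-test shape, not absolute fitness.  A constant
channel would make the affine map undefined; it is mapped to 0.5 with a
logged warning rather than erroring, because near-constant PetCO2
plateaus can occur in short tests.  Rolling windows are 40 s x 6
channels at a 1-s stride.

## Synthetic tests with known thresholds (`simulate`)

The simulator is the training corpus and the reference truth for every
experiment in this repository, so its construction is deliberately
transparent — piecewise-linear segments whose breakpoints *are* the
configured thresholds:

* VO2 demand: constant baseline until `ramp_start_s`, then a linear ramp
  reaching `VO2_max` at `duration_s`.  Ground-truth threshold VO2 values
  are read off this ramp in closed form.  An optional first-order lag
  (`kinetics_tau_s`) can smooth the VO2 channel; it defaults to 0
  because the ground-truth convention reads threshold VO2 from the
  un-lagged ramp, and a non-zero default would build a systematic
  offset between the emitted channel and its own truth.  Real VO2
  kinetics (tau ~ 30 s) can be switched on when that bias is wanted.
* VCO2: piecewise-linear in ramp VO2 with slope 0.90 below VT1 and 1.15
  above (classical V-slope geometry), starting from RER 0.85 at rest.
* VE: affine in VCO2 (intercept 6 l/min, slope 24 l per l of VCO2) plus
  a linear hyperventilation term of 0.09 l/min per second above VT2.
  The positive intercept makes VE/VCO2 fall through the moderate domain
  and flatten in the heavy domain; the hyperventilation term turns it
  upward above VT2 — exactly the qualitative pattern contract.
* PetO2 / PetCO2: piecewise-linear in time with slopes
  (-0.018, +0.022, +0.050) and (+0.015, 0, -0.050) mmHg/s across the
  three domains, from 100 and 36 mmHg.
* Rf and HR ramp linearly across their configured ranges.

Defaults describe a moderately fit adult (VO2max 3000 ml/min, 12-min
test); corpus heterogeneity is emulated by `sample_config`, which draws
duration 600-840 s, VO2max 2200-3800 ml/min, VT1 at 35-50 % and VT2 at
65-85 % of the ramp.  Noise is additive Gaussian per channel with
SD = `noise_level` x 2 % of the channel's dynamic range, applied on the
1-s grid before breath-domain resampling; channels are floored at small
positive values so extreme draws cannot produce physically impossible
records.  Breath times accumulate successive intervals 60/Rf evaluated
at the current breath time, so the breath rate rises realistically
through the test.

What the simulator does **not** emulate: the cardio-dynamic (phase-I)
delay, the VO2 slow component, breath-by-breath measurement artefacts
and outliers, plateau or step protocols, and inter-expert label noise
(its labels are exact by construction).  Passing tests therefore show
that the pipeline recovers thresholds from idealized ramp physiology at
the configured noise levels — not that it matches expert labels on real
tests.

## Domain classifier and threshold detection (`regressor`)

The classifier maps a 40 x 6 window to a 3-way softmax through a fixed
layer order: convolution (16 filters, kernel 5) -> average pooling
(width 2) -> batch normalization -> flatten -> dropout (0.2) -> dense 16
-> dropout -> batch normalization -> dense 3.  Filter counts, kernel
size, activations (ReLU), optimizer (Adam, 1e-3) and batch size (128)
are this package's defaults, recorded in `RegressorConfig`.  The
network is implemented on a small in-house numpy layer library with
hand-written backprop (`cpetml._nn`); everything is float64 and driven
by explicit generators, so training is bitwise reproducible.

Training windows are labeled by the domain at the window's **center**
second — a symmetric assignment that minimizes boundary bias.  At
inference the window rolls at 1-s stride; probability rows are smoothed
with a centered moving average (11 s, shrinking at the edges) because
raw softmax sequences chatter near the boundaries, and the per-row
argmax sequence is projected onto the best monotone
moderate -> heavy -> severe segmentation (dynamic programming minimizing
disagreements; ties break toward the earliest change).  Change times are
reported on the probability-row timestamps; pipelines whose labels refer
to window centers pass `time_offset_s = (40-1)/2` so estimates are
unbiased.  Threshold VO2 is the mean VO2 over +-5 s around the change
time.  A transition that never occurs is an absent value, not an error;
when the segmentation degenerates to a single change (no heavy segment)
the change is reported as VT1 and VT2 is left absent.

The classical baseline locates VT1 in the (VO2, VCO2) plane and VT2 in
the (VCO2, VE) plane by exhaustive bisegmental least squares: two
independent lines over every interior split (>= 5 points per side,
prefix-sum OLS), keeping the split with minimal total RSS.  A breakpoint
is accepted only if the two-line model beats the single line by an
F-test (df 2, n-4) at alpha = 0.05, the second slope exceeds the first
(thresholds are disproportionate *increases*), and the line intersection
falls inside the data range.  The intersection abscissa is the
breakpoint; VT2's VCO2 abscissa is mapped to VO2 by interpolation along
the ramp.

## Shapley explanations (`explain`)

The six input channels are players in a cooperative game.  A coalition
is evaluated by interventional replacement: channels in the coalition
keep the explained window's values, the others are taken from each
window of a background set (default: windows drawn from the training
corpus) and the model outputs are averaged.  With 6 players the exact
Shapley sum over all 64 coalitions is cheap, so exact enumeration is the
reference implementation and the permutation-sampling estimator is the
fast path; with all 720 orderings enumerated the two coincide.  The
base value of each output is the mean model output over the background
set, giving the efficiency identity
`sum_c phi[c, d] + base[d] = f_d(x)`.  Channels — not individual time
samples — are the attribution unit; a per-sample attribution would need
2^240 coalitions and would not match how practitioners read the traces.
Positive phi pushes the model toward the corresponding intensity domain.

## Conditional GAN (`cgan`)

The generator consumes a 53-long input (50 standard-normal draws + a
3-element one-hot domain label) on two heads: the latent head reshapes
to (50, 1) and applies a valid convolution (kernel 11) to a (40, 8) map;
the label head embeds the label to 40 steps and applies a small 'same'
convolution.  The heads are concatenated and a mixing convolution plus a
transposed convolution produce the 40 x 7 output (VO2, VCO2, PetO2,
PetCO2, VE, Rf, HR), bounded to [0, 1] by a sigmoid.  Batch
normalization in the generator keeps pre-activations centered — without
it the sigmoid output saturates early in adversarial training.  The
discriminator mirrors the two-head design (strided convolutions on the
window, a dense embedding of the label) and emits one scalar with the
0 = real / 1 = fake convention.

Desk-scale adversarial training (hundreds of windows, one CPU) is
notoriously unstable, so the training loop combines standard
stabilizers, all recorded in `GanConfig`: the discriminator also sees
real windows paired with *wrong* labels as fakes (matching-aware term,
which is what actually teaches label consistency); the generator update
adds a small supervised anchor `lambda * MSE(fake, real window of the
same label)` (lambda = 10, pix2pix-style) that pins the conditional
means while the adversarial term shapes the rest; gradients are clipped
to unit global norm; the learning rate (3e-4, Adam beta1 = 0.5) decays
linearly over the second half of training; and generated samples come
from an exponential moving average (decay 0.999) of the generator
weights.  Losses are binary cross-entropy on both sides.  The per-epoch
history tracks both losses plus the label-matched per-channel mean
discrepancy between generated and real windows — the fidelity number the
tests assert on.

Generated windows are denormalized with per-channel min/max statistics
(e.g. the `population_stats` summary of a simulated corpus) and can be
resampled to the breath domain using their own generated Rf channel.
Windows destined for the domain classifier are denormalized first and
then passed through `derive_ratios`, because the classifier consumes
ratio channels the generator does not emit.  Full-length test assembly
remains the parametric simulator's job; the GAN models 40-s windows.

## Evaluation (`bench`)

Threshold agreement is scored on the VO2 scale with the
model - reference sign convention (positive bias = overestimation):
RMSE, fractions within +-120 and +-240 mlO2 (both ranges reported for
both thresholds), and Bland-Altman bias with 1.96-SD limits of
agreement.  Pairs with an absent estimate on either side are excluded
and counted.  Splits are seeded random partitions at the whole-test
level (train size = round(n x fraction)).

The reference experiment (`ExperimentConfig` defaults, used by the
acceptance tests and `scripts/acceptance.py`) simulates 250 tests at
noise level 0.3, trains on the 80 % split (windows at 2-s stride,
10 epochs) and evaluates on the 50 held-out tests; it runs in about two
minutes on one CPU.  These sizes are the package's documented study
conditions; accuracy numbers quoted anywhere in this repository are the
outputs of exactly this computation.

## Numerical notes and limitations

* All randomness flows through `numpy.random.default_rng` seeds carried
  in configs; identical configs give bitwise-identical results.
* The monotone-segmentation projection assumes one pass through the
  domains; it cannot represent a test that genuinely never leaves the
  moderate domain other than by reporting absent thresholds.
* The F-test in the baseline assumes i.i.d. Gaussian residuals; on
  1-Hz interpolated data residuals are serially correlated, so the test
  is anti-conservative — harmless here because it only gates breakpoint
  acceptance.
* `within_range_fraction` treats boundary differences (exactly the half
  width) as inside, matching the closed ranges quoted in reports.
* The cGAN recipe is tuned for stability at desk scale, not for sample
  fidelity at corpus scale; matching the visual quality of a GAN trained
  on hundreds of real tests is out of scope.
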