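# cpetml

Machine-learning analysis of cardiopulmonary exercise tests (CPET):
automatic detection of the ventilatory thresholds, synthetic CPET
generation with known ground truth, and Shapley-value explanations of
the classifier's decisions — in one importable package.

## Who this is for

Exercise physiologists and biomedical-ML researchers who work with
breath-by-breath gas-exchange data and need (a) an objective, repeatable
estimate of the two ventilatory thresholds, (b) labeled synthetic tests
to develop and benchmark detection algorithms, and (c) a view into
*which* ventilatory variables drive a neural detector's decisions.

## The methods in brief

An incremental test traverses three exercise-intensity domains —
moderate, heavy, severe — separated by the ventilatory thresholds VT1
(first disproportionate rise of VCO2 vs VO2 and of VE) and VT2
(respiratory compensation point: second VE rise, PetCO2 starts falling).
Thresholds are reported as the VO2 (mlO2/min) at the transition.

* **Rolling-window CNN.**  Six per-test-normalized channels (RER, VE,
  PetO2, PetCO2, VE/VO2, VE/VCO2) in a 40-s window feed a small
  convolutional network with a 3-way softmax over the domains
  p(moderate), p(heavy), p(severe).  Rolling the window over the test
  gives one probability row per second; after smoothing, the thresholds
  are where the most probable domain changes (projected onto the
  monotone moderate→heavy→severe order).
* **V-slope baseline.**  Classical bisegmental regression: two lines fit
  VCO2 vs VO2 (VT1) or VE vs VCO2 (VT2); a breakpoint exists where the
  two-line fit beats one line by an F-test, and lies at the lines'
  intersection.
* **Parametric simulator.**  Piecewise-linear ramp physiology whose
  segment slopes follow the canonical domain patterns and whose
  breakpoints *are* the configured thresholds — the training corpus and
  ground truth for everything above.
* **Conditional GAN.**  A generator maps 50 random values + a one-hot
  domain label (53-long input) to a 40 × 7 window of normalized CPET
  channels; a two-head discriminator scores (window, label) pairs with
  the 0 = real / 1 = fake convention.
* **Shapley explanations.**  Exact coalition enumeration over the six
  input channels against a background window set: per window and output
  domain, six attributions that sum to (model output − base value).
* **Agreement metrics.**  RMSE on threshold VO2, fractions within
  ±120 / ±240 mlO2, and Bland–Altman bias with 1.96-SD limits of
  agreement.

Details, defaults and limitations: `docs/methods.md`.

## Worked example

```
python examples/train_threshold_detector.py
```

simulates 60 tests (noise level 0.3), trains the window classifier on
48 of them and reports, for the 12 held-out tests:

```
trained on 48 tests, validated on 12
final training accuracy: 0.990
cnn     VT1: rmse   11.7 mlO2/min | within +-120: 1.00 +-240: 1.00 | bias   +7.1 LoA [  -11.9,   +26.0]
cnn     VT2: rmse   14.7 mlO2/min | within +-120: 1.00 +-240: 1.00 | bias   -6.9 LoA [  -33.4,   +19.6]
vslope  VT1: rmse   18.2 mlO2/min | within +-120: 1.00 +-240: 1.00 | bias   -7.1 LoA [  -41.5,   +27.2]
vslope  VT2: rmse    8.5 mlO2/min | within +-120: 1.00 +-240: 1.00 | bias   +4.6 LoA [  -10.1,   +19.3]
```

RMSE is the headline accuracy of the threshold VO2 estimates; the ±120
and ±240 mlO2 fractions describe how many estimates fall inside the
conventional agreement ranges, and the Bland–Altman row gives the
systematic offset (bias) and the spread of disagreement (limits of
agreement).  On this idealized simulated physiology both methods land
within a few tens of mlO2/min of the true thresholds; real tests are
noisier in ways the simulator does not model (see `docs/methods.md`).

Other entry points: `examples/simulate_and_detect.py` (V-slope on one
noisy test), `examples/explain_decisions.py` (Shapley channel ranking),
`examples/generate_synthetic_windows.py` (train the cGAN, sample
labeled windows), and a thin CLI (`cpetml --help`) with `simulate`,
`train`, `detect`, `baseline`, `explain`, `evaluate`, `gan-train`,
`gan-sample` subcommands.

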