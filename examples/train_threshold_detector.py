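"""Train the rolling-window CNN on simulated tests and score it against
the known thresholds of held-out tests (takes a minute or two).

The experiment driver simulates a corpus, splits it at the test level,
trains the 40 x 6 window classifier, detects VT1/VT2 on the validation
tests from the probability crossings, and reports RMSE (mlO2/min),
fractions within +-120/+-240 mlO2, and Bland-Altman agreement, alongside
the V-slope baseline run on the same tests.
"""

from cpetml.bench import ExperimentConfig, run_experiment
from cpetml.regressor import RegressorConfig

cfg = ExperimentConfig(n_tests=60, noise_level=0.3, seed=7,
                       regressor=RegressorConfig(epochs=6))
report = run_experiment(cfg)

print(f"trained on {report['n_train']} tests, "
      f"validated on {report['n_validation']}")
print(f"final training accuracy: "
      f"{report['training_history']['accuracy'][-1]:.3f}")
for method in ("cnn", "vslope"):
    for vt in ("VT1", "VT2"):
        a = report["agreement"][method][vt]
        print(f"{method:7s} {vt}: rmse {a['rmse']:6.1f} mlO2/min | "
              f"within +-120: {a['frac_within_120']:.2f} "
              f"+-240: {a['frac_within_240']:.2f} | "
              f"bias {a['bias']:+6.1f} "
              f"LoA [{a['loa_low']:+7.1f}, {a['loa_high']:+7.1f}]")
print("rmse is the headline accuracy; bias near zero means neither "
      "method systematically over- or underestimates the thresholds")
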