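"""Agreement metrics, dataset splitting, and the end-to-end experiment.

Threshold estimates are compared to their references on the VO2 scale
(mlO2/min): root-mean-square error, the fraction of estimates falling
within +-120 and +-240 mlO2 of the reference, and Bland-Altman agreement
(bias and 1.96-SD limits of agreement).  Differences follow the
model - reference convention, so a positive bias means overestimation.
Pairs where either side reports an absent threshold are excluded from the
metrics and counted separately.

``run_experiment`` wires the whole pipeline together: simulate a corpus
with known thresholds, preprocess, split at the test level, train the
CNN, detect thresholds on the held-out tests with both the CNN and the
V-slope baseline, and report the agreement statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cpetio import (REGRESSOR_CHANNELS, derive_ratios,
                     interpolate_to_seconds, normalize_minmax)
from .errors import CPETError, InsufficientDataError
from .regressor import (RegressorConfig, detect_thresholds,
                        infer_probabilities, label_windows, train_regressor,
                        vslope_baseline)
from .simulate import sample_config, simulate_cpet

__all__ = [
    "AgreementReport", "split_dataset", "paired_differences",
    "rmse_thresholds", "within_range_fraction", "bland_altman",
    "ExperimentConfig", "run_experiment",
]

#: Half-widths (mlO2/min) of the agreement ranges reported for both
#: thresholds (the narrow one is conventionally quoted for VT2, the wide
#: one for VT1; the full 2x2 grid is emitted).
RANGE_NARROW = 120.0
RANGE_WIDE = 240.0


def split_dataset(ids, train_fraction: float, seed: int = 0):
    """Seeded random partition of test ids into (train, validation)."""
    ids = list(ids)
    n = len(ids)
    if not 0 < train_fraction < 1:
        raise CPETError("train_fraction must be in (0, 1)")
    if n < 2:
        raise InsufficientDataError("need at least 2 ids to split")
    n_train = round(n * train_fraction)
    if n_train == 0 or n_train == n:
        raise CPETError("split would leave one side empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    val = [ids[i] for i in sorted(perm[n_train:])]
    return train, val


def paired_differences(estimates, references):
    """(model - reference) differences over pairs where both are present.

    Returns ``(diffs, n_dropped)``.
    """
    if len(estimates) != len(references):
        raise CPETError("estimates and references must have equal length")
    diffs, dropped = [], 0
    for e, r in zip(estimates, references):
        if e is None or r is None or not (
                math.isfinite(e) and math.isfinite(r)):
            dropped += 1
            continue
        diffs.append(float(e) - float(r))
    return np.asarray(diffs), dropped


def rmse_thresholds(estimates, references) -> float:
    """Root-mean-square error (mlO2/min) over retained pairs."""
    diffs, _ = paired_differences(estimates, references)
    if diffs.size == 0:
        raise InsufficientDataError("no retained pairs for RMSE")
    return float(np.sqrt(np.mean(diffs ** 2)))


def within_range_fraction(estimates, references, half_width: float) -> float:
    """Fraction of retained pairs with |model - reference| <= half_width."""
    diffs, _ = paired_differences(estimates, references)
    if diffs.size == 0:
        raise InsufficientDataError("no retained pairs")
    return float(np.mean(np.abs(diffs) <= half_width))


def bland_altman(estimates, references):
    """(bias, loa_low, loa_high): mean difference +- 1.96 sample SD."""
    diffs, _ = paired_differences(estimates, references)
    if diffs.size < 2:
        raise InsufficientDataError("Bland-Altman needs >= 2 pairs")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


@dataclass
class AgreementReport:
    """Agreement between one method's threshold estimates and references."""

    n_pairs: int
    n_dropped: int
    rmse: float
    frac_within_120: float
    frac_within_240: float
    bias: float
    loa_low: float
    loa_high: float
    differences: list = field(default_factory=list)

    @classmethod
    def from_pairs(cls, estimates, references) -> "AgreementReport":
        diffs, dropped = paired_differences(estimates, references)
        if diffs.size < 2:
            raise InsufficientDataError(
                "agreement report needs >= 2 retained pairs")
        bias, lo, hi = bland_altman(estimates, references)
        return cls(
            n_pairs=int(diffs.size), n_dropped=dropped,
            rmse=float(np.sqrt(np.mean(diffs ** 2))),
            frac_within_120=float(np.mean(np.abs(diffs) <= RANGE_NARROW)),
            frac_within_240=float(np.mean(np.abs(diffs) <= RANGE_WIDE)),
            bias=bias, loa_low=lo, loa_high=hi,
            differences=[float(d) for d in diffs])

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExperimentConfig:
    """Settings of the end-to-end parameter-recovery experiment."""

    n_tests: int = 250
    train_fraction: float = 0.8
    noise_level: float = 0.3
    train_window_stride_s: int = 2
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    seed: int = 0


def run_experiment(config: ExperimentConfig | None = None) -> dict:
    """Simulate, train, detect, and score; returns a JSON-able report.

    Per validation test the report stores the ground truth and both
    methods' estimates, plus AgreementReports for VT1 and VT2 under the
    CNN and the V-slope baseline.  Fully determined by ``config.seed``.
    """
    config = config or ExperimentConfig()
    rng = np.random.default_rng(config.seed)
    sim_cfgs = [sample_config(rng, noise_level=config.noise_level)
                for _ in range(config.n_tests)]

    tests = []
    for cfg in sim_cfgs:
        bt, gt = simulate_cpet(cfg)
        st = derive_ratios(interpolate_to_seconds(bt))
        nt = normalize_minmax(st, REGRESSOR_CHANNELS)
        tests.append({"cfg": cfg, "st": st, "nt": nt, "gt": gt})

    train_ids, val_ids = split_dataset(
        range(config.n_tests), config.train_fraction,
        seed=int(rng.integers(2 ** 31 - 1)))

    xs, ys = [], []
    for i in train_ids:
        tensor, onehot, _ = label_windows(
            tests[i]["nt"], tests[i]["gt"],
            width_s=config.regressor.window,
            stride_s=config.train_window_stride_s)
        xs.append(tensor)
        ys.append(onehot)
    model, history = train_regressor(
        np.concatenate(xs), np.concatenate(ys), config.regressor,
        seed=int(rng.integers(2 ** 31 - 1)))

    center_offset = (config.regressor.window - 1) / 2.0
    per_test = []
    est = {("cnn", "VT1"): [], ("cnn", "VT2"): [],
           ("vslope", "VT1"): [], ("vslope", "VT2"): []}
    ref = {"VT1": [], "VT2": []}
    ordering_violations = 0
    for i in val_ids:
        t = tests[i]
        dp = infer_probabilities(model, t["nt"])
        cnn = detect_thresholds(dp, t["st"], time_offset_s=center_offset)
        vs = vslope_baseline(t["st"], ramp_start_s=t["cfg"].ramp_start_s)
        if (cnn.VT1_s is not None and cnn.VT2_s is not None
                and not (cnn.VT1_s < cnn.VT2_s
                         and cnn.VT1_VO2 < cnn.VT2_VO2)):
            ordering_violations += 1
        est[("cnn", "VT1")].append(cnn.VT1_VO2)
        est[("cnn", "VT2")].append(cnn.VT2_VO2)
        est[("vslope", "VT1")].append(vs.VT1_VO2)
        est[("vslope", "VT2")].append(vs.VT2_VO2)
        ref["VT1"].append(t["gt"].VT1_VO2)
        ref["VT2"].append(t["gt"].VT2_VO2)
        per_test.append({
            "test_id": int(i), "sim_seed": int(t["cfg"].seed),
            "ground_truth": t["gt"].as_labels_dict(),
            "cnn": cnn.as_dict(), "vslope": vs.as_dict()})

    agreement = {}
    for method in ("cnn", "vslope"):
        agreement[method] = {}
        for vt in ("VT1", "VT2"):
            agreement[method][vt] = AgreementReport.from_pairs(
                est[(method, vt)], ref[vt]).as_dict()

    detected = {vt: sum(1 for e in est[("cnn", vt)] if e is not None)
                for vt in ("VT1", "VT2")}
    return {
        "config": {
            "n_tests": config.n_tests,
            "train_fraction": config.train_fraction,
            "noise_level": config.noise_level,
            "train_window_stride_s": config.train_window_stride_s,
            "regressor": asdict(config.regressor),
            "seed": config.seed,
        },
        "n_train": len(train_ids), "n_validation": len(val_ids),
        "training_history": history,
        "agreement": agreement,
        "cnn_detected": detected,
        "cnn_ordering_violations": ordering_violations,
        "per_test": per_test,
    }
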