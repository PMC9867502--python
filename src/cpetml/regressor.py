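"""Rolling-window CNN domain classifier and threshold extraction.

The classifier maps a 40-s window of six normalized channels (RER, VE,
PetO2, PetCO2, VE/VO2, VE/VCO2) to a softmax over the three
exercise-intensity domains.  Rolling the window over the whole test gives
one probability row per second; the ventilatory thresholds are located
where the most probable domain changes.  Because raw softmax sequences
chatter near the boundaries, the probabilities are smoothed with a short
centered moving average and the per-row argmax sequence is projected onto
the best monotone moderate -> heavy -> severe segmentation before the
change times are read off.

A classical V-slope baseline (bisegmental least squares with an F-test
for the existence of a breakpoint) is provided for comparison: VT1 from
the VCO2-vs-VO2 plane, VT2 from the VE-vs-VCO2 plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import _nn
from .cpetio import NormalizedTable, SecondTable, window_tensor
from .errors import CPETError, InsufficientDataError, ValidationError
from .simulate import GroundTruth

__all__ = [
    "RegressorConfig", "DomainProbabilities", "ThresholdEstimate",
    "CNNDomainClassifier", "build_regressor", "label_windows",
    "train_regressor", "infer_probabilities", "detect_thresholds",
    "vslope_baseline", "bisegmental_fit",
]


@dataclass
class RegressorConfig:
    """Hyperparameters of the CNN; the layer order itself is fixed."""

    window: int = 40
    n_channels: int = 6
    n_filters: int = 16
    kernel: int = 5
    pool: int = 2
    dense_units: int = 16
    dropout: float = 0.2
    lr: float = 1e-3
    batch_size: int = 128
    epochs: int = 10


@dataclass
class DomainProbabilities:
    """Per-window softmax output; one row per rolling-window start time."""

    data: pd.DataFrame  # columns: t, p_moderate, p_heavy, p_severe

    def __post_init__(self):
        p = self.probs
        if np.any(p < -1e-12):
            raise ValidationError("probabilities must be nonnegative")
        sums = p.sum(axis=1)
        if np.any(sums <= 0):
            raise ValidationError("probability rows must have positive mass")
        # softmax rows sum to 1; a single uniform rescaling of all rows is
        # tolerated because threshold detection depends only on ordering
        if np.any(np.abs(sums - sums[0]) > 1e-6 * sums[0]):
            raise ValidationError("probability rows must share one scale")
        t = self.t
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError("rows must be time-ordered")

    @classmethod
    def from_array(cls, t, probs) -> "DomainProbabilities":
        df = pd.DataFrame({"t": np.asarray(t, float),
                           "p_moderate": probs[:, 0],
                           "p_heavy": probs[:, 1],
                           "p_severe": probs[:, 2]})
        return cls(df)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(float)

    @property
    def probs(self) -> np.ndarray:
        return self.data[["p_moderate", "p_heavy", "p_severe"]].to_numpy(float)

    def __len__(self):
        return len(self.data)


@dataclass
class ThresholdEstimate:
    """VT1/VT2 as time (s) and VO2 (mlO2/min); any field may be absent."""

    VT1_s: float | None = None
    VT2_s: float | None = None
    VT1_VO2: float | None = None
    VT2_VO2: float | None = None
    method: str = "cnn"

    def as_dict(self) -> dict:
        return asdict(self)


class CNNDomainClassifier:
    """The fixed layer stack: conv -> average pooling -> batch norm ->
    flatten -> dropout -> dense(16) -> dropout -> batch norm -> dense(3)
    with a softmax readout."""

    def __init__(self, config: RegressorConfig | None = None, seed: int = 0):
        self.config = config or RegressorConfig()
        cfg = self.config
        self.rng = np.random.default_rng(seed)
        conv_out = cfg.window - cfg.kernel + 1
        flat = (conv_out // cfg.pool) * cfg.n_filters
        self.net = _nn.Sequential([
            _nn.Conv1D(cfg.n_channels, cfg.n_filters, cfg.kernel, self.rng),
            _nn.Relu(),
            _nn.AvgPool1D(cfg.pool),
            _nn.BatchNorm(cfg.n_filters),
            _nn.Flatten(),
            _nn.Dropout(cfg.dropout, self.rng),
            _nn.Dense(flat, cfg.dense_units, self.rng),
            _nn.Relu(),
            _nn.Dropout(cfg.dropout, self.rng),
            _nn.BatchNorm(cfg.dense_units),
            _nn.Dense(cfg.dense_units, 3, self.rng),
        ])

    def logits(self, x, training=False):
        x = np.asarray(x, float)
        if x.ndim == 2:
            x = x[None]
        cfg = self.config
        if x.shape[1:] != (cfg.window, cfg.n_channels):
            raise ValidationError(
                f"expected windows of shape ({cfg.window}, {cfg.n_channels}),"
                f" got {x.shape[1:]}")
        return self.net.forward(x, training=training)

    def predict_proba(self, x) -> np.ndarray:
        """Softmax domain probabilities for a batch of (40, 6) windows."""
        return _nn.softmax(self.logits(x, training=False))

    # -- persistence -------------------------------------------------------
    def save(self, path):
        arrays = {f"p{i}": p for i, p in enumerate(self.net.params)}
        for i, l in enumerate(self.net.layers):
            if isinstance(l, _nn.BatchNorm):
                arrays[f"bn{i}_mean"] = l.running_mean
                arrays[f"bn{i}_var"] = l.running_var
        arrays["config"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "CNNDomainClassifier":
        data = np.load(path)
        config = RegressorConfig(**json.loads(bytes(data["config"]).decode()))
        model = cls(config)
        for i, p in enumerate(model.net.params):
            p[...] = data[f"p{i}"]
        for i, l in enumerate(model.net.layers):
            if isinstance(l, _nn.BatchNorm):
                l.running_mean = data[f"bn{i}_mean"]
                l.running_var = data[f"bn{i}_var"]
        return model


def build_regressor(config: RegressorConfig | None = None,
                    seed: int = 0) -> CNNDomainClassifier:
    """Construct the (untrained) rolling-window CNN."""
    return CNNDomainClassifier(config, seed=seed)


def label_windows(nt: NormalizedTable, gt: GroundTruth,
                  width_s: int = 40, stride_s: int = 1):
    """Windows plus one-hot domain labels, labeled at the window center.

    Returns ``(tensor (n, width, 6), onehot (n, 3), starts (n,))``.
    """
    tensor, starts = window_tensor(nt, width_s=width_s, stride_s=stride_s)
    t_lo, t_hi = gt.t[0], gt.t[-1]
    if starts[0] < t_lo or starts[-1] + width_s - 1 > t_hi:
        raise ValidationError("ground truth does not cover the table span")
    centers = starts + (width_s - 1) / 2.0
    labels = np.array([gt.domain_at(c) for c in centers])
    onehot = np.eye(3)[labels]
    return tensor, onehot, starts


def train_regressor(windows, onehot, config: RegressorConfig | None = None,
                    seed: int = 0, model: CNNDomainClassifier | None = None):
    """Train the CNN with Adam on categorical cross-entropy.

    Fully seeded: weight init, dropout masks and batch shuffling all
    derive from ``seed``.  Returns ``(model, history)`` where history maps
    'loss' and 'accuracy' to per-epoch values.
    """
    windows = np.asarray(windows, float)
    onehot = np.asarray(onehot, float)
    if windows.shape[0] == 0:
        raise InsufficientDataError("no training windows")
    counts = onehot.sum(axis=0)
    for d, c in zip(("moderate", "heavy", "severe"), counts):
        if c == 0:
            raise CPETError(f"class absent from training data: {d}")
    if model is None:
        model = CNNDomainClassifier(config, seed=seed)
    cfg = model.config
    rng = np.random.default_rng(seed + 1)
    opt = _nn.Adam(model.net.params, lr=cfg.lr)
    n = windows.shape[0]
    history = {"loss": [], "accuracy": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, yb = windows[idx], onehot[idx]
            logits = model.logits(xb, training=True)
            loss, dlogits = _nn.softmax_cross_entropy(logits, yb)
            model.net.backward(dlogits)
            opt.step(model.net.grads)
            losses.append(loss * len(idx))
            correct += int((logits.argmax(1) == yb.argmax(1)).sum())
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(correct / n)
    return model, history


def infer_probabilities(model: CNNDomainClassifier,
                        nt: NormalizedTable) -> DomainProbabilities:
    """Roll the window over the whole test: one probability row per second."""
    cfg = model.config
    tensor, starts = window_tensor(nt, width_s=cfg.window, stride_s=1)
    probs = model.predict_proba(tensor)
    return DomainProbabilities.from_array(starts, probs)


def _moving_average(p: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with shrinking edge windows, per column."""
    if width <= 1 or len(p) == 1:
        return p
    half = width // 2
    csum = np.cumsum(np.vstack([np.zeros((1, p.shape[1])), p]), axis=0)
    n = len(p)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def _monotone_segmentation(argmax: np.ndarray) -> tuple[int, int]:
    """Best (i, j) with moderate on [0,i), heavy on [i,j), severe on [j,n),
    minimizing disagreements with the argmax sequence; ties break toward
    the earliest change times."""
    n = len(argmax)
    not_mod = np.concatenate([[0], np.cumsum(argmax != 0)])
    not_heavy = np.concatenate([[0], np.cumsum(argmax != 1)])
    not_sev = np.concatenate([[0], np.cumsum(argmax != 2)])
    # cost(i, j) = not_mod[i] + (not_heavy[j]-not_heavy[i]) + (not_sev[n]-not_sev[j])
    #            = (not_mod[i]-not_heavy[i]) + (not_heavy[j]-not_sev[j]) + not_sev[n]
    g = not_heavy - not_sev
    # suffix argmin of g over j >= i, preferring the smallest j
    suf_idx = np.empty(n + 1, dtype=int)
    best = n
    suf_idx[n] = n
    for j in range(n - 1, -1, -1):
        if g[j] <= g[best]:
            best = j
        suf_idx[j] = best
    f = not_mod - not_heavy
    best_cost, best_ij = None, (0, 0)
    for i in range(n + 1):
        j = suf_idx[i] if i < n else n
        cost = f[i] + g[j]
        if best_cost is None or cost < best_cost:
            best_cost, best_ij = cost, (i, j)
    return best_ij


def detect_thresholds(dp: DomainProbabilities, st: SecondTable,
                      smooth_width_s: int = 11,
                      time_offset_s: float = 0.0,
                      vo2_halfwidth_s: float = 5.0) -> ThresholdEstimate:
    """Locate VT1/VT2 where the most probable domain changes.

    ``time_offset_s`` shifts the reported change times relative to the
    probability-row timestamps; pipelines whose training labels refer to
    the window center pass (window-1)/2 so the estimates are unbiased.
    VO2 at each threshold is the mean over +-``vo2_halfwidth_s`` seconds of
    the second-domain record around the change time.  Transitions that do
    not occur are reported as absent, not as errors.
    """
    if len(dp) == 0:
        raise InsufficientDataError("empty probability table")
    sm = _moving_average(dp.probs, smooth_width_s)
    argmax = sm.argmax(axis=1)
    i, j = _monotone_segmentation(argmax)
    n = len(argmax)
    t = dp.t

    def change_time(k: int) -> float:
        return float(t[k]) + time_offset_s

    est = ThresholdEstimate(method="cnn")
    if 0 < i < n:
        est.VT1_s = change_time(i)
        est.VT1_VO2 = _vo2_around(st, est.VT1_s, vo2_halfwidth_s)
    if i < j < n:
        est.VT2_s = change_time(j)
        est.VT2_VO2 = _vo2_around(st, est.VT2_s, vo2_halfwidth_s)
    return est


def _vo2_around(st: SecondTable, time_s: float, half: float) -> float:
    t = st.t
    mask = (t >= time_s - half) & (t <= time_s + half)
    if not mask.any():  # outside the record; clamp to nearest second
        k = int(np.argmin(np.abs(t - time_s)))
        mask = np.zeros(len(t), bool)
        mask[k] = True
    return float(st.channel("VO2")[mask].mean())


# ---------------------------------------------------------------------------
# classical baseline: bisegmental (two-line) regression

def bisegmental_fit(x: np.ndarray, y: np.ndarray, min_side: int = 5):
    """Exhaustive two-line least squares over all interior split points.

    Fits independent lines to the points left/right of every candidate
    split (each side keeping >= ``min_side`` points), picks the split with
    the smallest total residual sum of squares, and compares it to the
    single-line fit with an F-test (df 2, n-4).  Returns a dict with the
    breakpoint abscissa (intersection of the two lines), both line
    parameters, the RSS values, the split index and the p-value.
    """
    order = np.argsort(x, kind="stable")
    x, y = np.asarray(x, float)[order], np.asarray(y, float)[order]
    n = len(x)
    if n < 2 * min_side:
        raise InsufficientDataError(f"need >= {2 * min_side} points")

    ones = np.ones(n)
    cx = np.concatenate([[0], np.cumsum(x)])
    cy = np.concatenate([[0], np.cumsum(y)])
    cxx = np.concatenate([[0], np.cumsum(x * x)])
    cxy = np.concatenate([[0], np.cumsum(x * y)])
    cyy = np.concatenate([[0], np.cumsum(y * y)])

    def seg_fit(a, b):
        """OLS y = c0 + c1 x over points [a, b); returns (c0, c1, rss)."""
        m = b - a
        sx, sy = cx[b] - cx[a], cy[b] - cy[a]
        sxx, sxy = cxx[b] - cxx[a], cxy[b] - cxy[a]
        syy = cyy[b] - cyy[a]
        det = m * sxx - sx * sx
        if det <= 0:
            c1 = 0.0
            c0 = sy / m
        else:
            c1 = (m * sxy - sx * sy) / det
            c0 = (sy - c1 * sx) / m
        rss = syy - c0 * sy - c1 * sxy
        return c0, c1, max(rss, 0.0)

    best = None
    for k in range(min_side, n - min_side + 1):
        _, _, rss_l = seg_fit(0, k)
        _, _, rss_r = seg_fit(k, n)
        rss = rss_l + rss_r
        if best is None or rss < best[0] - 1e-12:
            best = (rss, k)
    rss2, k = best
    c0l, c1l, _ = seg_fit(0, k)
    c0r, c1r, _ = seg_fit(k, n)
    _, _, rss1 = seg_fit(0, n)

    if rss2 <= 0 or n <= 4:
        p_value = 0.0 if rss1 > rss2 + 1e-12 else 1.0
    else:
        f_stat = ((rss1 - rss2) / 2.0) / (rss2 / (n - 4))
        p_value = float(sstats.f.sf(f_stat, 2, n - 4))

    if abs(c1r - c1l) > 1e-300:
        x_break = (c0l - c0r) / (c1r - c1l)
    else:
        x_break = np.nan
    return {"x_break": x_break, "left": (c0l, c1l), "right": (c0r, c1r),
            "rss_two": rss2, "rss_one": rss1, "split_index": k,
            "split_x": float(x[k]), "p_value": p_value,
            "x_range": (float(x[0]), float(x[-1]))}


def _accept_breakpoint(fit: dict, alpha: float) -> bool:
    if fit["p_value"] >= alpha:
        return False
    if not np.isfinite(fit["x_break"]):
        return False
    lo, hi = fit["x_range"]
    if not (lo <= fit["x_break"] <= hi):
        return False
    # thresholds announce a disproportionate *increase* of y vs x
    return fit["right"][1] > fit["left"][1]


def vslope_baseline(st: SecondTable, ramp_start_s: float | None = None,
                    alpha: float = 0.05) -> ThresholdEstimate:
    """Classical breakpoint detection by bisegmental regression.

    VT1 is the slope change of VCO2 plotted against VO2; VT2 the slope
    change of VE against VCO2.  A breakpoint is accepted only when the
    two-line fit beats the single line by an F-test at ``alpha`` and the
    second slope exceeds the first.  Estimates are mapped back to VO2
    (mlO2/min) and time via interpolation along the ramp.
    """
    df = st.data
    if ramp_start_s is not None:
        df = df[df["t"] >= ramp_start_s]
    if len(df) < 10:
        raise InsufficientDataError("need >= 10 points for the baseline")
    t = df["t"].to_numpy(float)
    vo2 = df["VO2"].to_numpy(float)
    vco2 = df["VCO2"].to_numpy(float)
    ve = df["VE"].to_numpy(float)

    est = ThresholdEstimate(method="vslope")

    fit1 = bisegmental_fit(vo2, vco2)
    if _accept_breakpoint(fit1, alpha):
        est.VT1_VO2 = float(fit1["x_break"])
        est.VT1_s = _map_via_sorted(vo2, t, est.VT1_VO2)

    fit2 = bisegmental_fit(vco2, ve)
    if _accept_breakpoint(fit2, alpha):
        vco2_break = float(fit2["x_break"])
        est.VT2_VO2 = _map_via_sorted(vco2, vo2, vco2_break)
        est.VT2_s = _map_via_sorted(vco2, t, vco2_break)
    return est


def _map_via_sorted(x: np.ndarray, y: np.ndarray, x0: float) -> float:
    order = np.argsort(x, kind="stable")
    return float(np.interp(x0, x[order], y[order]))
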