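"""Conditional GAN over 40-s windows of seven CPET channels.

The generator consumes a 53-element input — 50 random values followed by
a 3-element one-hot intensity-domain label — and emits a 40 x 7 window of
normalized channels (VO2, VCO2, PetO2, PetCO2, VE, Rf, HR).  Both heads
pass through convolutional stacks, are concatenated, and a transposed
convolutional layer produces the final 40 x 7 map with a bounded
(sigmoid) output.  The discriminator takes a 40 x 7 window and the 3-long
label on separate heads and emits a single scalar, using the convention
0 = real / 1 = fake.

Training alternates discriminator and generator updates with binary
cross-entropy; everything is driven by one seed, so runs are
reproducible.  Generated windows are denormalized with per-channel
min/max statistics (from :func:`cpetml.simulate.population_stats` over a
synthetic corpus) and, because Rf is among the generated channels, can be
resampled to the breath domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import _nn
from .cpetio import (GAN_CHANNELS, SecondTable, normalize_minmax,
                     window_tensor)
from .errors import CPETError, InsufficientDataError, ValidationError
from .simulate import to_breath_domain

__all__ = [
    "GanConfig", "Generator", "Discriminator", "build_generator",
    "build_discriminator", "train_cgan", "generate_window",
    "denormalize_window", "generated_to_breath", "prepare_gan_windows",
    "mean_channel_discrepancy",
]

LATENT_DIM = 50
N_LABELS = 3
WINDOW = 40
N_CHANNELS = 7


@dataclass
class GanConfig:
    """Architecture and training hyperparameters (the tensor contract —
    53-long input, 40 x 7 output, two heads each side — is fixed).

    The last four fields are the desk-scale stabilizers documented in the
    methods note: a supervised MSE anchor on the generator toward
    label-matched real windows, global gradient-norm clipping, an
    exponential moving average of the generator weights for sampling,
    and a linear learning-rate decay over the second half of training.
    """

    latent_filters: int = 8
    label_filters: int = 4
    mix_filters: int = 16
    disc_filters: int = 16
    disc_dense: int = 32
    lr: float = 3e-4
    beta1: float = 0.5
    batch_size: int = 16
    mse_anchor: float = 10.0
    clip_norm: float = 1.0
    ema_decay: float = 0.999
    lr_decay: bool = True


class Generator:
    """(50-latent, 3-label) -> 40 x 7 window in [0, 1]."""

    def __init__(self, config: GanConfig | None = None, seed: int = 0):
        self.config = config or GanConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        # latent head: (50, 1) -> valid conv of kernel 11 -> (40, f)
        self.z_head = _nn.Sequential([
            _nn.Conv1D(1, cfg.latent_filters, 11, rng),
            _nn.LeakyRelu(),
        ])
        # label head: dense embedding to 40 steps, then a 'same' conv
        self.l_dense = _nn.Dense(N_LABELS, WINDOW, rng)
        self.l_act = _nn.LeakyRelu()
        self.l_head = _nn.Sequential([
            _nn.Conv1D(1, cfg.label_filters, 3, rng, padding="same"),
            _nn.LeakyRelu(),
        ])
        # concatenated (40, latent+label filters) -> transposed conv -> (40, 7)
        self.tail = _nn.Sequential([
            _nn.Conv1D(cfg.latent_filters + cfg.label_filters,
                       cfg.mix_filters, 5, rng, padding="same"),
            _nn.LeakyRelu(),
            _nn.ConvTranspose1D(cfg.mix_filters, N_CHANNELS, 5, rng),
            _nn.Sigmoid(),
        ])

    @property
    def params(self):
        return (self.z_head.params + self.l_dense.params
                + self.l_head.params + self.tail.params)

    @property
    def grads(self):
        return (self.z_head.grads + self.l_dense.grads
                + self.l_head.grads + self.tail.grads)

    def forward(self, z, labels, training=False):
        z = np.asarray(z, float)
        labels = np.asarray(labels, float)
        if z.ndim == 1:
            z = z[None]
        if labels.ndim == 1:
            labels = labels[None]
        if z.shape[1] != LATENT_DIM:
            raise ValidationError(
                f"latent input must have length {LATENT_DIM}, got {z.shape[1]}")
        if labels.shape[1] != N_LABELS:
            raise ValidationError("label must be a 3-element one-hot vector")
        zs = self.z_head.forward(z[:, :, None], training=training)
        le = self.l_act.forward(self.l_dense.forward(labels,
                                                     training=training))
        ls = self.l_head.forward(le[:, :, None], training=training)
        self._split = zs.shape[2]
        h = np.concatenate([zs, ls], axis=2)
        return self.tail.forward(h, training=training)

    __call__ = forward

    def backward(self, dout):
        dh = self.tail.backward(dout)
        dzs, dls = dh[:, :, :self._split], dh[:, :, self._split:]
        self.z_head.backward(dzs)
        dle = self.l_head.backward(dls)[:, :, 0]
        self.l_dense.backward(self.l_act.backward(dle))


class Discriminator:
    """(40 x 7 window, 3-label) -> scalar in [0, 1]; 0 = real, 1 = fake."""

    def __init__(self, config: GanConfig | None = None, seed: int = 0):
        self.config = config or GanConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        t1 = (WINDOW - 5) // 2 + 1          # conv k5 stride 2
        t2 = (t1 - 5) // 2 + 1
        self.w_head = _nn.Sequential([
            _nn.Conv1D(N_CHANNELS, cfg.disc_filters, 5, rng, stride=2),
            _nn.LeakyRelu(),
            _nn.Conv1D(cfg.disc_filters, cfg.disc_filters, 5, rng, stride=2),
            _nn.LeakyRelu(),
            _nn.Flatten(),
            _nn.Dense(t2 * cfg.disc_filters, cfg.disc_dense, rng),
            _nn.LeakyRelu(),
        ])
        self.l_head = _nn.Sequential([
            _nn.Dense(N_LABELS, 16, rng),
            _nn.LeakyRelu(),
        ])
        self.out = _nn.Dense(cfg.disc_dense + 16, 1, rng)

    @property
    def params(self):
        return self.w_head.params + self.l_head.params + self.out.params

    @property
    def grads(self):
        return self.w_head.grads + self.l_head.grads + self.out.grads

    def logits(self, windows, labels, training=False):
        windows = np.asarray(windows, float)
        labels = np.asarray(labels, float)
        if windows.ndim == 2:
            windows = windows[None]
        if labels.ndim == 1:
            labels = labels[None]
        if windows.shape[1:] != (WINDOW, N_CHANNELS):
            raise ValidationError(
                f"expected windows of shape ({WINDOW}, {N_CHANNELS}), "
                f"got {windows.shape[1:]}")
        hw = self.w_head.forward(windows, training=training)
        hl = self.l_head.forward(labels, training=training)
        self._split = hw.shape[1]
        return self.out.forward(np.concatenate([hw, hl], axis=1),
                                training=training)[:, 0]

    def __call__(self, windows, labels):
        """Probability of being fake (sigmoid of the logit)."""
        return _nn.sigmoid(self.logits(windows, labels))

    def backward(self, dlogits):
        """Returns the gradient w.r.t. the input windows (for G updates)."""
        dh = self.out.backward(dlogits[:, None])
        dhw, dhl = dh[:, :self._split], dh[:, self._split:]
        self.l_head.backward(dhl)
        return self.w_head.backward(dhw)


def build_generator(config: GanConfig | None = None, seed: int = 0
                    ) -> Generator:
    return Generator(config, seed=seed)


def build_discriminator(config: GanConfig | None = None, seed: int = 0
                        ) -> Discriminator:
    return Discriminator(config, seed=seed)


def _one_hot(label) -> np.ndarray:
    names = ("moderate", "heavy", "severe")
    if isinstance(label, str):
        if label not in names:
            raise ValidationError(f"unknown domain label: {label}")
        label = names.index(label)
    if isinstance(label, (int, np.integer)):
        if not 0 <= label < N_LABELS:
            raise ValidationError(f"domain index out of range: {label}")
        return np.eye(N_LABELS)[label]
    arr = np.asarray(label, float)
    if arr.shape != (N_LABELS,) or not (
            np.all((arr == 0) | (arr == 1)) and arr.sum() == 1):
        raise ValidationError("label must be one-hot over 3 domains")
    return arr


def _clipped(grads, max_norm: float):
    if max_norm <= 0:
        return grads
    total = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if total > max_norm:
        s = max_norm / total
        return [g * s for g in grads]
    return grads


def train_cgan(windows, labels, epochs: int, batch_size: int | None = None,
               seed: int = 0, config: GanConfig | None = None):
    """Adversarial training on labeled real windows.

    ``windows``: (n, 40, 7) normalized real data; ``labels``: (n, 3)
    one-hot.  Per epoch the discriminator is updated with binary
    cross-entropy on real pairs (target 0), generated pairs (target 1)
    and — to enforce label consistency — real windows paired with wrong
    labels (target 1); the generator is then updated to drive the
    discriminator's output on its samples toward 0 ("real"), with a
    small supervised MSE anchor toward a label-matched real window that
    pins the conditional means (see the methods note for why desk-scale
    adversarial training needs this).  Generated samples come from an
    exponential moving average of the generator weights.  Returns
    ``(generator, discriminator, history)``; history holds per-epoch
    mean losses and the label-matched per-channel mean discrepancy
    between generated and real windows.
    """
    windows = np.asarray(windows, float)
    labels = np.asarray(labels, float)
    if windows.shape[0] == 0:
        raise InsufficientDataError("empty training set")
    if windows.shape[1:] != (WINDOW, N_CHANNELS):
        raise ValidationError("real windows must be (n, 40, 7)")
    config = config or GanConfig()
    if batch_size is None:
        batch_size = config.batch_size
    rng = np.random.default_rng(seed)
    gen = Generator(config, seed=int(rng.integers(2 ** 31 - 1)))
    disc = Discriminator(config, seed=int(rng.integers(2 ** 31 - 1)))
    opt_g = _nn.Adam(gen.params, lr=config.lr, beta1=config.beta1)
    opt_d = _nn.Adam(disc.params, lr=config.lr, beta1=config.beta1)
    ema = [p.copy() for p in gen.params]

    n = windows.shape[0]
    label_idx = labels.argmax(axis=1)
    everything = np.arange(n)
    by_label = [np.nonzero(label_idx == d)[0] for d in range(N_LABELS)]
    by_label = [ix if ix.size else everything for ix in by_label]
    eval_z = rng.standard_normal((n, LATENT_DIM))
    history = {"d_loss": [], "g_loss": [], "mean_discrepancy": []}
    for epoch in range(epochs):
        if config.lr_decay and epochs > 1:
            frac = epoch / epochs
            scale = 1.0 if frac < 0.5 else max(
                0.05, 1.0 - 0.95 * (frac - 0.5) / 0.5)
            opt_g.lr = config.lr * scale
            opt_d.lr = config.lr * scale
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            xr, yr = windows[idx], labels[idx]
            m = len(idx)
            # --- discriminator: real -> 0, fake -> 1, mismatched -> 1
            z = rng.standard_normal((m, LATENT_DIM))
            xf = gen.forward(z, yr, training=True)
            ywrong = np.eye(N_LABELS)[
                (yr.argmax(1) + rng.integers(1, N_LABELS, m)) % N_LABELS]
            xb = np.concatenate([xr, xf, xr], axis=0)
            yb = np.concatenate([yr, yr, ywrong], axis=0)
            targets = np.concatenate([np.zeros(m), np.ones(2 * m)])
            logits = disc.logits(xb, yb, training=True)
            d_loss, dlogits = _nn.sigmoid_bce_with_logits(logits, targets)
            disc.backward(dlogits)
            opt_d.step(_clipped(disc.grads, config.clip_norm))
            # --- generator: adversarial BCE toward "real" + MSE anchor
            z = rng.standard_normal((m, LATENT_DIM))
            xf = gen.forward(z, yr, training=True)
            logits = disc.logits(xf, yr, training=True)
            g_loss, dlogits = _nn.sigmoid_bce_with_logits(logits,
                                                          np.zeros(m))
            dxf = disc.backward(dlogits)
            anchor_idx = [by_label[d][rng.integers(len(by_label[d]))]
                          for d in yr.argmax(1)]
            resid = xf - windows[anchor_idx]
            dxf = dxf + config.mse_anchor * 2.0 * resid / xf.size
            g_loss += config.mse_anchor * float((resid ** 2).mean())
            gen.backward(dxf)
            opt_g.step(_clipped(gen.grads, config.clip_norm))
            for e, p in zip(ema, gen.params):
                e *= config.ema_decay
                e += (1.0 - config.ema_decay) * p
            d_losses.append(d_loss * m)
            g_losses.append(g_loss * m)
        history["d_loss"].append(float(np.sum(d_losses) / n))
        history["g_loss"].append(float(np.sum(g_losses) / n))
        current = [p.copy() for p in gen.params]
        for p, e in zip(gen.params, ema):
            p[...] = e
        fake_eval = gen.forward(eval_z, labels, training=False)
        history["mean_discrepancy"].append(
            mean_channel_discrepancy(fake_eval, windows, labels, labels))
        for p, c in zip(gen.params, current):
            p[...] = c
    # hand back the smoothed (EMA) generator for sampling
    for p, e in zip(gen.params, ema):
        p[...] = e
    return gen, disc, history


def generate_window(generator: Generator, label, seed: int = 0,
                    count: int = 1, latents=None) -> np.ndarray:
    """Sample ``count`` windows conditioned on an intensity-domain label.

    Latents are seeded standard-normal draws unless supplied explicitly
    (user latents must have length 50).  Returns (count, 40, 7) in [0, 1];
    channel order VO2, VCO2, PetO2, PetCO2, VE, Rf, HR.
    """
    onehot = _one_hot(label)
    if latents is None:
        rng = np.random.default_rng(seed)
        latents = rng.standard_normal((count, LATENT_DIM))
    else:
        latents = np.asarray(latents, float)
        if latents.ndim == 1:
            latents = latents[None]
        if latents.shape[1] != LATENT_DIM:
            raise ValidationError(
                f"user latents must have length {LATENT_DIM}")
        count = latents.shape[0]
    labels = np.tile(onehot, (count, 1))
    return generator.forward(latents, labels, training=False)


def denormalize_window(window: np.ndarray, stats: dict) -> np.ndarray:
    """Map a normalized (40, 7) window back to absolute units.

    ``stats`` maps each of the seven channel names to (min, max), e.g.
    the ``mean_min``/``mean_max`` summary of
    :func:`cpetml.simulate.population_stats`.
    """
    w = np.asarray(window, float)
    out = np.empty_like(w)
    for c, ch in enumerate(GAN_CHANNELS):
        if ch not in stats:
            raise CPETError(f"stats missing channel: {ch}")
        lo, hi = stats[ch]
        if hi <= lo:
            raise CPETError(f"stats for {ch} must have max > min")
        out[..., c] = lo + w[..., c] * (hi - lo)
    return out


def generated_to_breath(window_abs: np.ndarray):
    """Resample an absolute-unit generated window to the breath domain,
    using its own generated Rf channel to place the breathing events."""
    w = np.asarray(window_abs, float)
    if w.shape != (WINDOW, N_CHANNELS):
        raise ValidationError("expected a single (40, 7) window")
    df = pd.DataFrame({"t": np.arange(float(WINDOW))})
    for c, ch in enumerate(GAN_CHANNELS):
        df[ch] = w[:, c]
    return to_breath_domain(SecondTable(df))


def prepare_gan_windows(sec_tables, ground_truths, stride_s: int = 5):
    """Real training windows for the cGAN from simulated second tables.

    Normalizes the seven GAN channels per test, extracts rolling windows,
    and labels each by the domain of its center second.  Returns
    ``(windows (n, 40, 7), onehot (n, 3))``.
    """
    all_w, all_y = [], []
    for st, gt in zip(sec_tables, ground_truths):
        nt = normalize_minmax(st, GAN_CHANNELS)
        tensor, starts = window_tensor(nt, width_s=WINDOW, stride_s=stride_s)
        centers = starts + (WINDOW - 1) / 2.0
        lab = np.array([gt.domain_at(c) for c in centers])
        all_w.append(tensor)
        all_y.append(np.eye(3)[lab])
    return np.concatenate(all_w), np.concatenate(all_y)


def mean_channel_discrepancy(generated, real, gen_labels=None,
                             real_labels=None) -> float:
    """Mean absolute difference between per-channel time-means of
    generated vs real windows, label-matched when labels are given."""
    g = np.asarray(generated, float)
    r = np.asarray(real, float)
    if gen_labels is None or real_labels is None:
        return float(np.abs(g.mean(axis=(0, 1)) - r.mean(axis=(0, 1))).mean())
    gl = np.asarray(gen_labels).argmax(axis=1)
    rl = np.asarray(real_labels).argmax(axis=1)
    diffs = []
    for d in range(N_LABELS):
        if (gl == d).any() and (rl == d).any():
            diffs.append(np.abs(g[gl == d].mean(axis=(0, 1))
                                - r[rl == d].mean(axis=(0, 1))))
    if not diffs:
        raise InsufficientDataError("no common labels between sets")
    return float(np.mean(diffs))


def save_gan(generator: Generator, discriminator: Discriminator, path):
    arrays = {f"g{i}": p for i, p in enumerate(generator.params)}
    arrays.update({f"d{i}": p for i, p in enumerate(discriminator.params)})
    arrays["config"] = np.frombuffer(
        json.dumps(asdict(generator.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_gan(path):
    data = np.load(path)
    config = GanConfig(**json.loads(bytes(data["config"]).decode()))
    gen = Generator(config)
    disc = Discriminator(config)
    for i, p in enumerate(gen.params):
        p[...] = data[f"g{i}"]
    for i, p in enumerate(disc.params):
        p[...] = data[f"d{i}"]
    return gen, disc
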