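"""Shapley-value attribution of the domain classifier's decisions.

Each of the six input channels is a player in a cooperative game.  A
coalition S is evaluated by interventional replacement against a
background set: channels in S keep the explained window's values, the
remaining channels are taken from each background window in turn, and the
coalition's worth is the mean model output over those composites.  The
Shapley value of a channel is then its exactly-weighted average marginal
contribution over all 2^5 coalitions of the other channels — feasible
because the players are the 6 channels, not individual time samples.

The base value of each output domain is the average model output over the
background set, so the efficiency axiom reads: the six channel
attributions sum to (model output on this window) - (base value).  A
positive value pushes the model toward the corresponding intensity
domain, a negative one pushes it away.

A permutation-sampling estimator is provided for speed; with all
orderings enumerated it reproduces the exact values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpetio import NormalizedTable, REGRESSOR_CHANNELS, window_tensor
from .errors import CPETError, InsufficientDataError

__all__ = [
    "Attribution", "TestAttribution", "shapley_exact", "shapley_sampling",
    "explain_test", "coalition_values",
]


@dataclass
class Attribution:
    """Shapley values for one window: ``phi[channel, domain]`` plus the
    per-domain base values and the window's start time."""

    phi: np.ndarray            # (n_channels, n_domains)
    base: np.ndarray           # (n_domains,)
    start_s: float
    channels: tuple = field(default=REGRESSOR_CHANNELS)


@dataclass
class TestAttribution:
    """Time-resolved attributions for a whole test."""

    phi: np.ndarray            # (n_windows, n_channels, n_domains)
    base: np.ndarray           # (n_domains,)
    starts: np.ndarray
    channels: tuple = field(default=REGRESSOR_CHANNELS)

    def __len__(self):
        return self.phi.shape[0]

    def __getitem__(self, k: int) -> Attribution:
        return Attribution(self.phi[k], self.base, float(self.starts[k]),
                           self.channels)

    def to_frame(self) -> pd.DataFrame:
        """Long format: window_start_s, channel, domain, phi, base."""
        domains = ("moderate", "heavy", "severe")
        rows = []
        for k in range(len(self)):
            for c, ch in enumerate(self.channels):
                for d, dom in enumerate(domains):
                    rows.append((float(self.starts[k]), ch, dom,
                                 float(self.phi[k, c, d]),
                                 float(self.base[d])))
        return pd.DataFrame(
            rows, columns=["window_start_s", "channel", "domain",
                           "phi", "base"])

    def mean_abs_by_channel(self) -> pd.DataFrame:
        """Per-domain mean |phi| per channel — the global importance ranking."""
        m = np.abs(self.phi).mean(axis=0)  # (channels, domains)
        return pd.DataFrame(m, index=list(self.channels),
                            columns=["moderate", "heavy", "severe"])


def _as_background(background) -> np.ndarray:
    bg = np.asarray(background, float)
    if bg.ndim == 2:
        bg = bg[None]
    if bg.shape[0] == 0:
        raise InsufficientDataError("background set must be nonempty")
    return bg


def coalition_values(value_fn, window, background) -> dict:
    """Worth of every coalition of channels, for all model outputs at once.

    Returns ``{frozenset(channel indices): (n_outputs,) array}`` where the
    worth is the mean of ``value_fn`` over background-composited windows.
    ``value_fn`` must accept a batch ``(n, T, C)`` and return ``(n, K)``.
    """
    x = np.asarray(window, float)
    bg = _as_background(background)
    n_ch = x.shape[-1]
    n_bg = bg.shape[0]
    coalitions = [frozenset(s)
                  for r in range(n_ch + 1)
                  for s in itertools.combinations(range(n_ch), r)]
    batch = np.empty((len(coalitions), n_bg) + bg.shape[1:], float)
    for i, S in enumerate(coalitions):
        comp = bg.copy()
        if S:
            comp[:, :, sorted(S)] = x[:, sorted(S)]
        batch[i] = comp
    flat = batch.reshape((-1,) + bg.shape[1:])
    out = np.asarray(value_fn(flat), float)
    out = out.reshape(len(coalitions), n_bg, -1).mean(axis=1)
    return {S: out[i] for i, S in enumerate(coalitions)}


def _exact_from_values(values: dict, n_ch: int) -> np.ndarray:
    """Shapley values (n_ch, n_outputs) from precomputed coalition worths."""
    n_out = len(next(iter(values.values())))
    phi = np.zeros((n_ch, n_out))
    fact = [math.factorial(k) for k in range(n_ch + 1)]
    denom = fact[n_ch]
    others = list(range(n_ch))
    for c in range(n_ch):
        rest = [o for o in others if o != c]
        for r in range(n_ch):
            w = fact[r] * fact[n_ch - r - 1] / denom
            for S in itertools.combinations(rest, r):
                S = frozenset(S)
                phi[c] += w * (values[S | {c}] - values[S])
    return phi


def shapley_exact(value_fn, window, background, domain: int | None = None):
    """Exact Shapley attribution by full coalition enumeration.

    ``value_fn(batch) -> (n, K)`` model outputs; channels are the players.
    Returns ``(phi, base)``: with ``domain`` given, ``phi`` is the
    (n_channels,) attribution of that output and ``base`` its scalar base
    value; otherwise all outputs at once, shapes (n_channels, K) and (K,).
    """
    x = np.asarray(window, float)
    values = coalition_values(value_fn, x, background)
    phi = _exact_from_values(values, x.shape[-1])
    base = values[frozenset()]
    if domain is None:
        return phi, base
    return phi[:, domain], float(base[domain])


def shapley_sampling(value_fn, window, background, domain: int | None = None,
                     n_permutations: int = 100, seed: int = 0,
                     all_permutations: bool = False):
    """Permutation-sampling approximation of the Shapley values.

    Averages the marginal contribution of each channel over seeded random
    channel orderings (coalition worths are memoised, so repeated prefixes
    cost nothing).  With ``all_permutations=True`` every ordering is
    enumerated exactly once, which reproduces :func:`shapley_exact`.
    """
    if not all_permutations and n_permutations < 1:
        raise CPETError("n_permutations must be >= 1")
    x = np.asarray(window, float)
    bg = _as_background(background)
    n_ch = x.shape[-1]

    cache: dict = {}

    def worth(S: frozenset) -> np.ndarray:
        if S not in cache:
            comp = bg.copy()
            if S:
                comp[:, :, sorted(S)] = x[:, sorted(S)]
            cache[S] = np.asarray(value_fn(comp), float).mean(axis=0)
        return cache[S]

    if all_permutations:
        perms = itertools.permutations(range(n_ch))
        n_used = math.factorial(n_ch)
    else:
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(n_ch)) for _ in range(n_permutations)]
        n_used = n_permutations

    base = worth(frozenset())
    phi = np.zeros((n_ch, len(base)))
    for perm in perms:
        S = frozenset()
        v_prev = base
        for c in perm:
            S = S | {c}
            v = worth(S)
            phi[c] += v - v_prev
            v_prev = v
    phi /= n_used
    if domain is None:
        return phi, base
    return phi[:, domain], float(base[domain])


def explain_test(model, nt: NormalizedTable, background,
                 method: str = "exact", n_permutations: int = 100,
                 seed: int = 0, stride_s: int = 1) -> TestAttribution:
    """Time-resolved Shapley attribution over a whole test.

    One Attribution per rolling-window position: ``(T - 39) x 6 x 3``
    values (for stride 1) plus the three base values.  ``background`` is a
    (B, 40, 6) window set, typically drawn from the training corpus.
    """
    cfg = model.config
    tensor, starts = window_tensor(nt, width_s=cfg.window, stride_s=stride_s)
    bg = _as_background(background)
    value_fn = model.predict_proba
    phis = []
    base = None
    for k in range(tensor.shape[0]):
        if method == "exact":
            phi, base = shapley_exact(value_fn, tensor[k], bg)
        elif method == "sampling":
            phi, base = shapley_sampling(
                value_fn, tensor[k], bg,
                n_permutations=n_permutations, seed=seed + k)
        else:
            raise CPETError(f"unknown method: {method}")
        phis.append(phi)
    return TestAttribution(np.stack(phis), np.asarray(base, float), starts,
                           tuple(nt.channels))
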