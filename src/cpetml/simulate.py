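"""Parametric physiological CPET simulator with known ventilatory thresholds.

Generates monotone incremental (ramp) tests whose channel trajectories
follow the canonical slope-sign patterns of the three exercise-intensity
domains:

* moderate: VO2, VCO2, VE increase; ventilatory equivalents (VE/VO2,
  VE/VCO2) decrease; PetO2 falls, PetCO2 rises;
* heavy (above VT1, the gas-exchange/lactate threshold): VE/VO2 and PetO2
  turn upward, VE/VCO2 and PetCO2 plateau (isocapnic buffering), VE and
  VCO2 accelerate relative to VO2;
* severe (above VT2, the respiratory compensation point): hyperventilation
  adds a further VE rise, VE/VCO2 turns upward and PetCO2 falls.

The construction is deliberately piecewise-linear so the breakpoints sit
exactly at the configured VT1/VT2: VO2 ramps linearly from baseline, VCO2
is piecewise-linear in VO2 (V-slope geometry, slope ~0.9 below VT1 and
~1.15 above), VE is affine in VCO2 with an extra linear hyperventilation
term above VT2, and the end-tidal pressures are piecewise-linear in time.
Gaussian noise scaled by a single ``noise_level`` knob is added per
channel, and the 1-Hz record is resampled to the breath domain using the
simulated respiratory frequency.  Ground-truth threshold VO2 values are
read from the noise-free ramp, so thresholds are expressed in mlO2/min as
well as in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpetio import BreathTable, SecondTable, derive_ratios
from .errors import ConfigError, DegenerateValueError, InsufficientDataError

__all__ = [
    "SimConfig", "GroundTruth", "simulate_cpet", "noise_free_second_table",
    "to_breath_domain", "population_stats", "segment_slopes", "sample_config",
]

# fixed physiological constants of the generative construction
_RER_BASELINE = 0.85        # VCO2/VO2 at rest
_VSLOPE_BELOW = 0.90        # dVCO2/dVO2 below VT1
_VSLOPE_ABOVE = 1.15        # dVCO2/dVO2 above VT1
_VE_INTERCEPT = 6.0         # l/min, dead-space intercept of VE vs VCO2
_VE_SLOPE = 24.0            # l VE per l VCO2
_HYPERVENT_RATE = 0.09      # l/min of extra VE per s above VT2
_PETO2_SLOPES = (-0.018, 0.022, 0.050)   # mmHg/s per domain
_PETCO2_SLOPES = (0.015, 0.0, -0.050)    # mmHg/s per domain
_PETO2_START = 100.0        # mmHg
_PETCO2_START = 36.0        # mmHg
_NOISE_FRACTION = 0.02      # noise SD = noise_level * 2% of channel range


@dataclass
class SimConfig:
    """Settings of one simulated ramp test.

    Defaults describe a moderately fit adult on a 12-min cycling ramp:
    rest VO2 0.5 l/min rising to a 3.0 l/min peak, VT1 at ~41 % and VT2 at
    ~76 % of the ramp.  ``noise_level`` is a unitless multiplier of the
    per-channel noise SD (2 % of the channel's dynamic range at level 1).
    ``kinetics_tau_s`` optionally applies a first-order lag to the VO2
    channel; it defaults to 0 so the emitted VO2 matches the ground-truth
    ramp exactly.
    """

    duration_s: float = 720.0
    ramp_start_s: float = 60.0
    VO2_baseline: float = 500.0
    VO2_max: float = 3000.0
    VT1_s: float = 330.0
    VT2_s: float = 540.0
    noise_level: float = 1.0
    Rf_range: tuple = (14.0, 45.0)
    HR_range: tuple = (75.0, 185.0)
    kinetics_tau_s: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.ramp_start_s < self.VT1_s < self.VT2_s
                < self.duration_s):
            raise ConfigError(
                "need 0 < ramp_start_s < VT1_s < VT2_s < duration_s, got "
                f"{self.ramp_start_s}, {self.VT1_s}, {self.VT2_s}, "
                f"{self.duration_s}")
        if self.VO2_max <= self.VO2_baseline:
            raise ConfigError("VO2_max must exceed VO2_baseline")
        if self.noise_level < 0:
            raise ConfigError("noise_level must be >= 0")
        if self.kinetics_tau_s < 0:
            raise ConfigError("kinetics_tau_s must be >= 0")

    @property
    def ramp_slope(self) -> float:
        """mlO2/min of VO2 gained per second of ramp."""
        return (self.VO2_max - self.VO2_baseline) / (self.duration_s
                                                     - self.ramp_start_s)


@dataclass
class GroundTruth:
    """Known thresholds and per-second domain labels of a simulated test."""

    VT1_s: float
    VT2_s: float
    VT1_VO2: float
    VT2_VO2: float
    t: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)  # 0=moderate, 1=heavy, 2=severe

    def domain_at(self, time_s: float) -> int:
        if time_s < self.VT1_s:
            return 0
        if time_s < self.VT2_s:
            return 1
        return 2

    def as_labels_dict(self) -> dict:
        return {"VT1_s": self.VT1_s, "VT2_s": self.VT2_s,
                "VT1_VO2": self.VT1_VO2, "VT2_VO2": self.VT2_VO2}


def _ramp(cfg: SimConfig, t: np.ndarray) -> np.ndarray:
    """Noise-free VO2 demand ramp (no kinetics lag)."""
    return cfg.VO2_baseline + cfg.ramp_slope * np.maximum(
        t - cfg.ramp_start_s, 0.0)


def _noise_free_channels(cfg: SimConfig):
    t = np.arange(0.0, cfg.duration_s + 1.0)
    ramp = _ramp(cfg, t)
    vt1_vo2 = float(_ramp(cfg, np.array([cfg.VT1_s]))[0])

    vo2 = ramp
    if cfg.kinetics_tau_s > 0:
        alpha = 1.0 - np.exp(-1.0 / cfg.kinetics_tau_s)
        vo2 = np.empty_like(ramp)
        vo2[0] = ramp[0]
        for i in range(1, len(ramp)):
            vo2[i] = vo2[i - 1] + alpha * (ramp[i] - vo2[i - 1])

    # V-slope geometry in the (ramp VO2, VCO2) plane: breakpoint at VT1
    vco2 = (_RER_BASELINE * cfg.VO2_baseline
            + _VSLOPE_BELOW * np.minimum(ramp - cfg.VO2_baseline,
                                         vt1_vo2 - cfg.VO2_baseline)
            + _VSLOPE_ABOVE * np.maximum(ramp - vt1_vo2, 0.0))

    # VE affine in VCO2 (positive intercept makes VE/VCO2 fall through the
    # moderate domain and flatten in the heavy one); hyperventilation above VT2
    ve = (_VE_INTERCEPT + _VE_SLOPE * vco2 / 1000.0
          + _HYPERVENT_RATE * np.maximum(t - cfg.VT2_s, 0.0))

    seg = np.searchsorted([cfg.VT1_s, cfg.VT2_s], t, side="right")
    peto2 = _piecewise_linear(t, cfg, _PETO2_START, _PETO2_SLOPES)
    petco2 = _piecewise_linear(t, cfg, _PETCO2_START, _PETCO2_SLOPES)

    rf = np.interp(t, [0.0, cfg.duration_s], list(cfg.Rf_range))
    hr = np.interp(t, [0.0, cfg.duration_s], list(cfg.HR_range))

    channels = {"t": t, "VO2": vo2, "VCO2": vco2, "VE": ve, "Rf": rf,
                "PetO2": peto2, "PetCO2": petco2, "HR": hr}
    return channels, seg


def _piecewise_linear(t, cfg: SimConfig, start: float, slopes):
    """Continuous piecewise-linear track with kinks at VT1 and VT2."""
    s1, s2, s3 = slopes
    seg1 = np.minimum(t, cfg.VT1_s)
    seg2 = np.clip(t - cfg.VT1_s, 0.0, cfg.VT2_s - cfg.VT1_s)
    seg3 = np.maximum(t - cfg.VT2_s, 0.0)
    return start + s1 * seg1 + s2 * seg2 + s3 * seg3


def _ground_truth(cfg: SimConfig, t: np.ndarray, seg: np.ndarray
                  ) -> GroundTruth:
    return GroundTruth(
        VT1_s=cfg.VT1_s, VT2_s=cfg.VT2_s,
        VT1_VO2=float(_ramp(cfg, np.array([cfg.VT1_s]))[0]),
        VT2_VO2=float(_ramp(cfg, np.array([cfg.VT2_s]))[0]),
        t=t.copy(), labels=seg.copy())


def noise_free_second_table(cfg: SimConfig) -> tuple[SecondTable, GroundTruth]:
    """The deterministic 1-Hz trajectories underlying :func:`simulate_cpet`."""
    channels, seg = _noise_free_channels(cfg)
    st = SecondTable(pd.DataFrame(channels))
    return st, _ground_truth(cfg, channels["t"], seg)


# physical floors applied after noise injection
_FLOORS = {"VO2": 1.0, "VCO2": 1.0, "VE": 0.1, "Rf": 1.0,
           "PetO2": 1.0, "PetCO2": 1.0, "HR": 30.0}


def simulate_cpet(cfg: SimConfig) -> tuple[BreathTable, GroundTruth]:
    """Simulate one incremental CPET.

    Returns the breath-by-breath record (noise added on the 1-Hz grid,
    then resampled at breath times derived from the simulated Rf) and the
    ground truth read from the noise-free trajectories.
    """
    channels, seg = _noise_free_channels(cfg)
    rng = np.random.default_rng(cfg.seed)
    noisy = {"t": channels["t"]}
    for ch, x in channels.items():
        if ch == "t":
            continue
        scale = _NOISE_FRACTION * float(np.ptp(x))
        if scale == 0.0:
            scale = _NOISE_FRACTION * abs(float(np.mean(x)))
        y = x + cfg.noise_level * scale * rng.standard_normal(len(x))
        noisy[ch] = np.maximum(y, _FLOORS[ch])
    st = SecondTable(pd.DataFrame(noisy))
    return to_breath_domain(st), _ground_truth(cfg, channels["t"], seg)


def to_breath_domain(st: SecondTable) -> BreathTable:
    """Resample a 1-Hz record at breath times implied by its Rf channel.

    Breath times are accumulated from the start of the grid: each
    inter-breath interval is 60/Rf evaluated at the current breath time,
    i.e. the running solution of dt = 60/Rf(t).
    """
    if "Rf" not in st.data.columns:
        raise DegenerateValueError("Rf channel required for breath sampling")
    rf = st.channel("Rf")
    if np.any(rf <= 0):
        raise DegenerateValueError("Rf must be positive everywhere")
    t = st.t
    t0, t_end = t[0], t[-1]
    breath_times = []
    tb = t0
    while True:
        tb = tb + 60.0 / float(np.interp(tb, t, rf))
        if tb > t_end:
            break
        breath_times.append(tb)
    if len(breath_times) < 2:
        raise InsufficientDataError("record too short for breath sampling")
    bt_arr = np.asarray(breath_times)
    out = {"t": bt_arr}
    for ch in st.channels:
        out[ch] = np.interp(bt_arr, t, st.channel(ch))
    return BreathTable(pd.DataFrame(out))


def population_stats(tables) -> dict:
    """Per-channel min/max distribution over a collection of tests.

    Returns ``{channel: {"mins": [...], "maxes": [...], "mean_min": m,
    "mean_max": M}}`` — the corpus summary used to denormalize generated
    windows back to absolute units.
    """
    tables = list(tables)
    if not tables:
        raise InsufficientDataError("population_stats needs >= 1 table")
    channels = [c for c in tables[0].channels]
    stats = {}
    for ch in channels:
        mins = [float(np.min(tb.channel(ch))) for tb in tables]
        maxes = [float(np.max(tb.channel(ch))) for tb in tables]
        stats[ch] = {"mins": mins, "maxes": maxes,
                     "mean_min": float(np.mean(mins)),
                     "mean_max": float(np.mean(maxes))}
    return stats


def segment_slopes(st: SecondTable, gt: GroundTruth) -> dict:
    """Least-squares slope of every channel over each intensity domain.

    Used to check the slope-sign contract of the three domain patterns.
    Requires a table whose time axis matches the ground-truth label grid.
    """
    st = derive_ratios(st)
    t = st.t
    labels = np.array([gt.domain_at(x) for x in t])
    slopes = {}
    for ch in st.channels:
        y = st.channel(ch)
        per_domain = []
        for d in range(3):
            mask = labels == d
            if mask.sum() < 2:
                per_domain.append(np.nan)
                continue
            per_domain.append(float(np.polyfit(t[mask], y[mask], 1)[0]))
        slopes[ch] = tuple(per_domain)
    return slopes


def sample_config(rng: np.random.Generator, noise_level: float = 1.0,
                  kinetics_tau_s: float = 0.0) -> SimConfig:
    """Draw a random but physiologic test configuration.

    Emulates corpus heterogeneity: peak aerobic power, test duration and
    threshold placement vary across subjects; thresholds are placed at
    35-50 % (VT1) and 65-85 % (VT2) of the ramp.
    """
    duration = float(rng.uniform(600.0, 840.0))
    ramp_start = float(rng.uniform(45.0, 75.0))
    vt1 = ramp_start + float(rng.uniform(0.35, 0.50)) * (duration - ramp_start)
    vt2 = ramp_start + float(rng.uniform(0.65, 0.85)) * (duration - ramp_start)
    return SimConfig(
        duration_s=duration,
        ramp_start_s=ramp_start,
        VO2_baseline=float(rng.uniform(400.0, 600.0)),
        VO2_max=float(rng.uniform(2200.0, 3800.0)),
        VT1_s=vt1,
        VT2_s=vt2,
        noise_level=noise_level,
        Rf_range=(float(rng.uniform(12.0, 18.0)),
                  float(rng.uniform(38.0, 55.0))),
        HR_range=(float(rng.uniform(60.0, 90.0)),
                  float(rng.uniform(170.0, 200.0))),
        kinetics_tau_s=kinetics_tau_s,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )
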