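"""CPET data model, file I/O, and the shared preprocessing chain.

A cardiopulmonary exercise test (CPET) is recorded breath by breath:
oxygen uptake VO2 (ml/min), carbon-dioxide output VCO2 (ml/min), minute
ventilation VE (l/min), respiratory frequency Rf (breaths/min), end-tidal
pressures PetO2/PetCO2 (mmHg) and, optionally, heart rate and workload.
Every model in this package consumes the same preprocessed representation:
the breath-domain record is linearly interpolated onto a uniform 1-s grid,
ventilatory equivalents (VE/VO2, VE/VCO2) and the respiratory exchange
ratio (VCO2/VO2) are derived, the six classifier channels are min-max
normalized per test, and 40-s rolling windows are extracted.

The canonical on-disk formats are a plain CSV with header
``t,VO2,VCO2,VE,Rf,PetO2,PetCO2,HR,load`` (optional ``# domain=`` comment
line) and a label JSON with the ventilatory-threshold annotations.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (DegenerateValueError, FormatError, InsufficientDataError,
                     TooShortTestError, ValidationError)

logger = logging.getLogger(__name__)

#: Channels every CPET record must provide (breath or second domain).
MANDATORY_CHANNELS = ("VO2", "VCO2", "VE", "Rf", "PetO2", "PetCO2")
#: Optional metadata channels, carried through but never fed to the models.
OPTIONAL_CHANNELS = ("HR", "load")
#: The six input channels of the intensity-domain classifier, in order.
REGRESSOR_CHANNELS = ("RER", "VE", "PetO2", "PetCO2", "VEVO2", "VEVCO2")
#: The seven channels synthesised by the conditional GAN, in order.
GAN_CHANNELS = ("VO2", "VCO2", "PetO2", "PetCO2", "VE", "Rf", "HR")
#: Derived ratio channels added by :func:`derive_ratios`.
DERIVED_CHANNELS = ("VEVO2", "VEVCO2", "RER")

#: Ordered exercise-intensity domains of an incremental test.
DOMAINS = ("moderate", "heavy", "severe")

_CSV_COLUMNS = ("t", "VO2", "VCO2", "VE", "Rf", "PetO2", "PetCO2", "HR", "load")


def _validate_record(df: pd.DataFrame) -> None:
    for col in ("t",) + MANDATORY_CHANNELS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col}")
    t = df["t"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"time not strictly increasing at row {bad[0] + 2}")
    for col in MANDATORY_CHANNELS:
        v = df[col].to_numpy(float)
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"non-finite values in column {col}")
        if np.any(v < 0):
            raise ValidationError(f"negative values in column {col}")


@dataclass
class BreathTable:
    """Breath-by-breath CPET record; ``t`` strictly increasing, in seconds."""

    data: pd.DataFrame

    def __post_init__(self):
        _validate_record(self.data)

    def __len__(self):
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(float)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(float)

    @property
    def channels(self):
        return [c for c in self.data.columns if c != "t"]


@dataclass
class SecondTable:
    """CPET record on a uniform 1-s grid, possibly with derived ratios."""

    data: pd.DataFrame

    def __post_init__(self):
        t = self.data["t"].to_numpy(float)
        if len(t) > 1 and not np.allclose(np.diff(t), 1.0):
            raise ValidationError("SecondTable grid step must be exactly 1 s")

    def __len__(self):
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(float)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(float)

    @property
    def channels(self):
        return [c for c in self.data.columns if c != "t"]

    @property
    def duration_s(self) -> float:
        t = self.t
        return float(t[-1] - t[0])


@dataclass
class NormalizedTable:
    """Per-test min-max rescaled channels plus the stats to undo the map."""

    data: pd.DataFrame
    stats: dict  # channel -> (min, max) observed in this test

    def __len__(self):
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy(float)

    @property
    def channels(self):
        return [c for c in self.data.columns if c != "t"]

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(float)

    def denormalize(self) -> pd.DataFrame:
        """Invert the per-channel affine map using the stored stats."""
        out = self.data.copy()
        for ch, (lo, hi) in self.stats.items():
            out[ch] = lo + out[ch] * (hi - lo)
        return out


@dataclass
class Window:
    """One rolling-window slice: ``values`` is (width, n_channels) in [0, 1]."""

    values: np.ndarray
    start_s: float
    channels: tuple = field(default=REGRESSOR_CHANNELS)


# ---------------------------------------------------------------------------
# file I/O

def read_cpet_csv(path) -> BreathTable:
    """Read a canonical CPET CSV into a validated :class:`BreathTable`.

    Lines starting with ``#`` are metadata comments (``# domain=second``
    marks an already-interpolated record; the returned table is the same
    either way, the flag is kept in ``table.data.attrs['domain']``).
    """
    domain = "breath"
    with open(path, "r", encoding="utf-8") as fh:
        header_comments = []
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            header_comments.append(line.strip("#\n ").strip())
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    for c in header_comments:
        if c.startswith("domain="):
            domain = c.split("=", 1)[1].strip()
    table = BreathTable(df)
    table.data.attrs["domain"] = domain
    return table


def write_cpet_csv(table, path, domain: str | None = None) -> None:
    """Write a breath- or second-domain table as a canonical CPET CSV."""
    df = table.data
    if domain is None:
        domain = df.attrs.get("domain", "breath")
        if isinstance(table, SecondTable):
            domain = "second"
    cols = [c for c in _CSV_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# domain={domain}\n")
        df[cols].to_csv(fh, index=False, float_format="%.10g")


def read_labels(path) -> dict:
    """Read a threshold-label JSON (times in s, VO2 in ml/min, nullable)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    keys = ("VT1_s", "VT2_s", "VT1_VO2", "VT2_VO2")
    for k in keys:
        if k not in raw:
            raise FormatError(f"label file missing key: {k}")
    return {k: (None if raw[k] is None else float(raw[k])) for k in keys}


def write_labels(labels: dict, path) -> None:
    keys = ("VT1_s", "VT2_s", "VT1_VO2", "VT2_VO2")
    out = {k: labels.get(k) for k in keys}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# preprocessing chain

def interpolate_to_seconds(bt: BreathTable) -> SecondTable:
    """Linearly interpolate a breath-domain record onto integer seconds.

    The grid runs from ``ceil(t_first)`` to ``floor(t_last)`` inclusive;
    each channel is interpolated between its bracketing breaths.
    """
    if len(bt) < 2:
        raise InsufficientDataError(
            "need at least 2 breaths to interpolate")
    t = bt.t
    t0, t1 = math.ceil(t[0]), math.floor(t[-1])
    if t1 < t0 or t[-1] - t[0] < 1.0:
        raise InsufficientDataError("test span shorter than 1 s")
    grid = np.arange(t0, t1 + 1, dtype=float)
    out = {"t": grid}
    for ch in bt.channels:
        out[ch] = np.interp(grid, t, bt.channel(ch))
    return SecondTable(pd.DataFrame(out))


def derive_ratios(st: SecondTable) -> SecondTable:
    """Add ventilatory equivalents and RER to a second-domain table.

    VEVO2 = VE[l/min] / (VO2[ml/min]/1000), VEVCO2 likewise, RER =
    VCO2/VO2.  Units: VE is l/min while the gas channels are ml/min, hence
    the factor 1000.  Idempotent.
    """
    df = st.data.copy()
    vo2 = df["VO2"].to_numpy(float)
    vco2 = df["VCO2"].to_numpy(float)
    for name, v in (("VO2", vo2), ("VCO2", vco2)):
        bad = np.nonzero(v <= 0)[0]
        if bad.size:
            t_bad = df["t"].iloc[bad[0]]
            raise DegenerateValueError(
                f"{name} <= 0 at t={t_bad:g} s; ratios undefined")
    ve = df["VE"].to_numpy(float)
    df["VEVO2"] = ve / (vo2 / 1000.0)
    df["VEVCO2"] = ve / (vco2 / 1000.0)
    df["RER"] = vco2 / vo2
    return SecondTable(df)


def normalize_minmax(st: SecondTable, channels=REGRESSOR_CHANNELS
                     ) -> NormalizedTable:
    """Rescale each requested channel to [0, 1] with this test's min/max.

    A constant channel carries no within-test information; it maps to 0.5
    everywhere (with a logged warning) so downstream tensors stay finite.
    """
    df = pd.DataFrame({"t": st.t})
    stats = {}
    for ch in channels:
        if ch not in st.data.columns:
            raise FormatError(f"channel not present: {ch}")
        x = st.channel(ch)
        if not np.all(np.isfinite(x)):
            raise ValidationError(f"non-finite values in channel {ch}")
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            logger.warning(
                "channel %s is constant (%.6g); normalizing to 0.5", ch, lo)
            df[ch] = np.full(len(x), 0.5)
        else:
            df[ch] = (x - lo) / (hi - lo)
        stats[ch] = (lo, hi)
    return NormalizedTable(df, stats)


def extract_windows(nt: NormalizedTable, width_s: int = 40,
                    stride_s: int = 1) -> list[Window]:
    """Cut the normalized table into rolling windows of ``width_s`` rows."""
    tensor, starts = window_tensor(nt, width_s=width_s, stride_s=stride_s)
    ch = tuple(nt.channels)
    return [Window(tensor[i], float(starts[i]), ch)
            for i in range(tensor.shape[0])]


def window_tensor(nt: NormalizedTable, width_s: int = 40, stride_s: int = 1):
    """Stacked rolling windows as a (n, width, channels) array + start times.

    Vectorised companion of :func:`extract_windows` used on the model path.
    """
    arr = nt.data[list(nt.channels)].to_numpy(float)
    t = nt.t
    n_rows = arr.shape[0]
    if n_rows < width_s:
        raise TooShortTestError(
            f"test has {n_rows} s but a window needs {width_s} s")
    n_win = (n_rows - width_s) // stride_s + 1
    idx = np.arange(width_s)[None, :] + stride_s * np.arange(n_win)[:, None]
    return arr[idx], t[::stride_s][:n_win].copy()
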