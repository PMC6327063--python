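"""EEG sub-band power analysis synchronized to imaging epochs.

Raw EEG (natively 12207 Hz) is downsampled by 40 (anti-alias low-pass then
decimation), band-pass filtered into the five standard bands — delta
(0.5-4 Hz), theta (4-8), alpha (8-13), beta (13-30), gamma (30-100) — with
a 60 Hz notch ahead of the gamma filter, and the power of each band is the
filtered-signal variance within non-overlapping 1-minute epochs, lightly
smoothed by a 3-sample median across epochs.  Total power is the sum over
the five bands and fractional powers (the "-f" convention) are each band's
share of that total, so they sum to one per epoch by construction.
Band-power epochs can then be correlated against imaging-derived series
(e.g. per-epoch CBF) aligned through the hardware sync channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "EEGRecord",
    "BandTable",
    "BandPowerSeries",
    "STANDARD_BANDS",
    "downsample",
    "band_power",
    "sync_correlate",
]

STANDARD_BANDS = [
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 100.0),
]


@dataclass
class EEGRecord:
    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.size < 2:
            raise ValueError("record needs at least 2 samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass
class BandTable:
    """Ordered, non-overlapping (name, low_hz, high_hz) band definitions."""

    bands: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for name, lo, hi in self.bands:
            if not 0 < lo < hi:
                raise ValueError(f"band {name}: need 0 < low < high")
            if lo < prev_hi:
                raise ValueError(f"band {name} overlaps the previous band")
            prev_hi = hi

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]


@dataclass
class BandPowerSeries:
    """Per-epoch band powers (variance units), fractions and totals."""

    power: pd.DataFrame  # epochs x bands
    fraction: pd.DataFrame  # epochs x bands, rows sum to 1
    total: np.ndarray  # per-epoch total power
    epoch_s: float


def downsample(rec: EEGRecord, factor: int = 40) -> EEGRecord:
    """Anti-aliased decimation: low-pass at 0.8x the new Nyquist, keep every
    ``factor``-th sample."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return EEGRecord(rec.samples.copy(), rec.fs_hz)
    if rec.samples.size // factor < 2:
        raise ValueError("decimation would leave fewer than 2 samples")
    new_fs = rec.fs_hz / factor
    sos = signal.butter(8, 0.8 * new_fs / 2.0, btype="low", fs=rec.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return EEGRecord(filtered[::factor], new_fs)


def _bandpass(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
    sos = signal.butter(4, (lo, hi), btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _notch(x: np.ndarray, freq: float, fs: float, q: float = 30.0) -> np.ndarray:
    b, a = signal.iirnotch(freq, q, fs=fs)
    return signal.filtfilt(b, a, x)


def band_power(
    rec: EEGRecord,
    bands: BandTable | None = None,
    epoch_s: float = 60.0,
    notch_hz: float = 60.0,
) -> BandPowerSeries:
    """Per-epoch variance power in each sub-band.

    Each band-pass runs over the full record (the gamma band after the
    line-noise notch); variances are taken in non-overlapping ``epoch_s``
    windows and median-filtered (3 samples) across epochs when there are at
    least three.  Fractions are computed after smoothing so they still sum
    to one per epoch.
    """
    bands = bands or BandTable(STANDARD_BANDS)
    n_per = int(round(epoch_s * rec.fs_hz))
    n_epochs = rec.samples.size // n_per
    if n_epochs < 1:
        raise ValueError(f"record shorter than one {epoch_s} s epoch")
    powers = {}
    for name, lo, hi in bands.bands:
        x = rec.samples
        if name == "gamma" and lo < notch_hz < hi:
            x = _notch(x, notch_hz, rec.fs_hz)
        bp = _bandpass(x, lo, hi, rec.fs_hz)
        segs = bp[: n_epochs * n_per].reshape(n_epochs, n_per)
        var = segs.var(axis=1)
        if n_epochs >= 3:
            var = ndimage.median_filter(var, size=3, mode="nearest")
        powers[name] = var
    power = pd.DataFrame(powers)
    total = power.sum(axis=1).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = power.div(power.sum(axis=1), axis=0)
    return BandPowerSeries(power=power, fraction=fraction, total=total, epoch_s=epoch_s)


def sync_correlate(imaging_series: np.ndarray, power_series: np.ndarray) -> float:
    """Squared Pearson correlation between two aligned per-epoch series."""
    a = np.asarray(imaging_series, dtype=float).ravel()
    b = np.asarray(power_series, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("series must have equal epoch counts (align by sync events first)")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in one of the series")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
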