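"""Bolus arrival-time angiography, vessel masking and microvascular connectivity.

Arrival-time mapping: after an intravenous fluorescent-tracer injection, the
fluorescence stack is resampled to 50 ms, background-subtracted (50 px) and
low-passed at 2 Hz; a single global intensity threshold then marks, per
pixel, the first time the wash-in crosses it.  A 5x5 median cleans the map,
which is restricted to a binary vessel mask.  Arteries fill before veins, so
arrival-time ordering encodes the vascular hierarchy.

Microvascular connectivity (MC): resting-state HbT (blood-volume) series are
averaged into 1 s blocks, band-limited to the vasomotor 0.01-0.1 Hz range,
stripped of the global fluctuation by linear regression on the field-of-view
mean, and each pixel's residual is Pearson-correlated with a seed pixel's.
Territories sharing a vascular supply correlate; the global-signal step is
what prevents the shared systemic fluctuation from masking that structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import filters

from .core_io import FilterSpec, FrameStack, background_subtract, temporal_filter, temporal_resample

__all__ = [
    "VesselMask",
    "ArrivalMap",
    "MCMap",
    "make_vessel_mask",
    "arrival_time_map",
    "global_signal_regress",
    "mc_map",
]


@dataclass
class VesselMask:
    mask: np.ndarray  # (H, W) bool
    source_channel: str = ""


@dataclass
class ArrivalMap:
    arrival_ms: np.ndarray  # (H, W), NaN where invalid
    valid: np.ndarray  # (H, W) bool


@dataclass
class MCMap:
    mc: np.ndarray  # (H, W) in [-1, 1]
    seed: tuple[int, int]
    band_hz: tuple[float, float]


def make_vessel_mask(
    image: np.ndarray,
    bg_radius_px: int = 50,
    vessels_bright: bool = True,
    source_channel: str = "",
) -> VesselMask:
    """Binary vessel segmentation: background subtraction then Otsu threshold.

    Expects vessels bright (absorption or fluorescence index); pass
    ``vessels_bright=False`` for reflectance-polarity input, which is
    inverted first so the same mask results.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img[np.isfinite(img)]) == 0:
        raise ValueError("image has no dynamic range; cannot segment vessels")
    if not vessels_bright:
        img = np.nanmax(img) - img
    img = np.nan_to_num(img)
    flat = background_subtract(img, min(bg_radius_px, min(img.shape) - 1))
    thr = filters.threshold_otsu(flat)
    return VesselMask(mask=flat > thr, source_channel=source_channel)


def arrival_time_map(
    fl_stack: FrameStack,
    threshold_frac: float = 0.5,
    dt_ms: float = 50.0,
    bg_radius_px: int = 50,
    lowpass_hz: float = 2.0,
    median_px: int = 5,
    vessel_mask: VesselMask | None = None,
) -> ArrivalMap:
    """Per-pixel tracer arrival time (first threshold crossing).

    Pipeline: resample to ``dt_ms`` -> per-frame background subtraction
    (``bg_radius_px``) -> zero-phase low-pass (``lowpass_hz``) -> one global
    threshold at ``threshold_frac`` of the robust (99th-percentile) plateau
    intensity -> first grid time at/above threshold -> ``median_px`` median
    on the arrival map -> restriction to the vessel mask (derived from the
    plateau image unless supplied).  Pixels that never cross are invalid.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    rs = temporal_resample(fl_stack, dt_ms)
    flat = np.stack(
        [background_subtract(fr, min(bg_radius_px, min(rs.frame_shape) - 1)) for fr in rs.data]
    )
    lp = temporal_filter(rs.replace(data=flat), FilterSpec("lowpass_time", cutoff_hz=lowpass_hz))
    data = lp.data
    n_tail = max(1, data.shape[0] // 10)
    plateau = data[-n_tail:].mean(axis=0)
    thr = threshold_frac * np.percentile(plateau, 99)
    crossed = data >= thr
    ever = crossed.any(axis=0)
    first_idx = crossed.argmax(axis=0)
    arrival = rs.timestamps_ms[first_idx].astype(float)
    arrival[~ever] = np.nan
    if vessel_mask is None:
        vessel_mask = make_vessel_mask(plateau, bg_radius_px=bg_radius_px)
    valid = ever & vessel_mask.mask
    arrival[~valid] = np.nan
    if median_px > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows off-vessel
            arrival = ndimage.generic_filter(arrival, np.nanmedian, size=median_px, mode="reflect")
    arrival[~valid] = np.nan
    valid &= np.isfinite(arrival)
    return ArrivalMap(arrival_ms=arrival, valid=valid)


def global_signal_regress(series_per_pixel: np.ndarray, global_series: np.ndarray) -> np.ndarray:
    """OLS-remove the global time course from every pixel series.

    ``series_per_pixel`` is (T, N); each column is regressed on [1, global]
    and the residual returned.  Residuals are exactly uncorrelated with the
    global series.
    """
    X = np.asarray(series_per_pixel, dtype=float)
    g = np.asarray(global_series, dtype=float)
    if X.shape[0] != g.shape[0]:
        raise ValueError("pixel series and global series differ in length")
    if np.ptp(g) == 0:
        raise ValueError("constant global series cannot be regressed out")
    G = np.column_stack([np.ones_like(g), g])
    beta, *_ = np.linalg.lstsq(G, X, rcond=None)
    return X - G @ beta


def _block_average(stack: FrameStack, block_s: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Mean frame per non-overlapping ``block_s`` time bin; returns (blocks, times_s)."""
    t_s = stack.times_s
    bins = np.floor((t_s - t_s[0]) / block_s + 1e-9).astype(int)
    n_blocks = bins[-1] + 1
    counts = np.bincount(bins, minlength=n_blocks)
    if np.any(counts == 0):
        raise ValueError("empty time block; frame rate too low for the block size")
    flat = stack.data.reshape(stack.n_frames, -1).astype(float)
    sums = np.zeros((n_blocks, flat.shape[1]))
    np.add.at(sums, bins, flat)
    blocks = (sums / counts[:, None]).reshape((n_blocks,) + stack.frame_shape)
    times = t_s[0] + (np.arange(n_blocks) + 0.5) * block_s
    return blocks, times


def _dct_bandpass(X: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Band-limit columns of X by projection onto in-band DCT components.

    The DCT-II basis diagonalises band limiting on a finite, non-periodic
    record: component k carries frequency k*fs/(2N).  Keeping only in-band
    components is zero-phase and free of the edge transients an IIR filter
    with a 0.01 Hz corner drags across a short series.
    """
    from scipy.fft import dct, idct

    n = X.shape[0]
    coef = dct(X, axis=0, norm="ortho")
    freqs = np.arange(n) * fs / (2.0 * n)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    coef[~keep] = 0.0
    return idct(coef, axis=0, norm="ortho")


def mc_map(
    hbt_stack: FrameStack,
    seed: tuple[int, int],
    band_hz: tuple[float, float] = (0.01, 0.1),
    block_s: float = 1.0,
    global_regression: bool = True,
    bandpass: str = "dct",
) -> MCMap:
    """Seed-based microvascular connectivity map.

    1 s block means -> zero-phase band-pass to the vasomotor band (default
    0.01-0.1 Hz; ``bandpass="dct"`` projects onto in-band DCT components,
    ``"butter"`` uses a 2nd-order forward-backward Butterworth) -> optional
    global-signal regression on the FoV mean -> Pearson r of every pixel's
    residual against the seed residual.  ``global_regression=False`` skips
    the nuisance step (useful to demonstrate why it is needed).
    """
    duration_s = hbt_stack.times_s[-1] - hbt_stack.times_s[0]
    if duration_s < 100.0:
        raise ValueError(
            f"recording spans {duration_s:.0f} s; >= 100 s needed to resolve the "
            f"{band_hz[0]}-{band_hz[1]} Hz band"
        )
    H, W = hbt_stack.frame_shape
    r0, c0 = seed
    if not (0 <= r0 < H and 0 <= c0 < W):
        raise ValueError(f"seed {seed} outside the {H}x{W} field of view")
    blocks, _ = _block_average(hbt_stack, block_s)
    fs = 1.0 / block_s
    flat = blocks.reshape(blocks.shape[0], -1)
    if bandpass == "dct":
        X = _dct_bandpass(flat, fs, band_hz)
    elif bandpass == "butter":
        sos = signal.butter(2, band_hz, btype="band", fs=fs, output="sos")
        X = signal.sosfiltfilt(sos, flat, axis=0)
    else:
        raise ValueError(f"unknown bandpass {bandpass!r}")
    if global_regression:
        g = X.mean(axis=1)
        X = global_signal_regress(X, g)
    X = X - X.mean(axis=0)
    s = X[:, r0 * W + c0]
    s_norm = np.sqrt((s**2).sum())
    if s_norm == 0:
        raise ValueError("seed pixel has zero variance after preprocessing")
    norms = np.sqrt((X**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        mc = (X.T @ s) / (norms * s_norm)
    return MCMap(mc=mc.reshape(H, W), seed=(r0, c0), band_hz=tuple(band_hz))
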