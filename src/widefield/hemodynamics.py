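"""Stimulus-locked hemodynamic and calcium response computation.

Green-light reflectance tracks total hemoglobin (HbT, a blood-volume index)
and red-laser reflectance tracks deoxyhemoglobin (dHb); both are used as
proportional absorption indices obtained by inverting the reflectance image.
Responses are expressed as the fractional change

    r(t) = (x(t) - xB) / xB

relative to the mean pre-stimulus baseline xB (the 1-3 s window of a 10 s
epoch with the stimulus at 3 s).  Because r is a ratio, the arbitrary white
reference used in the inversion and any global intensity scale cancel.

The standard pipeline mirrors common wide-field practice: illumination
correction by a large mean-filter flat field, millisecond-timestamped frames
resampled to a 10 ms grid, averaging across ~30 stimulus trials, a 1 s
moving average restricting the useful range to 1-10 s, a 3x3 median, and an
extra 20x20 mean for the noisier laser-derived contrasts (CBF, dHb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import speckle
from .core_io import EventTable, FilterSpec, FrameStack, spatial_filter, temporal_filter

__all__ = [
    "EpochSpec",
    "ResponseStack",
    "IlluminationField",
    "invert_ios",
    "estimate_illumination",
    "illumination_correct",
    "epoch_average",
    "compute_response",
    "standard_response_pipeline",
    "lowpass_response",
]

CONTRASTS = ("Ca", "HbT", "CBF", "dHb")


@dataclass
class EpochSpec:
    """Trial structure of a stimulus run.

    Defaults follow the auditory paradigm: 10 s epochs, 300 ms stimulus at
    the 3 s point, 60 epochs per run, baseline = the 1-3 s pre-stimulus
    window.
    """

    epoch_s: float = 10.0
    stim_onset_s: float = 3.0
    stim_dur_ms: float = 300.0
    n_epochs: int = 60
    baseline_window_s: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if not 0 < self.stim_onset_s < self.epoch_s:
            raise ValueError("stimulus onset must fall inside the epoch")
        b0, b1 = self.baseline_window_s
        if not (0 <= b0 < b1 <= self.stim_onset_s):
            raise ValueError("baseline window must lie within [0, stim_onset_s]")


@dataclass
class ResponseStack:
    """Per-pixel fractional response r(t) on an epoch-relative time axis."""

    r: np.ndarray  # (T, H, W)
    baseline_mean: np.ndarray  # (H, W)
    time_s: np.ndarray  # (T,)
    contrast: str
    valid: np.ndarray  # (H, W) bool
    steps: list[str] = field(default_factory=list)

    @property
    def dt_s(self) -> float:
        return float(np.diff(self.time_s)[0])

    def window(self, t0_s: float, t1_s: float) -> np.ndarray:
        """Frames with t0_s <= t <= t1_s (boolean index over time)."""
        return (self.time_s >= t0_s - 1e-9) & (self.time_s <= t1_s + 1e-9)


@dataclass
class IlluminationField:
    """Smoothed illumination estimate (large mean filter of a reference image)."""

    field: np.ndarray
    kernel_px: int


def invert_ios(frame: np.ndarray) -> np.ndarray:
    """Reflectance -> proportional absorption index: max(frame) - frame.

    The per-frame maximum acts as the white reference; only relative and
    fractional changes of the result are meaningful downstream (the choice
    of reference cancels in r(t)).  A constant frame has zero dynamic range
    and yields an all-zero index with a warning.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if np.ptp(frame) == 0:
        warnings.warn("constant frame has no dynamic range; inverted index is zero", stacklevel=2)
    return frame.max() - frame


def _invert_stack(stack: FrameStack) -> FrameStack:
    data = stack.data.astype(float)
    inv = data.max(axis=(1, 2), keepdims=True) - data
    return stack.replace(data=inv)


def estimate_illumination(
    stack: FrameStack, kernel_px: int = 100, t_window_ms: tuple[float, float] | None = None
) -> IlluminationField:
    """Estimate the illumination pattern from a (pre-stimulus) mean image.

    Frames inside ``t_window_ms`` (default: all frames) are averaged and
    smoothed with a ``kernel_px`` mean filter; structure broader than the
    kernel is attributed to illumination.
    """
    if t_window_ms is None:
        sel = slice(None)
    else:
        t = stack.timestamps_ms
        sel = (t >= t_window_ms[0]) & (t <= t_window_ms[1])
        if not np.any(sel):
            raise ValueError("no frames inside the illumination reference window")
    ref = stack.data[sel].astype(float).mean(axis=0)
    smooth = ndimage.uniform_filter(ref, size=kernel_px, mode="reflect")
    return IlluminationField(field=smooth, kernel_px=kernel_px)


def illumination_correct(stack: FrameStack, field: IlluminationField) -> FrameStack:
    """Flat-field division by the illumination estimate (normalised to unit mean).

    Normalising the field keeps corrected intensities on their original
    scale; a stack whose only spatial structure is the illumination pattern
    becomes spatially constant.
    """
    f = np.asarray(field.field, dtype=float)
    if np.any(f <= 0):
        raise ValueError("illumination field must be strictly positive")
    f = f / f.mean()
    return stack.replace(data=stack.data.astype(float) / f)


def epoch_average(
    stack: FrameStack,
    events: EventTable,
    spec: EpochSpec,
    dt_ms: float = 10.0,
    exclude: tuple[int, ...] = (),
    label: str | None = None,
) -> FrameStack:
    """Average stimulus-locked epochs onto an epoch-relative uniform grid.

    Each event marks a stimulus onset at ``spec.stim_onset_s`` within its
    epoch.  For every included event the surrounding epoch is interpolated
    onto a dt_ms grid (time 0 = epoch start) and the per-pixel mean across
    epochs returned.  ``exclude`` skips manually rejected trials by index
    into the (label-filtered) event list.
    """
    from .core_io import _interp_at

    events = events.select(label)
    if len(events) == 0:
        raise ValueError("no events to average")
    n = int(round(spec.epoch_s * 1000.0 / dt_ms))
    rel_ms = dt_ms * np.arange(n)
    t = stack.timestamps_ms
    acc = np.zeros((n,) + stack.frame_shape)
    count = 0
    for i, t_on in enumerate(events.times_ms):
        if i in exclude:
            continue
        t0 = t_on - spec.stim_onset_s * 1000.0
        if t0 < t[0] - 1e-6 or t0 + rel_ms[-1] > t[-1] + 1e-6:
            raise ValueError(f"event at {t_on} ms lacks a full epoch of data")
        acc += _interp_at(stack, t0 + rel_ms)
        count += 1
    if count == 0:
        raise ValueError("all epochs excluded")
    return stack.replace(data=acc / count, timestamps_ms=rel_ms)


def compute_response(avg: FrameStack, spec: EpochSpec, contrast: str = "HbT") -> ResponseStack:
    """Fractional response r(t) = (x(t) - xB)/xB against the pre-stimulus baseline."""
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}")
    t_s = avg.timestamps_ms / 1000.0
    b0, b1 = spec.baseline_window_s
    bsel = (t_s >= b0 - 1e-9) & (t_s <= b1 + 1e-9)
    if not np.any(bsel):
        raise ValueError("baseline window contains no samples")
    x = avg.data.astype(float)
    with np.errstate(invalid="ignore"):
        xb = np.nanmean(x[bsel], axis=0)
    valid = np.isfinite(xb) & (xb > 0)
    r = np.zeros_like(x)
    np.divide(x - xb, xb, out=r, where=valid)
    r[:, ~valid] = np.nan
    return ResponseStack(r=r, baseline_mean=xb, time_s=t_s, contrast=contrast, valid=valid)


def standard_response_pipeline(
    stack: FrameStack,
    events: EventTable,
    spec: EpochSpec,
    contrast: str,
    dt_ms: float = 10.0,
    illumination_kernel_px: int = 100,
    cbf_window_frames: int = 15,
    exclude: tuple[int, ...] = (),
    label: str | None = None,
) -> ResponseStack:
    """Full per-contrast response pipeline with the standard filter chain.

    Routing: the IOS contrasts (HbT, dHb) are inverted to absorption indices
    and flat-field corrected (illumination estimated from the first epoch's
    pre-stimulus frames); the calcium channel skips both; CBF first converts
    the raw speckle stack to a sliding-window 1/k^2 flow stack.  All routes
    then run epoch averaging, the fractional response, a 1 s moving average
    (useful range clipped to [1 s, epoch end]), and a 3x3 median; CBF and dHb
    additionally get a 20x20 mean because of their lower SNR.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}")
    steps: list[str] = []
    work = stack
    if contrast == "CBF":
        work = speckle.sliding_cbf(work, window_frames=cbf_window_frames)
        steps.append(f"sliding_cbf(window={cbf_window_frames})")
    elif contrast in ("HbT", "dHb"):
        work = _invert_stack(work)
        steps.append("invert_ios")
        first_on = events.select(label).times_ms[0] if len(events.select(label)) else None
        if first_on is None:
            raise ValueError("no events for illumination reference")
        t0 = first_on - spec.stim_onset_s * 1000.0
        field = estimate_illumination(
            work, kernel_px=min(illumination_kernel_px, min(work.frame_shape)),
            t_window_ms=(t0, first_on),
        )
        work = illumination_correct(work, field)
        steps.append(f"illumination_correct(kernel={field.kernel_px})")

    avg = epoch_average(work, events, spec, dt_ms=dt_ms, exclude=exclude, label=label)
    steps.append(f"epoch_average(dt_ms={dt_ms})")
    resp = compute_response(avg, spec, contrast=contrast)
    steps.append("compute_response")

    # 1 s moving average, then clip to the informative 1 s .. epoch-end range
    rstack = FrameStack(np.nan_to_num(resp.r), avg.timestamps_ms, avg.channel, avg.exposure_ms)
    rstack = temporal_filter(rstack, FilterSpec("moving_average_time", window_ms=1000.0))
    steps.append("moving_average(1 s)")
    keep = rstack.timestamps_ms / 1000.0 >= 1.0 - 1e-9
    r = rstack.data[keep]
    time_s = rstack.timestamps_ms[keep] / 1000.0

    r = np.stack([spatial_filter(fr, FilterSpec("median2d", size_px=3)) for fr in r])
    steps.append("median2d(3)")
    if contrast in ("CBF", "dHb"):
        size = min(20, min(r.shape[1:]))
        r = np.stack([spatial_filter(fr, FilterSpec("mean2d", size_px=size)) for fr in r])
        steps.append(f"mean2d({size})")
    r[:, ~resp.valid] = np.nan
    return ResponseStack(
        r=r, baseline_mean=resp.baseline_mean, time_s=time_s,
        contrast=contrast, valid=resp.valid, steps=steps,
    )


def lowpass_response(resp: ResponseStack, cutoff_hz: float = 2.0) -> ResponseStack:
    """Zero-phase low-pass of a response stack (preparation for GLM fitting)."""
    dt_ms = resp.dt_s * 1000.0
    rstack = FrameStack(np.nan_to_num(resp.r), resp.time_s * 1000.0, "CBF", max(dt_ms, 1e-3))
    out = temporal_filter(rstack, FilterSpec("lowpass_time", cutoff_hz=cutoff_hz))
    r = out.data.copy()
    r[:, ~resp.valid] = np.nan
    return ResponseStack(
        r=r, baseline_mean=resp.baseline_mean, time_s=resp.time_s,
        contrast=resp.contrast, valid=resp.valid, steps=resp.steps + [f"lowpass({cutoff_hz} Hz)"],
    )
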