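"""Stack/event I/O and the shared spatial/temporal filtering primitives.

Every analysis stage exchanges data through :class:`FrameStack` — a timestamped
sequence of 2-D intensity frames for one illumination channel.  Stacks live on
disk as multi-page TIFF files with a sidecar CSV of per-frame acquisition times
(``frame_index,time_ms``); image-sensor frame rates drift, so timestamps are
first-class and most temporal operations start by resampling onto a uniform
grid with :func:`temporal_resample`.

The filters gathered here (2-D median/mean, morphological background
subtraction, centred moving average, zero-phase low-pass) are the building
blocks reused by the hemodynamic, angiographic and connectivity pipelines.
All spatial filters use reflect padding and preserve shape and constants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, signal
from skimage import morphology

CHANNELS = ("FL", "IOS_GREEN", "IOS_RED", "CBF")

__all__ = [
    "FrameStack",
    "EventTable",
    "FilterSpec",
    "load_stack",
    "save_stack",
    "save_map",
    "load_map",
    "spatial_filter",
    "background_subtract",
    "temporal_resample",
    "temporal_filter",
    "grid_correlation",
]


@dataclass
class FrameStack:
    """A timestamped 2-D frame sequence for one illumination channel.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Intensity frames in acquisition order (arbitrary units).
    timestamps_ms : ndarray, shape (T,)
        Per-frame acquisition time in milliseconds, strictly increasing.
    channel : str
        One of ``FL`` (fluorescence), ``IOS_GREEN``, ``IOS_RED`` or the
        derived ``CBF`` label.
    exposure_ms : float
        Sensor integration time per frame.
    """

    data: np.ndarray
    timestamps_ms: np.ndarray
    channel: str
    exposure_ms: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be (T, H, W), got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if self.timestamps_ms.shape != (self.data.shape[0],):
            raise ValueError(
                f"{self.data.shape[0]} frames but {self.timestamps_ms.size} timestamps"
            )
        dt = np.diff(self.timestamps_ms)
        if self.n_frames > 1 and not np.all(dt > 0):
            raise ValueError("timestamps must be strictly increasing (ties are an error)")
        if not self.exposure_ms > 0:
            raise ValueError("exposure_ms must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        return self.timestamps_ms / 1000.0

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """True when the frame interval is constant (required by temporal filters)."""
        if self.n_frames < 3:
            return True
        dt = np.diff(self.timestamps_ms)
        return bool(np.all(np.abs(dt - dt[0]) <= rtol * abs(dt[0]) + 1e-9))

    @property
    def dt_ms(self) -> float:
        if not self.is_uniform():
            raise ValueError("stack is not uniformly sampled; resample first")
        return float(np.diff(self.timestamps_ms)[0]) if self.n_frames > 1 else np.nan

    def replace(self, **kwargs) -> "FrameStack":
        return dataclasses.replace(self, **kwargs)


@dataclass
class EventTable:
    """Stimulus / synchronisation events: sorted ``(time_ms, label)`` pairs."""

    times_ms: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.labels = [str(l) for l in self.labels]
        if self.times_ms.ndim != 1 or self.times_ms.size != len(self.labels):
            raise ValueError("times and labels must be 1-D and of equal length")
        if self.times_ms.size and self.times_ms.min() < 0:
            raise ValueError("event times must be non-negative")
        if np.any(np.diff(self.times_ms) < 0):
            raise ValueError("event times must be sorted")
        if any(not l for l in self.labels):
            raise ValueError("event labels must be non-empty")

    def __len__(self) -> int:
        return self.times_ms.size

    def select(self, label: str | None) -> "EventTable":
        if label is None:
            return self
        keep = [i for i, l in enumerate(self.labels) if l == label]
        return EventTable(self.times_ms[keep], [self.labels[i] for i in keep])

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path)
        return cls(df["time_ms"].to_numpy(), df["label"].astype(str).tolist())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ms": self.times_ms, "label": self.labels}).to_csv(
            path, index=False
        )


@dataclass
class FilterSpec:
    """Parameter record for a named filter.

    kind is one of ``median2d``, ``mean2d``, ``moving_average_time``,
    ``lowpass_time``, ``background_subtract``; only the matching size field
    needs to be set (``size_px``, ``radius_px``, ``window_ms`` or
    ``cutoff_hz``).
    """

    kind: str
    size_px: int | None = None
    radius_px: int | None = None
    window_ms: float | None = None
    cutoff_hz: float | None = None

    _KINDS = ("median2d", "mean2d", "moving_average_time", "lowpass_time", "background_subtract")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        for name in ("size_px", "radius_px"):
            v = getattr(self, name)
            if v is not None and (int(v) != v or v < 1):
                raise ValueError(f"{name} must be a positive integer")
        for name in ("window_ms", "cutoff_hz"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# I/O


def save_stack(stack: FrameStack, path: str | Path, timestamps_path: str | Path | None = None) -> None:
    """Write a stack as multi-page TIFF plus a ``frame_index,time_ms`` CSV."""
    path = Path(path)
    tifffile.imwrite(path, stack.data)
    ts_path = Path(timestamps_path) if timestamps_path else path.with_suffix(".times.csv")
    pd.DataFrame(
        {"frame_index": np.arange(stack.n_frames), "time_ms": stack.timestamps_ms}
    ).to_csv(ts_path, index=False)


def load_stack(
    path: str | Path,
    channel: str,
    timestamps_path: str | Path | None = None,
    exposure_ms: float = 1.0,
    frame_rate_fps: float | None = None,
) -> FrameStack:
    """Read a multi-page TIFF stack with its sidecar timestamp table.

    When no timestamp CSV exists, uniform timestamps are synthesised from
    ``frame_rate_fps``.  Integer TIFF pixel values are preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    ts_path = Path(timestamps_path) if timestamps_path else path.with_suffix(".times.csv")
    if ts_path.exists():
        df = pd.read_csv(ts_path)
        if len(df) != data.shape[0]:
            raise ValueError(
                f"{data.shape[0]} TIFF frames but {len(df)} timestamp rows in {ts_path}"
            )
        times = df.sort_values("frame_index")["time_ms"].to_numpy(dtype=float)
    elif frame_rate_fps:
        times = np.arange(data.shape[0]) * 1000.0 / frame_rate_fps
    else:
        raise ValueError(f"no timestamp table at {ts_path} and no frame_rate_fps given")
    return FrameStack(data, times, channel, exposure_ms)


def save_map(
    path: str | Path,
    arr: np.ndarray,
    display_clip_frac: float | None = None,
) -> None:
    """Write a derived 2-D map as float32 TIFF.

    ``display_clip_frac`` (e.g. 0.001) applies symmetric percentile clipping —
    a visualization convenience only, never used on analysis values.
    """
    out = np.asarray(arr, dtype=np.float32)
    if display_clip_frac is not None:
        finite = out[np.isfinite(out)]
        if finite.size:
            lo, hi = np.percentile(finite, [100 * display_clip_frac, 100 * (1 - display_clip_frac)])
            out = np.clip(out, lo, hi)
    tifffile.imwrite(Path(path), out)


def load_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Spatial filtering


def spatial_filter(frame: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """2-D median or mean filter with reflect padding (shape preserving)."""
    frame = np.asarray(frame, dtype=float)
    if spec.kind not in ("median2d", "mean2d"):
        raise ValueError(f"spatial_filter cannot apply kind {spec.kind!r}")
    size = spec.size_px
    if size is None:
        raise ValueError("size_px required")
    if size > min(frame.shape):
        raise ValueError(f"filter size {size} exceeds frame shape {frame.shape}")
    if spec.kind == "median2d":
        if size % 2 == 0:
            raise ValueError("median filter size must be odd")
        return ndimage.median_filter(frame, size=size, mode="reflect")
    return ndimage.uniform_filter(frame, size=size, mode="reflect")


def background_subtract(frame: np.ndarray, radius_px: int) -> np.ndarray:
    """Remove smooth background by subtracting a grayscale disk opening.

    A flat disk of the given radius is slid under the intensity surface
    (erosion then dilation); whatever it can reach — structure broader than
    the disk — is treated as background and subtracted.  Narrow bright
    features (vessels, tracer-filled capillaries) survive.  The operation is
    invariant to the intensity scale, so it is safe on fractional-response
    data as well as raw counts.
    """
    frame = np.asarray(frame, dtype=float)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px >= min(frame.shape):
        raise ValueError(f"radius {radius_px} >= min frame dimension {min(frame.shape)}")
    # sequence decomposition keeps large radii tractable
    footprint = morphology.disk(radius_px, decomposition="sequence")
    background = morphology.opening(frame, footprint)
    return frame - background


# ---------------------------------------------------------------------------
# Temporal operations


def _interp_at(stack: FrameStack, new_times_ms: np.ndarray) -> np.ndarray:
    """Per-pixel linear interpolation of a stack at arbitrary times."""
    t = stack.timestamps_ms
    new_times_ms = np.asarray(new_times_ms, dtype=float)
    idx = np.searchsorted(t, new_times_ms, side="right") - 1
    idx = np.clip(idx, 0, stack.n_frames - 2)
    denom = t[idx + 1] - t[idx]
    w = np.clip((new_times_ms - t[idx]) / denom, 0.0, 1.0)
    data = stack.data.astype(float)
    return (1.0 - w)[:, None, None] * data[idx] + w[:, None, None] * data[idx + 1]


def temporal_resample(stack: FrameStack, dt_ms: float) -> FrameStack:
    """Resample onto a uniform grid of step ``dt_ms`` spanning [t0, tN].

    Each output frame is the per-pixel linear interpolation of the two
    bracketing input frames; idempotent on an already-uniform stack sampled
    at its own step.
    """
    if not dt_ms > 0:
        raise ValueError("dt_ms must be positive")
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames to resample")
    t = stack.timestamps_ms
    n = int(np.floor((t[-1] - t[0]) / dt_ms + 1e-9)) + 1
    new_t = t[0] + dt_ms * np.arange(n)
    return stack.replace(data=_interp_at(stack, new_t), timestamps_ms=new_t)


def temporal_filter(stack: FrameStack, spec: FilterSpec) -> FrameStack:
    """Per-pixel filtering along time: centred moving average or zero-phase low-pass.

    The low-pass is a 4th-order Butterworth applied forward-backward
    (``sosfiltfilt``) so responses are not delayed; the moving average uses
    the nearest odd window length so it stays centred.
    """
    if not stack.is_uniform():
        raise ValueError("temporal_filter requires uniform timestamps; resample first")
    dt = stack.dt_ms
    data = stack.data.astype(float)
    if spec.kind == "moving_average_time":
        if spec.window_ms is None:
            raise ValueError("window_ms required")
        size = max(1, int(round(spec.window_ms / dt)))
        if size % 2 == 0:
            size += 1
        out = ndimage.uniform_filter1d(data, size=size, axis=0, mode="reflect")
    elif spec.kind == "lowpass_time":
        if spec.cutoff_hz is None:
            raise ValueError("cutoff_hz required")
        fs = 1000.0 / dt
        if not 0 < spec.cutoff_hz < fs / 2:
            raise ValueError(f"cutoff {spec.cutoff_hz} Hz outside (0, Nyquist={fs / 2} Hz)")
        sos = signal.butter(4, spec.cutoff_hz, btype="low", fs=fs, output="sos")
        out = signal.sosfiltfilt(sos, data, axis=0)
    else:
        raise ValueError(f"temporal_filter cannot apply kind {spec.kind!r}")
    return stack.replace(data=out)


# ---------------------------------------------------------------------------
# Validation metric


def grid_correlation(
    imageA: np.ndarray,
    imageB: np.ndarray,
    grid_px: int = 20,
    roi_px: int = 400,
) -> float:
    """Coefficient of determination between coarse-grid cell means.

    A ``grid_px`` x ``grid_px`` cell grid is laid over the centred
    ``roi_px`` x ``roi_px`` region of both images; cell mean intensities are
    correlated across cells and the squared Pearson coefficient returned.
    Used to score agreement between two imaging systems viewing the same
    field.
    """
    a = np.asarray(imageA, dtype=float)
    b = np.asarray(imageB, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if min(a.shape) < roi_px:
        raise ValueError(f"images smaller than roi_px={roi_px}")
    r0 = (a.shape[0] - roi_px) // 2
    c0 = (a.shape[1] - roi_px) // 2
    cells = roi_px // grid_px
    span = cells * grid_px

    def cell_means(img: np.ndarray) -> np.ndarray:
        roi = img[r0 : r0 + span, c0 : c0 + span]
        return roi.reshape(cells, grid_px, cells, grid_px).mean(axis=(1, 3)).ravel()

    ca, cb = cell_means(a), cell_means(b)
    if ca.std() == 0 or cb.std() == 0:
        raise ValueError("zero variance in cell-mean series")
    r = np.corrcoef(ca, cb)[0, 1]
    return float(r * r)
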