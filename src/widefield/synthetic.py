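"""Synthetic acquisitions with the statistical structure each stage assumes.

No public recordings accompany the instrument, so these generators stand in
for it: every downstream stage can be exercised end-to-end against known
ground truth.  Each generator is deterministic under its seed and returns,
besides the stack(s), a truth object sufficient to score the corresponding
analysis without re-deriving parameters.

What is emulated:

* time-integrated decorrelating speckle — a per-pixel complex Gaussian field
  evolving as an AR(1) process with step correlation exp(-dt/tau), whose
  squared magnitude is averaged over sub-steps spanning the exposure;
* stimulus-locked multi-channel sessions — a fast calcium transient and a
  gamma-variate hemodynamic response delayed ~1 s, riding on a shared
  spatially uniform 0.01-0.1 Hz global fluctuation, with jittered ~15 fps
  timestamps and white sensor noise;
* sigmoidal tracer-bolus wash-in with per-pixel midpoints inside a vessel
  mask;
* low-frequency correlated vascular territories plus a common global signal
  for connectivity mapping;
* banded EEG with per-minute amplitude profiles and 60 Hz line noise.

Defaults use a 64x64 field of view; the physiology-side defaults (epoch
structure, delays, response amplitudes, band edges) follow the acquisition
paradigm the analysis modules target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .core_io import EventTable, FrameStack
from .eeg import STANDARD_BANDS, EEGRecord

__all__ = [
    "SpeckleSimConfig",
    "Territory",
    "SessionConfig",
    "SessionTruth",
    "simulate_speckle",
    "simulate_neurovascular_session",
    "simulate_tracer_bolus",
    "simulate_mc_phantom",
    "simulate_eeg",
    "make_vessel_phantom",
]


# ---------------------------------------------------------------------------
# Speckle


@dataclass
class SpeckleSimConfig:
    """Decorrelating-speckle simulation settings."""

    tau_ms: float = 5.0
    exposure_ms: float = 5.0
    n_frames: int = 1000
    frame_shape: tuple[int, int] = (64, 64)
    substeps_per_exposure: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tau_ms, self.exposure_ms, self.n_frames) <= 0:
            raise ValueError("tau_ms, exposure_ms and n_frames must be positive")
        if self.substeps_per_exposure < 8:
            raise ValueError("need at least 8 substeps per exposure")


def simulate_speckle(cfg: SpeckleSimConfig) -> tuple[FrameStack, dict]:
    """Exposure-integrated intensity of an exponentially decorrelating field.

    Per pixel an independent circular complex Gaussian field evolves by
    E_{t+dt} = rho E_t + sqrt(1-rho^2) w,  rho = exp(-dt/tau), started from
    its stationary distribution; the recorded frame is the mean of |E|^2
    over the substeps spanning one exposure.  Temporal contrast of the
    resulting frames follows the k(tau, T) integration law.
    """
    rng = np.random.default_rng(cfg.seed)
    dt_sub = cfg.exposure_ms / cfg.substeps_per_exposure
    if dt_sub > cfg.tau_ms / 4:
        warnings.warn(
            f"substep {dt_sub:.3g} ms coarse relative to tau={cfg.tau_ms} ms; "
            "expect discretisation bias",
            stacklevel=2,
        )
    rho = np.exp(-dt_sub / cfg.tau_ms)
    mix = np.sqrt(1.0 - rho**2)
    shape = cfg.frame_shape

    def cgauss() -> np.ndarray:
        return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)

    fld = cgauss()  # stationary start: unit-mean intensity
    frames = np.empty((cfg.n_frames,) + shape, dtype=np.float32)
    for f in range(cfg.n_frames):
        acc = np.zeros(shape)
        for _ in range(cfg.substeps_per_exposure):
            fld = rho * fld + mix * cgauss()
            acc += np.abs(fld) ** 2
        frames[f] = acc / cfg.substeps_per_exposure
    times = np.arange(cfg.n_frames) * cfg.exposure_ms
    stack = FrameStack(frames, times, "IOS_RED", cfg.exposure_ms)
    truth = {"tau_ms": cfg.tau_ms, "exposure_ms": cfg.exposure_ms, "config": cfg}
    return stack, truth


# ---------------------------------------------------------------------------
# Neurovascular session


@dataclass
class Territory:
    """A responsive cortical patch: centre, size, per-channel amplitudes.

    Amplitudes are fractional (peak response relative to baseline) keyed by
    contrast name; dHb responses are conventionally negative (functional
    hyperemia washes deoxyhemoglobin out).
    """

    center: tuple[float, float]
    radius_px: float
    amplitudes: Mapping[str, float]
    stim_label: str = "stim"
    delay_s: float = 1.0


@dataclass
class SessionConfig:
    """Stimulus-session generator settings (auditory-paradigm defaults)."""

    fov_px: tuple[int, int] = (64, 64)
    n_epochs: int = 60
    epoch_s: float = 10.0
    stim_onset_s: float = 3.0
    stim_dur_ms: float = 300.0
    territories: Sequence[Territory] = field(default_factory=list)
    global_band_hz: tuple[float, float] = (0.01, 0.1)
    global_amp: float = 0.01
    noise_sd: Mapping[str, float] = field(default_factory=dict)  # fraction of baseline
    frame_rate_fps: float = 15.0
    jitter_frac: float = 0.05
    baseline: float = 1000.0
    channels: tuple[str, ...] = ("Ca", "HbT")
    vignette_amp: float = 0.0
    border_px: int = 3  # non-hemodynamic bright reference rim (bone/agarose)
    absorption_frac: float = 0.5  # baseline parenchymal absorption of the IOS channels
    seed: int = 0

    def __post_init__(self) -> None:
        H, W = self.fov_px
        for t in self.territories:
            r, c = t.center
            if not (0 <= r < H and 0 <= c < W):
                raise ValueError(f"territory centre {t.center} outside the {H}x{W} FoV")
            if t.delay_s < 0:
                raise ValueError("hemodynamic delay must be non-negative")


@dataclass
class SessionTruth:
    """Ground truth for scoring response/GLM recovery."""

    amplitude_maps: dict  # (channel, stim_label) -> (H, W) fractional peak amplitude
    territory_masks: dict  # stim_label -> (H, W) bool
    cortex_mask: np.ndarray  # (H, W) bool; interior pixels carrying hemodynamics
    delay_s: dict  # stim_label -> hemodynamic delay
    peak_time_s: dict  # (channel, stim_label) -> expected peak time within epoch
    global_series: np.ndarray  # global fluctuation at frame times
    events: EventTable
    config: SessionConfig


_CHANNEL_OF = {"Ca": "FL", "HbT": "IOS_GREEN", "dHb": "IOS_RED", "CBF": "CBF"}

_CA_RISE_S = 0.05
_CA_DECAY_S = 0.5
_HEMO_SHAPE = 3.0
_HEMO_PEAK_AFTER_DELAY_S = 1.0  # peak at onset + delay + 1 s (~2 s post-onset)


def _calcium_kernel(t_from_onset: np.ndarray) -> np.ndarray:
    t = np.clip(t_from_onset, 0.0, None)
    k = (1.0 - np.exp(-t / _CA_RISE_S)) * np.exp(-t / _CA_DECAY_S)
    k[t_from_onset <= 0] = 0.0
    peak = k.max() if k.size and k.max() > 0 else 1.0
    return k / peak if k.max() > 0 else k


def _hemo_kernel(t_from_onset: np.ndarray, delay_s: float) -> np.ndarray:
    """Gamma-variate (shape 3) peaking 1 s after the hyperemic delay, peak 1."""
    t = t_from_onset - delay_s
    u = np.clip(t / _HEMO_PEAK_AFTER_DELAY_S, 0.0, None)
    k = u**_HEMO_SHAPE * np.exp(_HEMO_SHAPE * (1.0 - u))
    k[t <= 0] = 0.0
    return k


def _territory_profile(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    # soft-edged disk: ~1 inside the radius, smooth roll-off over ~15% of it
    return 1.0 / (1.0 + np.exp((d - radius) / (0.15 * radius)))


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` (zero-phase Butterworth)."""
    w = rng.standard_normal(n)
    sos = signal.butter(2, band, btype="band", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, w)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_neurovascular_session(
    cfg: SessionConfig,
) -> tuple[dict[str, FrameStack], EventTable, SessionTruth]:
    """Epoch-structured multi-channel stacks with known activation truth.

    Stimuli of the distinct territory labels are interleaved across epochs;
    each territory responds only in its own epochs.  The calcium channel
    carries a fast transient at the stimulus, hemodynamic channels a
    gamma-variate response delayed by the territory's ``delay_s``; all
    channels share one spatially uniform low-frequency global fluctuation
    and channel-specific white noise.  Timestamps jitter around the nominal
    frame interval.

    IOS channels (HbT, dHb) are emitted as *reflectance*: the cortical
    interior reflects ``1 - absorption_frac * (1 + resp + g)`` of the
    illumination, so activation darkens it, while a ``border_px``-wide rim
    emulates non-hemodynamic tissue (bone/agarose) at full reflectance.
    The rim anchors the per-frame white reference used by the downstream
    inversion, so the inverted absorption index of the interior has
    fractional response exactly ``resp + g`` — the programmed amplitudes are
    recovered on the absorption side, and the global fluctuation survives
    the inversion.  The calcium channel is emitted directly as fluorescence
    ``1 + resp + g`` over the interior.  Truth includes ``cortex_mask``
    (the interior), which downstream cortex-wide averages should use.
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.fov_px
    duration_ms = cfg.n_epochs * cfg.epoch_s * 1000.0

    # jittered timestamps
    mean_dt = 1000.0 / cfg.frame_rate_fps
    n_frames = int(np.floor(duration_ms / mean_dt)) + 1
    dts = rng.normal(mean_dt, cfg.jitter_frac * mean_dt, size=n_frames - 1)
    dts = np.clip(dts, 0.2 * mean_dt, None)
    times = np.concatenate([[0.0], np.cumsum(dts)])
    times *= duration_ms / times[-1]  # pin the span so every epoch is covered

    # events: interleave the distinct stimulus labels across epochs
    labels_order = list(dict.fromkeys(t.stim_label for t in cfg.territories)) or ["stim"]
    ev_times, ev_labels = [], []
    for e in range(cfg.n_epochs):
        ev_times.append(e * cfg.epoch_s * 1000.0 + cfg.stim_onset_s * 1000.0)
        ev_labels.append(labels_order[e % len(labels_order)])
    events = EventTable(np.asarray(ev_times), ev_labels)

    epoch_idx = np.minimum((times // (cfg.epoch_s * 1000.0)).astype(int), cfg.n_epochs - 1)
    t_rel_s = (times - epoch_idx * cfg.epoch_s * 1000.0) / 1000.0
    epoch_label = np.asarray([labels_order[e % len(labels_order)] for e in epoch_idx])

    # shared global fluctuation, sampled on a fine grid then at frame times
    fine_fs = 10.0
    fine_t = np.arange(0.0, duration_ms / 1000.0 + 1.0 / fine_fs, 1.0 / fine_fs)
    g_fine = _bandlimited_noise(fine_t.size, fine_fs, cfg.global_band_hz, rng) * cfg.global_amp
    g = np.interp(times / 1000.0, fine_t, g_fine)

    # per-territory spatial profiles and per-frame kernels
    profiles = [_territory_profile((H, W), t.center, t.radius_px) for t in cfg.territories]
    overlap = np.sum([p > 0.5 for p in profiles], axis=0) if profiles else np.zeros((H, W))
    if np.any(overlap > 1):
        warnings.warn("overlapping territories: amplitudes are summed", stacklevel=2)

    vignette = None
    if cfg.vignette_amp > 0:
        rr, cc = np.mgrid[:H, :W]
        d = np.hypot(rr - (H - 1) / 2, cc - (W - 1) / 2)
        vignette = 1.0 - cfg.vignette_amp * (d / d.max()) ** 2

    interior = np.zeros((H, W), dtype=bool)
    b = cfg.border_px
    interior[b : H - b, b : W - b] = True

    stacks: dict[str, FrameStack] = {}
    amplitude_maps: dict = {}
    peak_time_s: dict = {}
    for chan in cfg.channels:
        resp = np.zeros((n_frames, H, W), dtype=np.float32)
        for terr, prof in zip(cfg.territories, profiles):
            amp = terr.amplitudes.get(chan, 0.0)
            key = (chan, terr.stim_label)
            amplitude_maps.setdefault(key, np.zeros((H, W)))
            amplitude_maps[key] += amp * prof
            if amp == 0.0:
                continue
            active = epoch_label == terr.stim_label
            dt_on = t_rel_s - cfg.stim_onset_s
            if chan == "Ca":
                kern = _calcium_kernel(dt_on)
                peak_time_s[key] = cfg.stim_onset_s + _CA_RISE_S * np.log(
                    1 + _CA_DECAY_S / _CA_RISE_S
                )
            else:
                kern = _hemo_kernel(dt_on, terr.delay_s)
                peak_time_s[key] = cfg.stim_onset_s + terr.delay_s + _HEMO_PEAK_AFTER_DELAY_S
            kern = np.where(active, kern, 0.0)
            resp += (amp * kern[:, None, None] * prof[None]).astype(np.float32)
        hemo_frac = resp + g[:, None, None].astype(np.float32)
        if chan in ("HbT", "dHb"):
            # reflectance: interior darkened by baseline absorption and its response
            data = cfg.baseline * (
                1.0 - cfg.absorption_frac * (1.0 + hemo_frac) * interior[None]
            )
        else:
            data = cfg.baseline * (1.0 + hemo_frac * interior[None])
        if vignette is not None:
            data = data * vignette[None]
        noise_sd = cfg.noise_sd.get(chan, 0.0)
        if noise_sd > 0:
            data = data + rng.normal(0.0, noise_sd * cfg.baseline, size=data.shape)
        exposure = 5.0 if chan in ("dHb", "CBF") else 50.0
        stacks[chan] = FrameStack(data.astype(np.float32), times.copy(), _CHANNEL_OF[chan], exposure)

    truth = SessionTruth(
        amplitude_maps=amplitude_maps,
        territory_masks={
            lab: np.any([p > 0.5 for t, p in zip(cfg.territories, profiles) if t.stim_label == lab], axis=0)
            for lab in labels_order
            if cfg.territories
        },
        cortex_mask=interior,
        delay_s={t.stim_label: t.delay_s for t in cfg.territories},
        peak_time_s=peak_time_s,
        global_series=g,
        events=events,
        config=cfg,
    )
    return stacks, events, truth


# ---------------------------------------------------------------------------
# Tracer bolus


def make_vessel_phantom(shape: tuple[int, int] = (64, 64), n_lines: int = 4, width_px: int = 3) -> np.ndarray:
    """Boolean mask of evenly spaced straight vessel segments (test phantom)."""
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    for i in range(n_lines):
        c = int((i + 1) * W / (n_lines + 1))
        mask[:, c : c + width_px] = True
    r = int(H / 2)
    mask[r : r + width_px, :] = True
    return mask


def make_bolus_arrival_phantom(
    shape: tuple[int, int] = (64, 64),
    n_vessels: int = 4,
    width_px: int = 3,
    arrival_range_ms: tuple[float, float] = (500.0, 3000.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Vessel mask plus per-pixel arrival midpoints increasing along each vessel.

    Parallel vessel segments with staggered inlet times; the tracer front
    propagates along each vessel, so midpoints vary smoothly in the flow
    direction (as in real angiograms) and jointly span ``arrival_range_ms``.
    Returns ``(arrival_ms, mask)``.
    """
    H, W = shape
    lo, hi = arrival_range_ms
    mask = np.zeros(shape, dtype=bool)
    arrival = np.zeros(shape)
    span = hi - lo
    rows = np.arange(H) / max(H - 1, 1)
    for i in range(n_vessels):
        c = int((i + 1) * W / (n_vessels + 1))
        inlet = lo + span * 0.5 * i / max(n_vessels - 1, 1)
        along = inlet + span * 0.5 * rows  # front travels down the vessel
        mask[:, c : c + width_px] = True
        arrival[:, c : c + width_px] = along[:, None]
    return arrival, mask


def simulate_tracer_bolus(
    arrival_truth_ms: np.ndarray,
    width_ms: float,
    vessel_mask: np.ndarray,
    frame_rate_fps: float = 20.0,
    duration_s: float = 5.0,
    baseline: float = 10.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[FrameStack, dict]:
    """Sigmoidal wash-in per vessel pixel with programmed midpoints.

    The logistic scale is ``width_ms / 4`` so ``width_ms`` spans roughly the
    12-88% rise.  Non-vessel pixels carry baseline plus noise only.
    ``noise_sd`` is in the amplitude's units (SNR = amplitude / noise_sd).
    """
    if not width_ms > 0:
        raise ValueError("width_ms must be positive")
    arrival = np.asarray(arrival_truth_ms, dtype=float)
    mask = np.asarray(vessel_mask, bool)
    if np.any(arrival[mask] > duration_s * 1000.0):
        raise ValueError("midpoints must lie within the recording duration")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * frame_rate_fps))
    times = np.arange(n) * 1000.0 / frame_rate_fps
    from scipy.special import expit

    s = width_ms / 4.0
    wash = expit((times[:, None, None] - arrival[None]) / s)
    data = baseline + amplitude * wash * mask[None]
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    stack = FrameStack(data.astype(np.float32), times, "FL", 1000.0 / frame_rate_fps)
    return stack, {"arrival_ms": arrival, "vessel_mask": mask, "width_ms": width_ms}


# ---------------------------------------------------------------------------
# Connectivity phantom


def simulate_mc_phantom(
    labels: np.ndarray,
    shared_freq_band_hz: tuple[float, float] = (0.01, 0.1),
    source_amp: float = 0.02,
    global_amp: float = 0.06,
    noise_sd: float = 0.02,
    duration_s: float = 300.0,
    frame_rate_fps: float = 5.0,
    baseline: float = 1000.0,
    seed: int = 0,
) -> tuple[FrameStack, dict]:
    """Territories with independent low-frequency sources plus a common global.

    ``labels`` (H, W, integers) partitions the field of view; every pixel of
    territory k shares source s_k (band-limited, unit variance, scaled by
    ``source_amp``), all pixels share the global series (``global_amp``), and
    white noise is added on top of the baseline.
    """
    labels = np.asarray(labels)
    if duration_s < 100.0:
        raise ValueError("duration too short to resolve the 0.01-0.1 Hz band (< 100 s)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * frame_rate_fps))
    times = np.arange(n) * 1000.0 / frame_rate_fps
    uniq = np.unique(labels)
    sources = {
        k: _bandlimited_noise(n, frame_rate_fps, shared_freq_band_hz, rng) * source_amp
        for k in uniq
    }
    g = (
        _bandlimited_noise(n, frame_rate_fps, shared_freq_band_hz, rng) * global_amp
        if global_amp > 0
        else np.zeros(n)
    )
    H, W = labels.shape
    frac = np.zeros((n, H, W))
    for k, s in sources.items():
        frac[:, labels == k] += s[:, None]
    frac += g[:, None, None]
    data = baseline * (1.0 + frac)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd * baseline, size=data.shape)
    stack = FrameStack(data.astype(np.float32), times, "IOS_GREEN", 1000.0 / frame_rate_fps)
    truth = {"labels": labels, "sources": sources, "global_series": g}
    return stack, truth


# ---------------------------------------------------------------------------
# EEG


def simulate_eeg(
    state_profile: Mapping[str, np.ndarray],
    fs_hz: float = 12207.0,
    line_amp: float = 0.0,
    bands: Sequence[tuple[str, float, float]] = tuple(STANDARD_BANDS),
    seed: int = 0,
) -> tuple[EEGRecord, dict]:
    """Banded EEG with per-minute amplitude envelopes and 60 Hz line noise.

    ``state_profile`` maps band name -> per-minute RMS amplitude.  Each band
    is band-limited unit-variance noise scaled by its (piecewise-constant)
    envelope; the programmed per-minute band variance (amplitude squared) is
    returned as truth.
    """
    lengths = {len(np.atleast_1d(v)) for v in state_profile.values()}
    if not lengths or lengths == {0}:
        raise ValueError("state_profile must give at least one minute of amplitudes")
    n_min = max(lengths)
    rng = np.random.default_rng(seed)
    n_per_min = int(round(60.0 * fs_hz))
    n = n_min * n_per_min
    x = np.zeros(n)
    band_edges = {name: (lo, hi) for name, lo, hi in bands}
    truth_var = {}
    for name, amps in state_profile.items():
        if name not in band_edges:
            raise ValueError(f"unknown band {name!r}")
        lo, hi = band_edges[name]
        if hi >= fs_hz / 2:
            raise ValueError(f"band {name} above Nyquist")
        amps = np.broadcast_to(np.atleast_1d(np.asarray(amps, float)), (n_min,))
        noise = _bandlimited_noise(n, fs_hz, (lo, hi), rng)
        envelope = np.repeat(amps, n_per_min)
        x += envelope * noise
        truth_var[name] = amps**2
    if line_amp:
        t = np.arange(n) / fs_hz
        x += line_amp * np.sin(2 * np.pi * 60.0 * t)
    return EEGRecord(x, fs_hz), {"per_minute_band_variance": truth_var, "n_minutes": n_min}
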