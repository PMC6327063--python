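"""Pixel-wise GLM activation mapping with a calcium-derived idealized response.

Wide-field hemodynamic maps are contaminated by a large, spatially
non-specific resting fluctuation.  Borrowing from task fMRI, each pixel's
fractional hemodynamic response r(t) is fit by ordinary least squares to

    r(t) = c0 + c1 * a(t) + c2 * g(t) + e(t)

where g(t) is the cortex-wide mean time course (the background regressor)
and a(t) — the idealized response — is the mean time course of a calcium
"hot-spot" (the peak-activity region in the calcium MIP, the gold standard
for localization) minus g(t).  The positive part of the activation
coefficient c1 forms the Act map, which is compared against the
conventional average and maximum-intensity-projection (MIP) maps over the
3-7 s post-stimulus window.  No per-pixel significance testing is applied:
raw positive coefficients are mapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .hemodynamics import ResponseStack

__all__ = [
    "Hotspot",
    "RegressorSet",
    "GLMResult",
    "ActivationMaps",
    "find_hotspot",
    "build_regressors",
    "fit_glm_pixelwise",
    "make_activation_maps",
    "binarize_map",
    "dice_coefficient",
]


@dataclass
class Hotspot:
    mask: np.ndarray  # (H, W) bool
    centroid: tuple[float, float]  # (row, col)
    threshold: float


@dataclass
class RegressorSet:
    """Idealized response a(t) and background g(t) on a shared time axis."""

    a: np.ndarray
    g: np.ndarray
    time_s: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.a) == len(self.g) == len(self.time_s)):
            raise ValueError("regressors and time axis must have equal length")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.g))):
            raise ValueError("regressors must be finite")


@dataclass
class GLMResult:
    c0: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    residual_rms: np.ndarray
    valid: np.ndarray


@dataclass
class ActivationMaps:
    avg: np.ndarray
    mip: np.ndarray
    act: np.ndarray
    window_s: tuple[float, float]


def find_hotspot(calcium_mip: np.ndarray, frac: float = 0.95) -> Hotspot:
    """Largest connected region above the ``frac`` quantile of the calcium MIP.

    8-connectivity; a flat image has no distinguishable hot-spot and raises.
    """
    img = np.asarray(calcium_mip, dtype=float)
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    finite = np.isfinite(img)
    if not finite.any() or np.ptp(img[finite]) == 0:
        raise ValueError("degenerate image: no distinguishable hot-spot")
    thr = np.nanquantile(img, frac)
    above = np.where(finite, img > thr, False)
    if not above.any():
        raise ValueError("no pixels above the hot-spot threshold")
    labels = measure.label(above, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    rows, cols = np.nonzero(mask)
    return Hotspot(mask=mask, centroid=(rows.mean(), cols.mean()), threshold=float(thr))


def build_regressors(
    hemo: ResponseStack,
    hotspot: Hotspot | np.ndarray,
    cortex_mask: np.ndarray | None = None,
) -> RegressorSet:
    """Background g = cortex-wide mean; idealized a = hot-spot mean minus g.

    The hemodynamic stack should already be low-passed at 2 Hz
    (:func:`widefield.hemodynamics.lowpass_response`).  ``cortex_mask``
    defaults to the stack's valid-pixel mask.
    """
    hmask = hotspot.mask if isinstance(hotspot, Hotspot) else np.asarray(hotspot, bool)
    cmask = hemo.valid if cortex_mask is None else np.asarray(cortex_mask, bool)
    if not cmask.any():
        raise ValueError("empty cortex mask")
    if not hmask.any():
        raise ValueError("empty hot-spot")
    if np.any(hmask & ~cmask):
        raise ValueError("hot-spot must lie inside the cortex mask")
    r = np.nan_to_num(hemo.r)
    g = r[:, cmask].mean(axis=1)
    a = r[:, hmask].mean(axis=1) - g
    return RegressorSet(a=a, g=g, time_s=hemo.time_s)


def fit_glm_pixelwise(hemo: ResponseStack, reg: RegressorSet) -> GLMResult:
    """Per-pixel OLS fit of r(t) on [1, a(t), g(t)].

    Residuals are orthogonal to all three design columns (standard OLS
    property).  A rank-deficient design (a proportional to g, or a identically
    zero) is rejected for the whole run, not per pixel.
    """
    T = hemo.r.shape[0]
    if len(reg.a) != T:
        raise ValueError("regressor length does not match stack timepoints")
    X = np.column_stack([np.ones(T), reg.a, reg.g])
    if np.linalg.matrix_rank(X, tol=1e-10 * max(1.0, np.abs(X).max())) < 3:
        raise ValueError("rank-deficient design matrix (a collinear with g or constant)")
    H, W = hemo.r.shape[1:]
    Y = np.nan_to_num(hemo.r).reshape(T, -1)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    rms = np.sqrt((resid**2).mean(axis=0))
    shape = (H, W)
    return GLMResult(
        c0=coef[0].reshape(shape),
        c1=coef[1].reshape(shape),
        c2=coef[2].reshape(shape),
        residual_rms=rms.reshape(shape),
        valid=hemo.valid.copy(),
    )


def make_activation_maps(
    hemo: ResponseStack, glm: GLMResult, window_s: tuple[float, float] = (3.0, 7.0)
) -> ActivationMaps:
    """AVG / MIP over the post-stimulus window and the positive-c1 Act map."""
    sel = hemo.window(*window_s)
    if not sel.any():
        raise ValueError(f"window {window_s} s lies outside the epoch time axis")
    r = np.nan_to_num(hemo.r)[sel]
    return ActivationMaps(
        avg=r.mean(axis=0),
        mip=r.max(axis=0),
        act=np.clip(glm.c1, 0.0, None),
        window_s=window_s,
    )


def binarize_map(m: np.ndarray, rel_threshold: float = 0.5) -> np.ndarray:
    """Threshold a map at ``rel_threshold`` of its (finite) maximum."""
    m = np.asarray(m, dtype=float)
    finite = np.isfinite(m)
    if not finite.any():
        raise ValueError("no finite values to binarize")
    top = m[finite].max()
    if top <= 0:
        return np.zeros_like(m, dtype=bool)
    return np.where(finite, m >= rel_threshold * top, False)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return np.nan
    return float(2.0 * (a & b).sum() / denom)
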