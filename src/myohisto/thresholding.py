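"""Automatic global threshold selection.

Two selectors are provided, matching the two strategies the assay
pipelines rely on:

* **Robust background** — trim the brightest and dimmest pixel fractions,
  model the remainder as a Gaussian background, and set the threshold at
  mean + N standard deviations. Suited to images dominated by background
  with sparse bright objects.
* **Minimum cross-entropy** — Li's criterion family: evaluate, at every
  histogram bin edge, the cross-entropy between pixels and their class
  means under a background/foreground split, and pick the split that
  minimises it. Suited to images where foreground coverage is substantial
  or variable (macrophage aggregates, collagen).

Both selectors clamp their result to configurable lower/upper bounds;
tightening those bounds is the standard fix when automatic selection
misbehaves on an atypical image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .imgio import BinaryMask, GrayImage

__all__ = [
    "ThresholdConfig",
    "robust_background_threshold",
    "min_cross_entropy_threshold",
    "compute_threshold",
    "apply_threshold",
]

_METHODS = ("robust_background", "min_cross_entropy", "manual")


@dataclass
class ThresholdConfig:
    """Configuration for global threshold selection.

    Parameters
    ----------
    method:
        One of ``robust_background``, ``min_cross_entropy``, ``manual``.
    n_sd:
        The N in mean + N·SD for the robust background method. Larger N
        gives a more stringent (higher) threshold; 2 is the conventional
        default.
    trim_low, trim_high:
        Fractions of the dimmest / brightest pixels discarded before the
        background statistics are computed (default 5% each side).
    lower_bound, upper_bound:
        Clamp range for the returned threshold, on the [0, 1] intensity
        scale.
    manual_value:
        Fixed threshold, required iff method is ``manual``.
    bins:
        Histogram resolution for minimum cross-entropy; candidate
        thresholds are the ``bins`` left bin edges k/bins, k = 0..bins-1.
    pre_apply_sigma:
        Optional Gaussian blur (in pixels) applied to the image before the
        threshold is *applied* — never before it is computed. Default 0
        (off).
    """

    method: str = "robust_background"
    n_sd: float = 2.0
    trim_low: float = 0.05
    trim_high: float = 0.05
    lower_bound: float = 0.0
    upper_bound: float = 1.0
    manual_value: Optional[float] = None
    bins: int = 256
    pre_apply_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown threshold method {self.method!r}")
        if not (0 <= self.trim_low < 0.5 and 0 <= self.trim_high < 0.5):
            raise ValueError("trim fractions must lie in [0, 0.5)")
        if self.trim_low + self.trim_high >= 1:
            raise ValueError("trim_low + trim_high must be < 1")
        if not (0.0 <= self.lower_bound <= self.upper_bound <= 1.0):
            raise ValueError("need 0 <= lower_bound <= upper_bound <= 1")
        if self.bins < 1:
            raise ValueError("bins must be a positive integer")
        if self.pre_apply_sigma < 0:
            raise ValueError("pre_apply_sigma must be >= 0")
        if (self.manual_value is None) == (self.method == "manual"):
            raise ValueError("manual_value is required iff method is 'manual'")
        if self.manual_value is not None and not (0.0 <= self.manual_value <= 1.0):
            raise ValueError("manual_value must lie in [0, 1]")

    def _clamp(self, t: float) -> float:
        return float(min(max(t, self.lower_bound), self.upper_bound))


def robust_background_threshold(gray: GrayImage, cfg: ThresholdConfig) -> float:
    """Trimmed-background threshold: mean + n_sd · SD of the retained pixels.

    Sorts all intensities, discards floor(trim_low·n) of the dimmest and
    floor(trim_high·n) of the brightest, and computes the mean and
    population standard deviation of what remains. The upper trim serves
    as the foreground removal: after it, the retained distribution is
    treated as approximately Gaussian background.
    """
    if cfg.method != "robust_background":
        raise ValueError(f"config method is {cfg.method!r}, not 'robust_background'")
    x = np.sort(gray.pixels, axis=None)
    n = x.size
    if n < 3:
        raise ValueError("robust background threshold needs at least 3 pixels")
    lo = int(np.floor(cfg.trim_low * n))
    hi = int(np.floor(cfg.trim_high * n))
    kept = x[lo : n - hi]
    if kept.size == 0:
        raise ValueError("trim fractions removed every pixel")
    mu = float(kept.mean())
    sigma = float(kept.std())  # population SD
    return cfg._clamp(mu + cfg.n_sd * sigma)


def min_cross_entropy_threshold(gray: GrayImage, cfg: ThresholdConfig) -> float:
    """Minimum cross-entropy threshold by exhaustive bin-edge search.

    For each candidate t (a histogram bin edge), pixels split into
    background (x < t) and foreground (x >= t) with class means mu0, mu1,
    and the objective

        eta(t) = - sum_bg x·log(mu0) - sum_fg x·log(mu1)

    is evaluated over pixel intensities x (zero-intensity pixels
    contribute nothing). The t with the smallest eta wins; ties go to the
    smallest t, candidates with an empty class are skipped. The search is
    exhaustive rather than iterative because a few hundred evaluations are
    cheap and exactness makes the selector directly testable.
    """
    if cfg.method != "min_cross_entropy":
        raise ValueError(f"config method is {cfg.method!r}, not 'min_cross_entropy'")
    x = np.sort(gray.pixels, axis=None)
    n = x.size
    if n == 0:
        raise ValueError("empty image")
    if x[0] == x[-1]:  # degenerate single-valued image
        return cfg._clamp(float(x[0]))
    prefix = np.concatenate(([0.0], np.cumsum(x)))
    total = prefix[-1]
    candidates = np.arange(cfg.bins, dtype=np.float64) / cfg.bins
    best_t = None
    best_eta = np.inf
    for t in candidates:
        k = int(np.searchsorted(x, t, side="left"))
        nb, nf = k, n - k
        if nb == 0 or nf == 0:
            continue
        sb = prefix[k]
        sf = total - sb
        eta = 0.0
        if sb > 0:
            eta -= sb * np.log(sb / nb)
        if sf > 0:
            eta -= sf * np.log(sf / nf)
        if eta < best_eta:
            best_eta = eta
            best_t = float(t)
    if best_t is None:
        # all pixels fall on one side of every candidate edge; fall back to
        # the midpoint of the observed range
        best_t = float(0.5 * (x[0] + x[-1]))
    return cfg._clamp(best_t)


def compute_threshold(gray: GrayImage, cfg: ThresholdConfig) -> float:
    """Dispatch on cfg.method."""
    if cfg.method == "robust_background":
        return robust_background_threshold(gray, cfg)
    if cfg.method == "min_cross_entropy":
        return min_cross_entropy_threshold(gray, cfg)
    return cfg._clamp(float(cfg.manual_value))


def apply_threshold(gray: GrayImage, threshold: float, smooth_sigma: float = 0.0) -> BinaryMask:
    """Classify pixels: foreground (1) where intensity >= threshold.

    ``smooth_sigma`` optionally blurs the image before classification
    (never before threshold *selection*); default off.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    pix = gray.pixels
    if smooth_sigma > 0:
        pix = gaussian_filter(pix, smooth_sigma)
    return BinaryMask((pix >= threshold).astype(np.uint8))
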