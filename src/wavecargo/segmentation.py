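"""Organizer-wave segmentation.

The segmentation chain mirrors the standard Fiji/ImageJ recipe for
MinDE-type surface waves: per frame, a disc median filter suppresses
shot noise, a pseudo-flat-field correction (division by a wide Gaussian
blur, mean-preserving) removes uneven illumination, and an automatic
histogram threshold — Huang's fuzzy-entropy criterion or Li's minimum
cross-entropy iteration, both on a 256-bin histogram of the min–max
scaled frame — splits pixels into the wave mask (organizer maximum,
"max(MinD)") and its logical complement (organizer minimum,
"min(MinD)"). The masks are meant to be applied to the *original*,
unfiltered intensities downstream; the filtered image exists only to
define them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import median as _skimage_median
from skimage.morphology import disk

from .stack import ImageStack

logger = logging.getLogger(__name__)

_N_BINS = 256


@dataclass
class WaveMaskPair:
    """Complementary per-frame binary masks of the organizer wave.

    ``wave_mask`` marks pixels above threshold (inside the wave);
    ``complement_mask`` is its exact logical complement, so the two
    partition every frame. Frames whose filtered image is constant
    cannot be thresholded and are flagged invalid.
    """

    wave_mask: np.ndarray  # (T, H, W) bool
    complement_mask: np.ndarray  # (T, H, W) bool
    threshold_method: str
    threshold_values: np.ndarray  # (T,) float, NaN where invalid
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.wave_mask.shape[0], dtype=bool)
        if np.any(self.wave_mask & self.complement_mask):
            raise ValueError("masks overlap")
        if not np.all(self.wave_mask | self.complement_mask):
            raise ValueError("masks do not cover every pixel")

    @property
    def n_frames(self) -> int:
        return self.wave_mask.shape[0]


def median_filter(image: np.ndarray, radius: int) -> np.ndarray:
    """Disc median filter with reflective edge handling."""
    image = np.asarray(image, dtype=np.float64)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius > min(image.shape) // 2:
        raise ValueError(
            f"radius {radius} exceeds half the smaller image side "
            f"({min(image.shape) // 2})"
        )
    return _skimage_median(image, footprint=disk(radius), mode="mirror")


def pseudo_flat_field_correct(image: np.ndarray, radius: float) -> np.ndarray:
    """Divide by a Gaussian-blurred copy (sigma = radius) and rescale by
    the blur's mean so the global intensity scale is preserved.

    A smooth multiplicative vignette much wider than the image features
    is recovered by the blur and divided out; a uniform image passes
    through unchanged.
    """
    image = np.asarray(image, dtype=np.float64)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not np.any(image > 0):
        raise ValueError("image must contain at least one positive pixel")
    blurred = gaussian_filter(image, sigma=radius, mode="reflect")
    if np.any(blurred <= 0):
        warnings.warn(
            "blurred image contains non-positive values; flooring", stacklevel=2
        )
        floor = max(blurred[blurred > 0].min() * 1e-6, np.finfo(float).tiny)
        blurred = np.maximum(blurred, floor)
    return image / blurred * blurred.mean()


def _scaled_histogram(image: np.ndarray) -> tuple[np.ndarray, float, float]:
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise ValueError("cannot threshold a constant image")
    hist, _ = np.histogram(image, bins=_N_BINS, range=(lo, hi))
    return hist.astype(np.float64), lo, hi


def _bin_to_intensity(t: float, lo: float, hi: float) -> float:
    # threshold lies between bin t and t+1 of the [lo, hi] range
    return lo + (t + 0.5) * (hi - lo) / (_N_BINS - 1)


def threshold_huang(image: np.ndarray) -> float:
    """Huang's fuzzy-entropy threshold.

    For each candidate split of the 256-bin histogram the image is
    viewed as a fuzzy two-class set; pixel membership decays with
    distance from its class mean, and the split minimizing total
    Shannon fuzziness wins (exhaustive scan over all 255 splits).
    Returns the threshold mapped back to intensity units.
    """
    hist, lo, hi = _scaled_histogram(image)
    levels = np.arange(_N_BINS, dtype=np.float64)
    w = hist
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w * levels)
    total_w, total_wx = cum_w[-1], cum_wx[-1]
    first = int(np.flatnonzero(w)[0])
    last = int(np.flatnonzero(w)[-1])
    C = last - first  # fuzzy membership range
    if C == 0:
        raise ValueError("cannot threshold a constant image")

    candidates = []
    scores = []
    for t in range(first, last):
        w0, wx0 = cum_w[t], cum_wx[t]
        w1, wx1 = total_w - w0, total_wx - wx0
        if w0 == 0 or w1 == 0:
            continue
        mu0, mu1 = wx0 / w0, wx1 / w1
        mu = np.where(levels <= t, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(levels - mu) / C)
        # Shannon entropy of the membership; u in (0.5, 1] so 1-u can be 0
        with np.errstate(divide="ignore", invalid="ignore"):
            S_lvl = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        S_lvl = np.nan_to_num(S_lvl, nan=0.0, posinf=0.0, neginf=0.0)
        candidates.append(t)
        scores.append(float(np.sum(w * S_lvl)))
    scores_arr = np.asarray(scores)
    # on clean bimodal data every split inside the empty gap ties; take the
    # middle of the tying plateau so the threshold sits mid-gap
    tied = np.flatnonzero(scores_arr <= scores_arr.min() + 1e-9 * (1 + abs(scores_arr.min())))
    best_t = candidates[int(tied[len(tied) // 2])]
    return _bin_to_intensity(best_t, lo, hi)


def threshold_li(image: np.ndarray, max_iter: int = 64) -> float:
    """Li–Lee minimum-cross-entropy threshold (iterative form).

    Starting from the histogram mean, iterates
    ``t ← (μ_below/ln μ_below-style update)`` — the standard fixed point
    whose solution minimizes the cross entropy between image and
    thresholded image — until successive thresholds differ by less than
    half a bin. Uses the same 256-bin scaled histogram as
    :func:`threshold_huang`.
    """
    hist, lo, hi = _scaled_histogram(image)
    levels = np.arange(_N_BINS, dtype=np.float64) + 1.0  # shift >0 for logs
    w = hist
    t = float(np.sum(w * levels) / np.sum(w))  # start at the global mean
    for _ in range(max_iter):
        below = levels <= t
        w_b, w_f = np.sum(w[below]), np.sum(w[~below])
        if w_b == 0 or w_f == 0:
            break
        mu_b = np.sum(w[below] * levels[below]) / w_b
        mu_f = np.sum(w[~below] * levels[~below]) / w_f
        if mu_b <= 0 or np.isclose(mu_b, mu_f):
            break
        t_new = (mu_b - mu_f) / (np.log(mu_b) - np.log(mu_f))
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    return _bin_to_intensity(t - 1.0, lo, hi)  # undo the +1 level shift


_THRESHOLDS = {"huang": threshold_huang, "li": threshold_li}


def segment_wave(
    stack: ImageStack,
    organizer_channel: int | str = 0,
    method: str = "huang",
    median_radius: int = 4,
    flatfield_radius: float = 75.0,
) -> WaveMaskPair:
    """Segment the organizer wave in every frame.

    Per frame: median filter → pseudo-flat-field correction → automatic
    threshold; the wave mask is all pixels strictly above the threshold
    (ties go to the complement). Frames that are constant after
    filtering are flagged invalid (all-complement) and logged. The
    returned masks are intended for the original, unfiltered stack.
    """
    if method not in _THRESHOLDS:
        raise ValueError(f"method must be one of {sorted(_THRESHOLDS)}")
    frames = stack.channel(organizer_channel)
    T = frames.shape[0]
    wave = np.zeros(frames.shape, dtype=bool)
    thresholds = np.full(T, np.nan)
    valid = np.ones(T, dtype=bool)
    for t in range(T):
        filtered = median_filter(frames[t], median_radius)
        filtered = pseudo_flat_field_correct(filtered, flatfield_radius)
        if filtered.max() <= filtered.min():
            valid[t] = False
            logger.warning("frame %d constant after filtering; marked invalid", t)
            continue
        thr = _THRESHOLDS[method](filtered)
        thresholds[t] = thr
        wave[t] = filtered > thr
    return WaveMaskPair(
        wave_mask=wave,
        complement_mask=~wave,
        threshold_method=method,
        threshold_values=thresholds,
        valid=valid,
    )
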