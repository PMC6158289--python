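"""Kymographs, stack normalization, bleach correction and wave metrics.

A kymograph samples intensities along a fixed line in every frame and
stacks the samples into a (time, position) image; traveling waves show
up as stripes whose slope encodes the velocity and whose spacing the
wavelength. This module also provides the two stack-level corrections
used around kymograph display — per-frame Gaussian blur + division by
the frame mean (removes global intensity drift before display) and
photobleaching correction by histogram matching against a reference
frame — plus a spectral estimator for wavelength and velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.exposure import match_histograms

from .stack import ImageStack


@dataclass
class Kymograph:
    """Space-time intensity image along a line selection."""

    values: np.ndarray  # (T, N) intensity
    line: tuple[float, float, float, float]  # x0, y0, x1, y1 (px)
    spatial_step: float  # µm per sample
    time_step: float  # s per row


def extract_kymograph(
    stack: ImageStack,
    channel: int | str,
    line: tuple[float, float, float, float],
    width: int = 3,
) -> Kymograph:
    """Sample intensities along ``line`` (x0, y0, x1, y1) in every frame.

    Samples are taken at 1 px spacing by linear interpolation and
    averaged over ``width`` unit-spaced perpendicular offsets centered
    on the line.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    x0, y0, x1, y1 = line
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length == 0:
        raise ValueError("line is degenerate (zero length)")
    frames = stack.channel(channel)
    _, H, W = frames.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= W - 1 and 0 <= y <= H - 1):
            raise ValueError(f"line endpoint ({x}, {y}) outside image")
    n = int(np.floor(length)) + 1
    t_par = np.linspace(0.0, length, n)
    ux, uy = (x1 - x0) / length, (y1 - y0) / length  # unit along
    px, py = -uy, ux  # unit perpendicular
    offsets = np.arange(width, dtype=np.float64) - (width - 1) / 2.0
    xs = x0 + t_par[None, :] * ux + offsets[:, None] * px  # (width, n)
    ys = y0 + t_par[None, :] * uy + offsets[:, None] * py
    coords = np.stack([ys.ravel(), xs.ravel()])
    rows = np.empty((frames.shape[0], n))
    for t in range(frames.shape[0]):
        samples = map_coordinates(frames[t], coords, order=1, mode="nearest")
        rows[t] = samples.reshape(width, n).mean(axis=0)
    return Kymograph(
        values=rows,
        line=line,
        spatial_step=stack.pixel_size,
        time_step=stack.frame_interval,
    )


def normalize_by_frame_mean(
    stack: ImageStack, channel: int | str | None = None, blur_sigma: float = 1.0
) -> ImageStack:
    """Gaussian-blur each frame, then divide it by its own mean.

    Removes frame-to-frame global intensity drift so kymograph stripes
    reflect spatial structure only; every output frame has mean 1.
    Operates on one channel (others pass through) or all channels.
    """
    pix = stack.pixels.astype(np.float64).copy()
    channels = (
        range(stack.n_channels) if channel is None else [stack.channel_index(channel)]
    )
    for c in channels:
        for t in range(stack.n_frames):
            frame = gaussian_filter(pix[t, c], blur_sigma, mode="reflect")
            m = frame.mean()
            if m <= 0:
                raise ValueError(f"frame {t} channel {c} has nonpositive mean")
            pix[t, c] = frame / m
    return replace(stack, pixels=pix)


def bleach_correct_histogram_match(
    stack: ImageStack, channel: int | str, reference_frame: int = 0
) -> ImageStack:
    """Correct photobleaching by matching every frame's empirical
    intensity CDF to that of ``reference_frame``.

    Uses the full empirical distribution (exact quantile mapping on
    float data), so matching a frame to itself is the identity and the
    operation is idempotent up to quantization.
    """
    c = stack.channel_index(channel)
    if not 0 <= reference_frame < stack.n_frames:
        raise ValueError("reference frame out of range")
    ref = stack.pixels[:, c][reference_frame]
    if ref.max() <= ref.min():
        raise ValueError("reference frame is constant; matching undefined")
    pix = stack.pixels.astype(np.float64).copy()
    for t in range(stack.n_frames):
        frame = pix[t, c]
        if frame.max() <= frame.min():
            warnings.warn(
                f"frame {t} is constant; set to reference median", stacklevel=2
            )
            pix[t, c] = np.full_like(frame, np.median(ref))
            continue
        pix[t, c] = match_histograms(frame, ref)
    return replace(stack, pixels=pix)


def estimate_wavelength_velocity(
    kymograph: Kymograph, peak_snr: float = 3.0
) -> tuple[float, float]:
    """Dominant wavelength (µm) and phase velocity (µm/s) of a wave
    pattern from the peak of the kymograph's 2D power spectrum.

    The zero-spatial-frequency column (global flicker, including the DC
    origin) is excluded so the peak always carries spatial structure. A
    positive velocity means motion toward increasing position along the
    line; a static striped pattern gives velocity 0. Returns
    ``(nan, nan)`` if no admissible peak rises ``peak_snr``-fold above
    the median admissible power (pattern undetermined).
    """
    v = kymograph.values
    T, N = v.shape
    if T < 4 or N < 4:
        raise ValueError("kymograph too small for spectral estimation")
    # Hann window against leakage, 4x zero-padding for frequency resolution
    win = np.hanning(T)[:, None] * np.hanning(N)[None, :]
    Tp, Np = 4 * T, 4 * N
    spec = np.fft.fftshift(np.abs(np.fft.fft2((v - v.mean()) * win, s=(Tp, Np))) ** 2)
    ft = np.fft.fftshift(np.fft.fftfreq(Tp, d=kymograph.time_step))  # cycles/s
    fx = np.fft.fftshift(np.fft.fftfreq(Np, d=kymograph.spatial_step))  # cycles/µm
    # exclude spatial frequencies below one cycle per line (global flicker,
    # including DC) so the peak always carries spatial structure
    mask = np.ones_like(spec, dtype=bool)
    mask[:, np.abs(fx) < 0.5 / (N * kymograph.spatial_step)] = False
    off = spec[mask]
    if off.max() < peak_snr * np.median(off):
        return (float("nan"), float("nan"))
    spec_masked = np.where(mask, spec, 0.0)
    it, ix = np.unravel_index(np.argmax(spec_masked), spec.shape)

    def refine(idx: int, axis_vals: np.ndarray, along_time: bool) -> float:
        sl = (
            (slice(idx - 1, idx + 2), ix) if along_time else (it, slice(idx - 1, idx + 2))
        )
        if idx == 0 or idx == axis_vals.size - 1:
            return axis_vals[idx]
        y0, y1, y2 = np.log(spec[sl] + 1e-300)
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        step = axis_vals[1] - axis_vals[0]
        return axis_vals[idx] + np.clip(shift, -0.5, 0.5) * step

    f_t = refine(it, ft, True)
    f_x = refine(ix, fx, False)
    wavelength = 1.0 / abs(f_x)
    # a component cos(2π(f_x·x + f_t·t)) moves at v = −f_t/f_x
    velocity = -f_t / f_x
    return float(wavelength), float(velocity)
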