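"""Time-averaged axial concentration profiles in rod-shaped compartments.

Pole-to-pole oscillations of the organizer leave a time-averaged
concentration gradient: organizer maxima at the compartment poles and a
central dip, while a laterally transported (anchored) cargo accumulates
at mid-compartment. This module quantifies that structure:

1. average the time series per pixel,
2. project the average onto the compartment long axis,
3. locate the compartment edges on the organizer profile (signal rise
   plus sign of the first spatial derivative) and clip,
4. locate the two organizer polar maxima — a quartic fit for rough
   positions, then a local parabola in a fixed window for refinement,
5. linearly remap the span between the maxima onto a unit box
   x ∈ [−0.5, 0.5] (both channels use the organizer-defined box) and
   divide each channel by its own mean over the box,
6. fit f(x) = a·x² + b by least squares. The curvature 2a (equivalently
   the profile depth a/4, identical up to a constant prefactor on a
   unit-length box) classifies the profile: a > tol polar, a < −tol
   center-enriched, |a| ≤ tol homogeneous.

The profiles are mean-normalized before fitting so that a is
dimensionless and comparable across compartments and channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .stack import ImageStack

CLASSIFICATION_TOLERANCE = 0.1  # |a| below this is "homogeneous"


@dataclass
class AxialProfile:
    """Per-channel mean intensity along the compartment long axis."""

    positions: np.ndarray  # (N,) px, strictly increasing
    values: np.ndarray  # (C, N)
    channel_names: list[str] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.values.shape[1] != self.positions.size:
            raise ValueError("values length must match positions")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.values.shape[0])]


@dataclass
class UnitBoxProfile:
    """Axial profiles remapped to the organizer-defined unit box."""

    x: np.ndarray  # (G,) in [-0.5, 0.5]
    values: np.ndarray  # (C, G), each channel mean-normalized
    channel_names: list[str]
    source: str = ""


@dataclass
class QuadraticFit:
    a: float
    b: float

    @property
    def curvature(self) -> float:
        return 2.0 * self.a

    @property
    def depth(self) -> float:
        return self.a / 4.0


def time_average(stack: ImageStack, channel: int | str | None = None) -> np.ndarray:
    """Per-pixel arithmetic mean over frames; one channel or all."""
    if stack.n_frames < 2:
        raise ValueError("need at least two frames to average")
    if channel is None:
        return stack.pixels.mean(axis=0)
    return stack.channel(channel).mean(axis=0)


def project_long_axis(
    avg_image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    channel_names: list[str] | None = None,
    source: str = "",
) -> AxialProfile:
    """Mean over the short axis at every long-axis position.

    ``avg_image`` is (C, H, W) (or (H, W) for one channel); ``roi`` is an
    axis-aligned rectangle (row0, col0, row1, col1), 0-based, half-open.
    The long axis is whichever side of the ROI is longer; both
    orientations are handled identically.
    """
    img = np.asarray(avg_image, dtype=np.float64)
    if img.ndim == 2:
        img = img[None]
    _, H, W = img.shape
    if roi is None:
        roi = (0, 0, H, W)
    r0, c0, r1, c1 = roi
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ValueError(f"roi {roi} outside image of shape {(H, W)}")
    sub = img[:, r0:r1, c0:c1]
    if (r1 - r0) > (c1 - c0):  # long axis along rows
        values = sub.mean(axis=2)
        positions = np.arange(r0, r1, dtype=np.float64)
    else:
        values = sub.mean(axis=1)
        positions = np.arange(c0, c1, dtype=np.float64)
    return AxialProfile(
        positions=positions,
        values=values,
        channel_names=channel_names or [],
        source=source,
    )


def detect_edges_and_clip(
    profile: AxialProfile,
    organizer_channel: int = 0,
    k: float = 3.0,
    background_window: int = 10,
    smooth_sigma: float = 2.0,
) -> AxialProfile:
    """Clip an axial profile to the compartment located on the organizer.

    The left edge is the first position where the organizer signal
    exceeds background + k·σ_background *and* the (lightly smoothed)
    first spatial derivative is positive; the right edge is symmetric.
    Background mean and σ come from ``background_window`` samples at
    each end of the profile. Profiles with no crossing are rejected —
    the compartment carries no usable oscillation signal.
    """
    y = profile.values[organizer_channel]
    n = y.size
    w = min(background_window, n // 4)
    if w < 1:
        raise ValueError("profile too short for background estimation")
    bg_samples = np.concatenate([y[:w], y[-w:]])
    thr = bg_samples.mean() + k * bg_samples.std()
    ys = gaussian_filter1d(y, smooth_sigma)
    dy = np.gradient(ys)

    above = y > thr
    rising = above & (dy > 0)
    falling = above & (dy < 0)
    if not rising.any() or not falling.any():
        raise ValueError("no compartment edges found (no signal rise above background)")
    left = int(np.flatnonzero(rising)[0])
    right = int(np.flatnonzero(falling)[-1])
    if right - left < 2:
        raise ValueError("detected edges leave no interior")
    return AxialProfile(
        positions=profile.positions[left : right + 1],
        values=profile.values[:, left : right + 1],
        channel_names=profile.channel_names,
        source=profile.source,
    )


def locate_polar_maxima(
    profile: AxialProfile,
    organizer_channel: int = 0,
    window: int = 40,
) -> tuple[float, float]:
    """Two-step localization of the organizer's two polar maxima.

    Stage 1: a fourth-order polynomial least-squares fit over the whole
    clipped profile; its interior local maxima give rough estimates.
    Stage 2: a parabola fitted over a ``window``-px region of interest
    around each estimate; the refined maximum is the parabola vertex
    (clamped to the window). If a window's parabola opens upward, the
    window's discrete argmax is used instead (with a warning).
    """
    x = profile.positions
    y = profile.values[organizer_channel]
    if x.size <= 2 * window:
        raise ValueError(
            f"clipped profile ({x.size} px) too short for two disjoint "
            f"{window}-px windows"
        )
    # quartic on a scaled coordinate for conditioning
    xc, xs = x.mean(), (x.max() - x.min()) / 2.0
    u = (x - xc) / xs
    coeffs = np.polyfit(u, y, 4)
    droots = np.roots(np.polyder(coeffs))
    second = np.polyder(coeffs, 2)
    maxima = [
        float(r.real)
        for r in droots
        if abs(r.imag) < 1e-9
        and u.min() < r.real < u.max()
        and np.polyval(second, r.real) < 0
    ]
    if len(maxima) < 2:
        raise ValueError("quartic fit has fewer than two interior maxima")
    maxima = sorted(maxima)
    rough = [maxima[0] * xs + xc, maxima[-1] * xs + xc]

    refined = []
    half = window / 2.0
    for est in rough:
        # re-center the window on each refined vertex; for a symmetric
        # peak the fixed point has the window centered on the maximum,
        # where the parabola vertex is unbiased
        for _ in range(8):
            sel = (x >= est - half) & (x <= est + half)
            xw, yw = x[sel], y[sel]
            c2, c1, _ = np.polyfit(xw - est, yw, 2)
            if c2 >= 0:
                warnings.warn(
                    "refinement parabola opens upward; using discrete argmax",
                    stacklevel=2,
                )
                vertex = float(xw[np.argmax(yw)])
                est = vertex
                break
            vertex = float(np.clip(est - c1 / (2.0 * c2), xw.min(), xw.max()))
            if abs(vertex - est) < 0.01:
                est = vertex
                break
            est = vertex
        refined.append(est)
    x_left, x_right = sorted(refined)
    if not x_left < x_right:
        raise ValueError("refined maxima coincide")
    return x_left, x_right


def project_unit_box(
    profile: AxialProfile,
    x_left: float,
    x_right: float,
    grid_size: int = 101,
) -> UnitBoxProfile:
    """Remap [x_left, x_right] linearly onto x ∈ [−0.5, 0.5] and resample.

    Both channels are projected with the same (organizer-defined) box;
    values are linearly interpolated onto a fixed grid and each channel
    is divided by its own mean over the box.
    """
    if not x_left < x_right:
        raise ValueError("x_left must be < x_right")
    if x_left < profile.positions[0] or x_right > profile.positions[-1]:
        raise ValueError("box edges outside the clipped profile")
    xg = np.linspace(-0.5, 0.5, grid_size)
    sample_at = x_left + (xg + 0.5) * (x_right - x_left)
    vals = np.empty((profile.values.shape[0], grid_size))
    for c in range(profile.values.shape[0]):
        v = np.interp(sample_at, profile.positions, profile.values[c])
        m = v.mean()
        if m <= 0:
            raise ValueError(f"channel {c} has nonpositive mean over the box")
        vals[c] = v / m
    return UnitBoxProfile(
        x=xg,
        values=vals,
        channel_names=list(profile.channel_names),
        source=profile.source,
    )


def fit_quadratic(x: np.ndarray, values: np.ndarray) -> QuadraticFit:
    """Least-squares fit of f(x) = a·x² + b (no linear term)."""
    x = np.asarray(x, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if x.size < 10:
        raise ValueError("need at least 10 samples for the quadratic fit")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate grid")
    A = np.column_stack([x**2, np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(A, values, rcond=None)
    return QuadraticFit(a=float(a), b=float(b))


def classify_profile(a: float, tolerance: float = CLASSIFICATION_TOLERANCE) -> str:
    """``center_enriched`` (a < −tol), ``homogeneous`` (|a| ≤ tol) or
    ``polar`` (a > tol)."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if a < -tolerance:
        return "center_enriched"
    if a > tolerance:
        return "polar"
    return "homogeneous"


def analyze_compartment(
    stack: ImageStack,
    roi: tuple[int, int, int, int] | None = None,
    organizer_channel: int | str = 0,
    tolerance: float = CLASSIFICATION_TOLERANCE,
    edge_k: float = 3.0,
    window: int = 40,
    grid_size: int = 101,
    background_window: int = 10,
    smooth_sigma: float = 2.0,
) -> dict:
    """Full chain: time average → projection → clip → maxima → unit box
    → per-channel quadratic fit and classification.

    Returns a dict with the unit-box profile, per-channel
    :class:`QuadraticFit` and classification, and the box edges.
    """
    org = stack.channel_index(organizer_channel)
    avg = time_average(stack)
    prof = project_long_axis(avg, roi, channel_names=list(stack.channel_names))
    clipped = detect_edges_and_clip(
        prof, org, k=edge_k, background_window=background_window,
        smooth_sigma=smooth_sigma,
    )
    x_left, x_right = locate_polar_maxima(clipped, org, window=window)
    unit = project_unit_box(clipped, x_left, x_right, grid_size)
    fits = {}
    classes = {}
    for c, name in enumerate(unit.channel_names):
        fit = fit_quadratic(unit.x, unit.values[c])
        fits[name] = fit
        classes[name] = classify_profile(fit.a, tolerance)
    return {
        "unit_profile": unit,
        "fits": fits,
        "classifications": classes,
        "box": (x_left, x_right),
    }
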