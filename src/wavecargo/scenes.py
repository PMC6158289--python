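"""Seeded synthetic two-channel fluorescence scenes.

Generates time-lapse stacks that carry the statistical structure the
analysis pipeline assumes — a self-organized "organizer" protein (MinDE-
like surface waves or pole-to-pole oscillations) in channel 0 and an
anticorrelated membrane cargo in channel 1 — together with full ground
truth, so every downstream stage can be validated without microscope
data.

Two cargo behaviours are modelled:

``transient``
    A peripheral binder in fast exchange with solution. Its membrane
    occupancy responds instantaneously to the organizer:
    ``C = baseline * (1 - κ · Dn)`` with ``Dn`` the min–max normalized
    organizer field of the same frame and ``κ ∈ [0, 1)`` the depletion
    strength. No mass constraint applies (the reservoir is the bulk).

``anchored``
    A lipid-anchored cargo that cannot detach on the wave timescale and
    only moves laterally. It obeys the conservative transport equation

        ∂C/∂t = ∇·( D_c ∇C + χ C ∇Dn )

    i.e. diffusion plus drift *down* the organizer gradient — the
    simplest mass-conserving realization of a propagating diffusion
    barrier. Integrated with an explicit conservative (finite-volume,
    upwind drift) scheme, so total cargo is conserved to solver
    tolerance under reflecting or periodic boundaries.

Imaging artifacts are layered onto the clean fields in a fixed order —
vignette illumination, exponential photobleaching, Poisson shot noise,
Gaussian read noise — and each layer can be disabled independently; the
all-off configuration returns the clean fields exactly.

Conventions (repo-wide): pixel coordinates are 0-based row-major; frame
indices 0-based; the wave travels along the column (x) axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .stack import ImageStack

Mode = Literal["planar", "collision", "spiral_like", "compartment"]
CargoMode = Literal["transient", "anchored"]

#: Noise layer settings used when a test or demo wants "realistic" imaging
#: conditions: a vignette comparable to the field of view, moderate shot
#: noise, 1-unit read noise and slow bleaching.
DEFAULT_NOISE = dict(
    illumination_sigma=80.0,
    photon_gain=5.0,
    read_noise_sigma=1.0,
    bleach_tau=400.0,
)


def default_noise(width: int, height: int, mode: str = "planar") -> dict:
    """Geometry-scaled version of :data:`DEFAULT_NOISE`.

    The vignette width tracks the imaged region: a full-field scene sees
    σ ≈ 0.85× its larger side, while a compartment ROI — a small crop of
    a much larger field of view — sees only the shallow tail of the
    instrument vignette (σ ≈ 2× the crop).
    """
    factor = 2.0 if mode == "compartment" else 0.85
    out = dict(DEFAULT_NOISE)
    out["illumination_sigma"] = factor * max(width, height)
    return out


@dataclass(frozen=True)
class SceneParams:
    """Full parameterization of a synthetic scene.

    Lengths are in pixels, times in frames; ``pixel_size`` (µm/px) and
    ``frame_interval`` (s) attach physical units for downstream stages.
    """

    mode: Mode = "planar"
    width: int = 96
    height: int = 96
    n_frames: int = 60
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    # organizer wave geometry
    wavelength: float = 48.0
    wave_speed: float = 1.0
    duty_cycle: float = 0.4
    organizer_background: float = 20.0
    organizer_amplitude: float = 100.0
    pulse_shape: Literal["asymmetric", "square"] = "asymmetric"
    oscillation_period: int = 20  # compartment mode only (frames)
    # cargo
    cargo_mode: CargoMode = "transient"
    cargo_baseline: float = 100.0
    depletion_strength: float = 0.4  # κ, transient mode
    cargo_diffusion: float = 1.0  # D_c, px²/frame
    barrier_coupling: float = 20.0  # χ, px²/frame
    forcing_off_frame: int | None = None
    # imaging artifacts (None / 0 disables a layer)
    illumination_sigma: float | None = None
    photon_gain: float | None = None
    read_noise_sigma: float = 0.0
    bleach_tau: float | None = None
    rng_seed: int = 0
    # numerics
    n_substeps: int | None = None  # None: choose stable step automatically
    compartment_margin: int = 10  # px of empty border in compartment mode

    def __post_init__(self) -> None:
        if not 0 <= self.depletion_strength < 1:
            raise ValueError("depletion strength κ must lie in [0, 1)")
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must lie in (0, 1)")
        if self.width < 8 or self.height < 8:
            raise ValueError("scene dimensions must be at least 8 px")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.mode == "planar" and self.wave_speed * self.n_frames < self.wavelength:
            raise ValueError(
                "planar scene must span at least one wavelength: "
                f"speed*frames = {self.wave_speed * self.n_frames:g} < "
                f"wavelength = {self.wavelength:g}"
            )
        if self.cargo_diffusion < 0 or self.barrier_coupling < 0:
            raise ValueError("D_c and χ must be nonnegative")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    clean_organizer: np.ndarray  # (T, H, W)
    clean_cargo: np.ndarray  # (T, H, W)
    true_mask: np.ndarray  # (T, H, W) bool — organizer above half amplitude
    total_cargo_mass: np.ndarray  # (T,)
    illumination_field: np.ndarray  # (H, W)
    bleach_factors: np.ndarray  # (T,)


# ---------------------------------------------------------------------------
# wave fields


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def pulse_profile(phase: np.ndarray, duty_cycle: float, shape: str) -> np.ndarray:
    """Periodic organizer pulse w(φ) ∈ [0, 1], period 1.

    The fraction of the period with w > 1/2 equals ``duty_cycle`` exactly
    (up to grid sampling). ``asymmetric`` uses a slow smooth rise, a
    plateau and a steep fall (front/rear asymmetry of a reaction wave
    with sharp rear detachment); ``square`` is the idealized on/off
    pulse for which closed-form masked statistics exist.
    """
    phi = np.asarray(phase, dtype=np.float64) % 1.0
    if shape == "square":
        return (phi < duty_cycle).astype(np.float64)
    if shape != "asymmetric":
        raise ValueError(f"unknown pulse shape {shape!r}")
    d = duty_cycle
    s = min(d, 1.0 - d)
    rise, fall = 0.25 * s, 0.0625 * s
    plateau = d - 0.15625 * s  # above-half-max time = rise/2 + plateau + fall/2 = d
    w = np.zeros_like(phi)
    m = phi < rise
    w[m] = _smoothstep(phi[m] / rise)
    m = (phi >= rise) & (phi < rise + plateau)
    w[m] = 1.0
    m = (phi >= rise + plateau) & (phi < rise + plateau + fall)
    w[m] = _smoothstep(1.0 - (phi[m] - rise - plateau) / fall)
    return w


def _planar_organizer(p: SceneParams, t: int) -> np.ndarray:
    x = np.arange(p.width, dtype=np.float64)
    phase = (p.wave_speed * t - x) / p.wavelength
    row = p.organizer_background + p.organizer_amplitude * pulse_profile(
        phase, p.duty_cycle, p.pulse_shape
    )
    return np.broadcast_to(row, (p.height, p.width)).copy()


def _collision_organizer(p: SceneParams, t: int) -> np.ndarray:
    """Two mirror-image wavetrains running into the midline, where a
    smooth taper (width λ/4) annihilates them."""
    x = np.arange(p.width, dtype=np.float64)
    mid = (p.width - 1) / 2.0
    xm = np.where(x <= mid, x, p.width - 1 - x)  # distance travelled toward mid
    phase = (p.wave_speed * t - xm) / p.wavelength
    w = pulse_profile(phase, p.duty_cycle, p.pulse_shape)
    taper = _smoothstep(np.abs(x - mid) / (p.wavelength / 4.0))
    row = p.organizer_background + p.organizer_amplitude * w * taper
    return np.broadcast_to(row, (p.height, p.width)).copy()


def _spiral_organizer(p: SceneParams, t: int) -> np.ndarray:
    yy, xx = np.mgrid[0 : p.height, 0 : p.width].astype(np.float64)
    cy, cx = (p.height - 1) / 2.0, (p.width - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    phase = (p.wave_speed * t - r) / p.wavelength + theta / (2.0 * np.pi)
    w = pulse_profile(phase, p.duty_cycle, p.pulse_shape)
    core = _smoothstep(r / (p.wavelength / 4.0))  # quench the singular core
    return p.organizer_background + p.organizer_amplitude * w * core


# Polar occupancy template for compartment mode: a Gaussian along the long
# axis peaking slightly inside each pole. σ = 0.30 of the axis keeps the
# time-averaged organizer dip pronounced while the graded occupancy stays
# shallow enough that a transient binder's time average is nearly flat.
_POLE_POS = 0.12
_POLE_SIGMA = 0.30


def _compartment_interior(p: SceneParams) -> tuple[slice, slice]:
    m = p.compartment_margin
    if p.height - 2 * m < 4 or p.width - 2 * m < 8:
        raise ValueError("compartment margin leaves no interior")
    return slice(m, p.height - m), slice(m, p.width - m)


def _compartment_organizer(p: SceneParams, t: int) -> np.ndarray:
    rows, cols = _compartment_interior(p)
    nx = cols.stop - cols.start
    u = np.arange(nx, dtype=np.float64) / (nx - 1)
    left_half = (t % p.oscillation_period) < p.oscillation_period / 2
    pole = _POLE_POS if left_half else 1.0 - _POLE_POS
    g = np.exp(-((u - pole) ** 2) / (2.0 * _POLE_SIGMA**2))
    field = np.zeros((p.height, p.width))
    field[rows, cols] = p.organizer_background + p.organizer_amplitude * g
    return field


_ORGANIZER = {
    "planar": _planar_organizer,
    "collision": _collision_organizer,
    "spiral_like": _spiral_organizer,
    "compartment": _compartment_organizer,
}


def _normalize(field: np.ndarray) -> np.ndarray:
    """Min–max normalization; a constant field maps to all zeros."""
    lo, hi = float(field.min()), float(field.max())
    if hi <= lo:
        return np.zeros_like(field)
    return (field - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# conservative cargo transport


def stable_step(D_c: float, chi: float, Dn: np.ndarray, cfl: float = 0.8) -> float:
    """Largest explicit time step (in frames) stable for diffusion D_c and
    drift χ·|∇Dn| on a unit grid, with safety factor ``cfl``."""
    gx = np.abs(np.diff(Dn, axis=1)).max(initial=0.0)
    gy = np.abs(np.diff(Dn, axis=0)).max(initial=0.0)
    rate = 4.0 * D_c + 2.0 * chi * (gx + gy)
    if rate <= 0:
        return np.inf
    return cfl / rate


def transport_step(
    C: np.ndarray,
    Dn: np.ndarray,
    D_c: float,
    chi: float,
    dt: float,
    boundary: str = "reflecting",
) -> np.ndarray:
    """One explicit finite-volume step of ∂C/∂t = ∇·(D_c∇C + χC∇Dn).

    Face fluxes use centered diffusion and first-order upwind drift;
    summing the divergence telescopes exactly, so total mass is conserved
    to floating-point accuracy for both boundary conditions.
    """
    if boundary == "periodic":

        def face_flux(axis: int) -> np.ndarray:
            Cn = np.roll(C, -1, axis=axis)
            dDn = np.roll(Dn, -1, axis=axis) - Dn
            v = -chi * dDn  # drift velocity at the face, down the gradient
            Cface = np.where(v > 0, C, Cn)
            return -D_c * (Cn - C) + v * Cface

        Fx = face_flux(1)
        Fy = face_flux(0)
        div = (Fx - np.roll(Fx, 1, axis=1)) + (Fy - np.roll(Fy, 1, axis=0))
        return C - dt * div

    if boundary != "reflecting":
        raise ValueError(f"unknown boundary {boundary!r}")

    out = C.copy()
    # interior faces only; domain faces carry zero flux
    for axis in (0, 1):
        sl_lo = [slice(None)] * 2
        sl_hi = [slice(None)] * 2
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        Clo, Chi = C[tuple(sl_lo)], C[tuple(sl_hi)]
        dDn = Dn[tuple(sl_hi)] - Dn[tuple(sl_lo)]
        v = -chi * dDn
        Cface = np.where(v > 0, Clo, Chi)
        F = -D_c * (Chi - Clo) + v * Cface
        out[tuple(sl_lo)] -= dt * F
        out[tuple(sl_hi)] += dt * F
    return out


def evolve_cargo(
    C: np.ndarray,
    Dn: np.ndarray,
    D_c: float,
    chi: float,
    duration: float,
    boundary: str,
    n_substeps: int | None = None,
    max_substeps: int = 100_000,
) -> np.ndarray:
    """Advance the cargo field by ``duration`` frames under a frozen
    organizer field, subcycling at a stable explicit step."""
    dt_max = stable_step(D_c, chi, Dn)
    if n_substeps is None:
        n = max(1, int(np.ceil(duration / dt_max))) if np.isfinite(dt_max) else 1
        if n > max_substeps:
            raise RuntimeError(
                f"stable step bound {dt_max:.3g} frames requires {n} substeps "
                f"per frame (> {max_substeps}); reduce D_c or χ"
            )
    else:
        n = n_substeps
        if duration / n > dt_max:
            raise ValueError(
                f"explicit scheme unstable: step {duration / n:.3g} exceeds the "
                f"stable-step bound {dt_max:.3g} frames for D_c={D_c:g}, χ={chi:g}"
            )
    dt = duration / n
    for _ in range(n):
        C = transport_step(C, Dn, D_c, chi, dt, boundary)
    return C


# ---------------------------------------------------------------------------
# scene assembly


def _boundary_for(mode: str) -> str:
    return "periodic" if mode == "planar" else "reflecting"


def _make_clean_fields(p: SceneParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clean organizer and cargo fields plus the true half-max mask."""
    organizer_fn = _ORGANIZER[p.mode]
    T, H, W = p.n_frames, p.height, p.width
    organizer = np.empty((T, H, W))
    cargo = np.empty((T, H, W))
    mask = np.empty((T, H, W), dtype=bool)

    if p.mode == "compartment":
        rows, cols = _compartment_interior(p)
    else:
        rows = cols = slice(None)
    boundary = _boundary_for(p.mode)

    C = None  # anchored cargo state on the active region
    for t in range(T):
        forced_off = p.forcing_off_frame is not None and t >= p.forcing_off_frame
        if forced_off:
            D = np.zeros((H, W))
            D[rows, cols] = p.organizer_background
        else:
            D = organizer_fn(p, t)
        organizer[t] = D
        mask[t] = D > p.organizer_background + 0.5 * p.organizer_amplitude

        Dn_active = _normalize(D[rows, cols])
        if p.cargo_mode == "transient":
            Ct = np.zeros((H, W))
            Ct[rows, cols] = p.cargo_baseline * (
                1.0 - p.depletion_strength * Dn_active
            )
            cargo[t] = Ct
        else:
            if C is None:
                C = np.full(Dn_active.shape, p.cargo_baseline)
            cargo[t] = 0.0
            cargo[t][rows, cols] = C
            # evolve to the next frame under this frame's (frozen) organizer
            chi = 0.0 if forced_off else p.barrier_coupling
            C = evolve_cargo(
                C,
                Dn_active,
                p.cargo_diffusion,
                chi,
                1.0,
                boundary,
                p.n_substeps,
            )
    return organizer, cargo, mask


def _apply_artifacts(
    p: SceneParams, organizer: np.ndarray, cargo: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Layer illumination → bleach → shot noise → read noise, in that
    fixed physical order, onto both channels."""
    T, H, W = organizer.shape
    rng = np.random.default_rng(p.rng_seed)

    if p.illumination_sigma:
        yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
        illum = np.exp(
            -((yy - (H - 1) / 2) ** 2 + (xx - (W - 1) / 2) ** 2)
            / (2.0 * p.illumination_sigma**2)
        )
    else:
        illum = np.ones((H, W))

    if p.bleach_tau:
        bleach = np.exp(-np.arange(T) / p.bleach_tau)
    else:
        bleach = np.ones(T)

    out = []
    for clean in (organizer, cargo):
        sig = clean * illum[None] * bleach[:, None, None]
        if p.photon_gain:
            sig = rng.poisson(sig * p.photon_gain).astype(np.float64) / p.photon_gain
        if p.read_noise_sigma:
            sig = sig + rng.normal(0.0, p.read_noise_sigma, sig.shape)
        out.append(np.clip(sig, 0.0, None))
    return out[0], out[1], illum, bleach


def generate_scene(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    """Generate the scene described by ``params``.

    Returns the noisy two-channel stack (channel 0 = organizer,
    channel 1 = cargo) and the full :class:`GroundTruth`. Identical
    params (including the seed) give bit-identical output.
    """
    organizer, cargo, mask = _make_clean_fields(params)
    noisy_org, noisy_cargo, illum, bleach = _apply_artifacts(params, organizer, cargo)
    pixels = np.stack([noisy_org, noisy_cargo], axis=1)
    stack = ImageStack(
        pixels=pixels,
        pixel_size=params.pixel_size,
        frame_interval=params.frame_interval,
        channel_names=["organizer", "cargo"],
    )
    truth = GroundTruth(
        clean_organizer=organizer,
        clean_cargo=cargo,
        true_mask=mask,
        total_cargo_mass=cargo.sum(axis=(1, 2)),
        illumination_field=illum,
        bleach_factors=bleach,
    )
    return stack, truth


def generate_planar_scene(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    if params.mode != "planar":
        raise ValueError("params.mode must be 'planar'")
    return generate_scene(params)


def generate_collision_scene(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    if params.mode != "collision":
        raise ValueError("params.mode must be 'collision'")
    return generate_scene(params)


def generate_spiral_scene(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    if params.mode != "spiral_like":
        raise ValueError("params.mode must be 'spiral_like'")
    return generate_scene(params)


def generate_compartment_scene(params: SceneParams) -> tuple[ImageStack, GroundTruth]:
    if params.mode != "compartment":
        raise ValueError("params.mode must be 'compartment'")
    return generate_scene(params)


# ---------------------------------------------------------------------------
# calibration scenes for the profile chain


def quadratic_compartment_stack(
    a: float,
    params: SceneParams | None = None,
    cargo_scale: float = 100.0,
) -> tuple[ImageStack, float]:
    """A compartment stack whose cargo channel is an *exact* quadratic
    a·x² + b on the organizer-defined unit box.

    The organizer channel carries the standard oscillation (so edge
    detection and polar-maximum localization run unchanged); the cargo
    channel is static, with b chosen as 1 − a/12 so the profile's mean
    over the box is exactly 1 and the mean-normalized fit should return
    ``a`` itself. Used to calibrate the full chain (project → clip →
    locate maxima → unit box → fit): any deviation of the fitted â from
    ``a`` measures chain error, not scene structure.

    Returns the stack and the true box half-width in pixels (from a
    fine-grid evaluation of the organizer time average).
    """
    p = params or default_params("compartment", "transient")
    b0 = 1.0 - a / 12.0
    if b0 + min(0.0, a) / 4.0 <= 0:
        raise ValueError("quadratic dips below zero on the unit box")
    rows, cols = _compartment_interior(p)
    nx = cols.stop - cols.start

    # analytic polar-maximum positions of the organizer time average
    uf = np.linspace(0.0, 1.0, 20001)
    gsum = np.exp(-((uf - _POLE_POS) ** 2) / (2 * _POLE_SIGMA**2)) + np.exp(
        -((uf - (1 - _POLE_POS)) ** 2) / (2 * _POLE_SIGMA**2)
    )
    half = gsum.size // 2
    u_left = uf[np.argmax(gsum[:half])]
    u_right = uf[half + np.argmax(gsum[half:])]

    u = np.arange(nx, dtype=np.float64) / (nx - 1)
    ux = (u - u_left) / (u_right - u_left) - 0.5  # unit-box coordinate
    cargo_row = cargo_scale * (a * ux**2 + b0)
    if np.any(cargo_row < 0):
        raise ValueError("quadratic extension negative inside the compartment")

    T = 2 * p.oscillation_period
    organizer = np.stack([_compartment_organizer(p, t) for t in range(T)])
    cargo = np.zeros_like(organizer)
    cargo[:, rows, cols] = cargo_row[None, None, :]
    stack = ImageStack(
        pixels=np.stack([organizer, cargo], axis=1),
        pixel_size=p.pixel_size,
        frame_interval=p.frame_interval,
        channel_names=["organizer", "cargo"],
    )
    return stack, (u_right - u_left) * (nx - 1) / 2.0


# ---------------------------------------------------------------------------
# study-condition presets


def default_params(mode: Mode, cargo_mode: CargoMode, **overrides) -> SceneParams:
    """Scene parameters representing the standard study conditions per
    geometry.

    Planar/collision/spiral scenes use a 48 px wavelength travelling at
    1 px/frame; compartments are rods (long axis ≈ 4× the short axis)
    oscillating pole-to-pole with a 20-frame period. The anchored-cargo
    coupling χ is set per geometry so the drift Péclet number χ·|∇Dn|/D_c
    is well above 1 — the strongly-excluded regime of a tightly anchored
    protein — given each geometry's organizer gradient scale.
    """
    base: dict = dict(mode=mode, cargo_mode=cargo_mode)
    if mode == "compartment":
        # interior 160×28 rod; shallow Gaussian occupancy -> weak gradients,
        # so a larger χ is needed to reach the same Péclet number
        base.update(
            width=180,
            height=48,
            n_frames=120,
            oscillation_period=20,
            barrier_coupling=8.0,
            cargo_diffusion=0.5,
            depletion_strength=0.15,
            wave_speed=0.0,
            wavelength=48.0,
        )
    elif mode == "collision":
        base.update(
            width=192,
            height=48,
            n_frames=200,
            wavelength=48.0,
            wave_speed=1.0,
            barrier_coupling=20.0,
            cargo_diffusion=1.0,
        )
    else:
        base.update(
            width=96,
            height=96,
            n_frames=60,
            wavelength=48.0,
            wave_speed=1.0,
            barrier_coupling=20.0,
            cargo_diffusion=1.0,
        )
    base.update(overrides)
    return SceneParams(**base)
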