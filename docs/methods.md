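# Methods

## The measurement problem

A reaction–diffusion system (the "organizer", MinDE in the motivating
experiments) self-organizes into traveling surface waves or, confined
in rod-shaped compartments, pole-to-pole oscillations. Other
membrane-bound proteins that do not take part in the reaction are
nevertheless redistributed: a peripheral binder in fast exchange with
solution is locally depleted wherever the organizer is dense, while a
lipid-anchored protein that cannot detach is laterally transported —
accumulating where waves collide, draining from spiral cores, and
piling up at mid-compartment under pole-to-pole oscillations. The
package quantifies both signatures from two-channel time-lapse stacks
and ships a generator that produces scenes with exactly these
statistical structures plus ground truth, so the whole chain is
testable without microscope data.

## Segmentation chain

Per frame, on the organizer channel only: a disc median filter (radius
default 4 px, the middle of the commonly used 3–6 px range), a
pseudo-flat-field correction — division by a Gaussian blur of the frame
(σ = radius, default 75 px) rescaled by the blur's mean so the global
intensity scale is preserved — then an automatic threshold on a 256-bin
histogram of the min–max-scaled frame. Pixels strictly above threshold
form the wave mask; ties go to the complement, so the two masks
partition the frame exactly. Masks are applied to the *original*
intensities downstream; the filtered image only defines geometry,
which also makes the masks invariant under global intensity scaling.

Two threshold criteria are provided. *Huang*: exhaustive scan of all
255 splits, minimizing total Shannon fuzziness with membership
u(g) = 1/(1 + |g − μ_class|/C); on clean bimodal histograms every split
inside the empty gap ties, and the tie is broken at the plateau middle
so the threshold sits mid-gap (on real, noisy histograms ties do not
occur). *Li*: the minimum-cross-entropy fixed-point iteration
t ← (μ_below − μ_above)/(ln μ_below − ln μ_above), stopped when
successive thresholds differ by < 0.5 bin; it converges in far fewer
than 64 iterations on any 256-bin histogram and is cross-checked in the
tests against an independent library implementation. The flat-field
rescaling convention (mean-preserving) is a dialect choice; thresholds
shift slightly with histogram binning, which is why the 256-bin
convention is fixed and recorded.

## Masked statistics

The per-frame means I (whole frame), I_min(MinD) (complement mask) and
I_max(MinD) (wave mask) use the mask-multiplication recipe: multiply
mask and image, drop **all** zero products, average the rest. Dropping
zero products removes out-of-mask pixels but also genuinely zero-valued
pixels inside the mask — an upward bias whenever true zeros exist. The
quirk is reproduced faithfully because it is part of the established
recipe; `drop_zeros=False` gives the plain mask-membership mean. The
contrast (I_min − I_max)/I_max is computed per frame and pooled;
pooling is deliberately unweighted across experiments (each experiment
contributes one mean regardless of its image count). Reference
normalization divides by the reference intensity and by the fluorescent
fraction, since the measured signal undercounts total protein by the
labeled fraction. Intensity ratios between conditions are formed on
per-condition mean statistics; a per-image variant would require paired
frames, which the acquisition scheme does not provide.

## Compartment profile analysis

The time-averaged stack is projected on the compartment long axis
(mean over the short axis; both ROI orientations are equivalent). The
compartment is located on the organizer profile: background mean and σ
come from windows at both profile ends, and the edges are the first and
last positions above background + k·σ (k = 3) whose lightly smoothed
(σ = 2 px) first derivative has the right sign. Profiles with no such
crossing are rejected, mirroring the manual exclusion of compartments
without oscillations. The two polar maxima are localized in two steps:
a quartic least-squares fit over the clipped profile provides rough
interior maxima; a parabola fitted in a 40 px window around each
estimate provides the refined vertex. The window is re-centered on each
vertex until convergence — for a locally symmetric peak the fixed point
has the window centered on the true maximum, where the parabola vertex
is unbiased; without re-centering the vertex inherits an O(1 px) bias
from the asymmetric window. An upward-opening parabola falls back to
the window's discrete argmax with a warning. The 40 px window
corresponds to the magnification of the motivating data and is
configurable.

Both channels are linearly remapped onto the organizer-defined unit box
x ∈ [−0.5, 0.5] (101-point grid, linear interpolation) and each is
divided by its own mean over the box, making the subsequent fit of
f(x) = a·x² + b dimensionless and comparable across compartments. The
centered coordinate is the only convention under which the sign rules
(a > 0 polar, a < 0 center-enriched) are meaningful for the symmetric
form a·x² + b. On a unit-length box, depth and curvature differ from a
only by constant prefactors (a/4 and 2a), so all three are reported.
Because published depth values depend on an unspecified intensity
normalization, no absolute comparison is claimed; the mean
normalization here is stated so results are reproducible within this
convention. The classification tolerance defaults to |a| ≤ 0.1 for
"homogeneous": comfortably above the fit noise of the chain (SD < 0.07
at profile noise σ = 0.05) and well below the polar/center-enriched
magnitudes (≈ 0.4–0.6) the study conditions produce.

## Kymographs, bleaching, wave parameters

Kymographs sample a line selection at 1 px steps with linear
interpolation, averaged over 3 perpendicular offsets by default. The
preprocessing used for display normalization blurs each frame and
divides it by its own mean (every output frame has mean 1, so global
intensity drift cancels). Bleach correction matches each frame's full
empirical intensity CDF to a reference frame — exact quantile mapping
on float data rather than an 8-bit histogram, which avoids quantization
plateaus; the operation is idempotent and inverts a pure global decay.

Wavelength and velocity come from the peak of the kymograph's 2D power
spectrum (Hann window, 4× zero-padding, parabolic peak interpolation on
log power; the zero-spatial-frequency column is excluded so global
flicker cannot win). Velocity is −f_t/f_x scaled by the calibration;
static stripes give exactly zero. This estimator is generic plumbing —
the motivating study does not specify how wave parameters were measured
— and recovers generator values to ≈ 0.1% on clean plane waves, with a
5% tolerance asserted.

## The synthetic generator

**Organizer fields.** A periodic pulse w(φ) ∈ [0, 1] with smoothstep
rise, plateau, and a 4× steeper smoothstep fall (front/rear asymmetry of
a reaction wave with sharp rear detachment). The rise and fall spans
(0.25·s and 0.0625·s of the period, s = min(duty, 1−duty)) are chosen
steep enough that automatic thresholding reproduces the half-max mask
to ≥ 95% of pixels per frame on clean scenes; by construction the
fraction of the period above half-max equals the duty cycle exactly for
any such split. A `square` pulse variant makes the organizer binary,
which is what gives the masked statistics closed forms. Geometries:
planar wavetrain (periodic boundaries); two mirror wavetrains
annihilating in a smooth taper of width λ/4 at the midline (collision);
an Archimedean spiral with a quenched core (spiral-like); and a
pole-to-pole oscillation — a Gaussian occupancy profile (σ = 0.30 of
the axis, peak 0.12 from each pole) alternating sides with a
configurable period inside a rod with an empty margin (reflecting
boundaries). The σ/peak choice makes the organizer time average dip at
mid-compartment by ~15% (fitted a ≈ +0.44, the scale reported for such
oscillations) while keeping the occupancy graded enough that a
transient binder's time average stays flat to ~1–2%.

**Cargo models.** The transient binder responds instantaneously,
C = baseline·(1 − κ·Dn), with Dn the min–max normalized organizer field
of the same frame and κ ∈ [0, 1); its membrane density genuinely drops
(the reservoir is the bulk), so presence/absence full-image ratios are
1 − κ·⟨Dn⟩. The anchored cargo obeys the conservative transport
equation ∂C/∂t = ∇·(D_c ∇C + χ C ∇Dn): plain lateral diffusion plus
drift *down* the organizer gradient. This is a modeling choice of the
generator — the simplest mass-conserving realization of a propagating
diffusion barrier — not a mechanistic claim. It is integrated with an
explicit finite-volume scheme (centered diffusion, first-order upwind
drift, unit grid), sub-stepped at 0.8× the stable explicit step; face
fluxes telescope, so total mass is conserved to machine precision under
both boundary conditions, and the organizer is frozen within each frame
interval. Forcing a too-coarse step raises an error naming the
stable-step bound.

**Default study conditions.** Planar/collision scenes: λ = 48 px,
speed 1 px/frame, duty 0.4, D_c = 1 px²/frame, χ = 20 px²/frame —
drift Péclet χ|∇Dn|/D_c ≫ 1, the strongly excluded regime of a tightly
anchored protein, which drags cargo with the moving organizer minima
toward the collision line (central-band enrichment ≈ 10×). Compartment
scenes: 180×48 px rod (160×28 interior), 20-frame oscillation period,
120 frames, D_c = 0.5, χ = 8, κ = 0.15. These values were fixed from
the Péclet reasoning above so the three expected signatures appear at
the magnitudes the motivating experiments report (organizer a ≈ +0.44,
anchored cargo a ≈ −0.52, transient cargo a ≈ −0.09); they are study
conditions, not fitting parameters. The timescale separation after a
forcing-off event (small scales equalize quickly, the large-scale
gradient over hundreds of frames) follows from pure diffusion and the
pattern's length scales; no quantitative separation is targeted because
none is specified.

**Imaging artifacts** are layered in the fixed physical order
illumination × signal → bleaching exp(−t/τ) → Poisson shot noise at the
stated gain (on the bleached, illuminated signal) → additive Gaussian
read noise (signal-independent), with negative values clipped at zero.
Each layer is independently disableable and the all-off configuration
returns the clean fields bit-exactly. The default noise preset scales
the vignette with the imaged region (σ ≈ 0.85× the field for full-field
scenes, 2× for compartment crops, which see only the shallow tail of
the instrument vignette). All randomness flows from a single integer
seed; identical parameters give bit-identical stacks.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: reaction kinetics of the organizer itself
(wave geometry is prescribed, not emergent), cargo crowding/saturation,
3D geometry and out-of-focus light, dye photophysics beyond exponential
bleaching, camera fixed-pattern noise, and stage drift. Segmentation
and profile results on real data additionally depend on focus quality
and debris that the scenes do not contain.

## Numerical and interface conventions

Pixel coordinates are 0-based row-major, frame indices 0-based, ROIs
half-open; waves travel along the column axis. Stacks are multi-page
TIFF, channel-major interleave per frame, 16-bit unsigned with a
configurable scale recorded in metadata; masks are 0/255 8-bit TIFF;
all tables are UTF-8 CSV with header rows; scene parameters and run
configs are YAML, and every pipeline output directory receives the
fully resolved config plus package version. Degenerate inputs follow
one rule: reject loudly (constant frames cannot be thresholded and are
flagged invalid and excluded from statistics; empty masks, all-zero
masked products, degenerate lines and missing compartment edges raise).
Problem sizes in tests and the acceptance script (96–192 px scenes,
60–360 frames, 20 seeds) were chosen as the smallest at which the
studied effects are comfortably resolved.
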