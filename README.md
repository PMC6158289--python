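# wavecargo

Quantification of how self-organized protein surface waves — MinDE-type
reaction–diffusion waves on supported lipid bilayers, or pole-to-pole
oscillations in rod-shaped microcompartments — spatially redistribute
*other* membrane-bound proteins ("cargo") that do not react with the
wave itself. The package is aimed at in-vitro reconstitution labs
imaging two-channel TIRF/confocal time-lapses (channel 1: the wave
"organizer", e.g. EGFP-MinD; channel 2: a cargo such as an mCherry–MTS
peripheral binder or lipid-anchored streptavidin), and at anyone who
wants to test such an analysis against ground truth before pointing it
at real data.

## What it computes

**Wave segmentation.** Per frame: disc median filter → pseudo-flat-field
correction (division by a wide Gaussian blur, mean-preserving) →
automatic histogram threshold (Huang fuzzy-entropy or Li minimum
cross-entropy, 256 bins) → two complementary binary masks: the wave
maximum max(MinD) and minimum min(MinD). Masks are applied to the
original, unfiltered intensities.

**Masked statistics and contrast.** Per frame and channel the three
means I, I_min(MinD), I_max(MinD) (mask multiplication with zero-product
removal, faithfully including its known quirk), and the wave contrast

    contrast = (I_min(MinD) − I_max(MinD)) / I_max(MinD)

which is positive for cargo anticorrelated with the organizer. Plus
condition ratios, normalization to a fluorescent reference standard with
fluorescent-fraction correction, per-experiment pooling (mean ± SD
across experiments), and a molecular surface-coverage helper
(density × footprint; 6.6×10³ µm⁻² of a 25 nm² tetramer covers 16.5% ≈
17% of the membrane).

**Compartment profiles.** Time average → projection on the compartment
long axis → edge clipping on the organizer signal → two-step polar
maxima localization (quartic fit, then a refined parabola in a 40 px
window) → both channels projected onto the organizer-defined unit box
x ∈ [−0.5, 0.5] and mean-normalized → least-squares fit of

    f(x) = a·x² + b

with curvature 2a and depth a/4. Classification: a > tol polar,
a < −tol center-enriched, |a| ≤ tol homogeneous (tol = 0.1).

**Kymographs.** Line-selection kymograph extraction, per-frame
blur-and-divide-by-mean normalization, photobleaching correction by
histogram matching against a reference frame, and a spectral
wavelength/velocity estimator.

**Synthetic scenes.** A seeded generator producing planar, colliding
and spiral-like wavetrains and oscillating compartments with two cargo
behaviours — a transient binder, C = baseline·(1 − κ·Dn), and a
mass-conserved anchored cargo obeying ∂C/∂t = ∇·(D_c ∇C + χ C ∇Dn)
(diffusion plus drift down the organizer gradient, a conservative
finite-volume scheme) — plus vignette illumination, exponential
bleaching, shot and read noise, and a forcing-off event emulating
organizer detachment. Every stage therefore has exact ground truth.

## Worked example

```python
import numpy as np
import wavecargo as wc

# a transient binder with 50% depletion under a planar wave
params = wc.default_params("planar", "transient",
                           pulse_shape="square", depletion_strength=0.5)
stack, truth = wc.generate_planar_scene(params)

masks = wc.segment_wave(stack, organizer_channel="organizer", method="huang")
stats = wc.compute_wave_stats(stack, masks)
print("agreement with ground truth:",
      round((masks.wave_mask == truth.true_mask).mean(), 3))
print("cargo contrast:", round(float(np.nanmean(wc.contrast(stats, "cargo"))), 3))
```

prints

```
agreement with ground truth: 0.997
cargo contrast: 0.993
```

With κ = 0.5 the cargo sits at baseline outside the wave and at half
baseline inside, so the exact contrast is κ/(1−κ) = 1.0; the fully
automatic pipeline lands within 1%. The same chain on real data is one
CLI call:

```
wavecargo wavestats movie.tif --channel 0 --method huang --outdir out/
```

The numbered scripts under `analysis/` run the complete study on
synthetic data — scene generation (`01`), wave contrast vs depletion
strength (`02`), compartment profile curvature and classification
(`03`), collision transport and wave-parameter recovery (`04`) — and
write their tables to `results/`.

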