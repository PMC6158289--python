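"""Directional transport at wave collisions and wave-parameter recovery.

Simulates counter-propagating wavetrains with lipid-anchored cargo:
cargo is dragged toward the collision midline (central-band enrichment),
and after a forcing-off event (organizer detachment) the pattern relaxes
by pure diffusion — small scales first, the large-scale gradient much
more slowly. Also recovers wavelength and speed of a planar wave from a
kymograph power spectrum. Writes results/transport_timeseries.csv and
results/wave_parameters.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import wavecargo as wc

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1

p = wc.default_params(
    "collision", "anchored", n_frames=360, forcing_off_frame=120, rng_seed=SEED
)
_, truth = wc.generate_collision_scene(p)
band = slice(int(p.width * 0.45), int(p.width * 0.55))
enrich = truth.clean_cargo[:, :, band].mean(axis=(1, 2)) / truth.clean_cargo.mean(
    axis=(1, 2)
)
var = truth.clean_cargo.var(axis=(1, 2))
ts = pd.DataFrame(
    {
        "frame": np.arange(p.n_frames),
        "central_band_enrichment": enrich,
        "cargo_spatial_variance": var,
        "forcing_off": np.arange(p.n_frames) >= p.forcing_off_frame,
    }
)
RESULTS.mkdir(exist_ok=True)
ts.to_csv(RESULTS / "transport_timeseries.csv", index=False)
print(f"Central-band enrichment just before detachment: "
      f"{enrich[p.forcing_off_frame - 1]:.2f}x the field mean.")
print(f"Variance {var.max():.1f} at detachment decays monotonically to "
      f"{var[-1]:.1f} ({100 * var[-1] / var.max():.1f}% of peak) after "
      f"{p.n_frames - p.forcing_off_frame} frames of free diffusion.")

rows = []
for wavelength, speed in ((40.0, 0.5), (50.0, 0.5), (50.0, 1.0)):
    pw = wc.default_params(
        "planar", "transient", wavelength=wavelength, wave_speed=speed,
        n_frames=120, width=128, height=32, rng_seed=SEED,
    )
    stack, _ = wc.generate_planar_scene(pw)
    ky = wc.extract_kymograph(stack, "organizer", (0, 16, 127, 16), width=3)
    wl, v = wc.estimate_wavelength_velocity(ky)
    rows.append(
        {
            "true_wavelength_px": wavelength,
            "true_speed_px_per_frame": speed,
            "recovered_wavelength_px": wl,
            "recovered_speed_px_per_frame": v,
        }
    )
    print(f"λ={wavelength:.0f} v={speed:.1f}  ->  recovered "
          f"λ={wl:.2f} v={v:.3f}")
pd.DataFrame(rows).to_csv(RESULTS / "wave_parameters.csv", index=False)
print(f"wrote {RESULTS / 'wave_parameters.csv'}")
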