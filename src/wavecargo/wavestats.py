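"""Masked intensity statistics of anticorrelated protein waves.

Given a two-channel stack and the complementary organizer masks, this
module computes, per frame and channel, the three mean intensities the
wave analysis is built on —

* ``I_full``       — mean over the whole image,
* ``I_min_minD``   — mean over the organizer *minimum* (complement mask),
* ``I_max_minD``   — mean over the organizer *maximum* (wave mask),

— and the derived quantities: the wave **contrast**
``(I_min(MinD) − I_max(MinD)) / I_max(MinD)`` (positive for a cargo
anticorrelated with the organizer), condition-to-condition intensity
ratios, normalization to a fluorescent reference standard, and pooling
of per-image means into per-experiment means with across-experiment
mean ± SD.

The masked means reproduce a quirk of the original mask-multiplication
recipe: the mask is multiplied into the image and *all zero products*
are dropped before averaging — which removes out-of-mask pixels but
also genuinely zero-valued pixels inside the mask. The faithful
behaviour is the default; ``drop_zeros=False`` gives the plain
mask-membership mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import WaveMaskPair
from .stack import ImageStack


@dataclass
class WaveIntensityStats:
    """Per-frame masked means for every channel of a stack.

    ``frame`` holds one row per (frame, channel) with columns
    ``I_full``, ``I_min_minD``, ``I_max_minD`` and ``valid``.
    """

    frame: pd.DataFrame
    channel_names: list[str]

    def values(self, channel: int | str, column: str, valid_only: bool = True) -> np.ndarray:
        ch = self._index(channel)
        df = self.frame[self.frame["channel"] == ch]
        if valid_only:
            df = df[df["valid"]]
        return df[column].to_numpy()

    def _index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_names.index(channel)
        return int(channel)


@dataclass
class PooledResult:
    """Unweighted pooling of per-experiment means."""

    group_means: dict[str, float]
    grand_mean: float
    sd: float | None  # across experiments; None for a single experiment
    n_experiments: int
    n_images: int


def masked_mean_zero_removed(
    image: np.ndarray, mask: np.ndarray, drop_zeros: bool = True
) -> float:
    """Mean intensity under a binary mask, via mask multiplication.

    With ``drop_zeros=True`` (faithful recipe) the pixelwise product of
    image and mask is formed and every zero product is discarded before
    averaging; note this also discards zero-valued pixels *inside* the
    mask, biasing the mean upward when such pixels exist. With
    ``drop_zeros=False`` all in-mask pixels are averaged.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not np.any(mask):
        raise ValueError("mask is empty")
    if drop_zeros:
        product = image * (mask != 0)
        kept = product[product != 0]
        if kept.size == 0:
            raise ValueError("all masked products are zero; no signal in mask")
        return float(kept.mean())
    return float(image[mask != 0].mean())


def compute_wave_stats(
    stack: ImageStack, masks: WaveMaskPair, drop_zeros: bool = True
) -> WaveIntensityStats:
    """The three masked means per frame and channel.

    Frames flagged invalid by segmentation, or whose masked region
    carries no signal, are excluded from statistics (``valid=False``)
    but kept in the table for bookkeeping.
    """
    if masks.n_frames != stack.n_frames:
        raise ValueError(
            f"mask frames ({masks.n_frames}) do not align with stack frames "
            f"({stack.n_frames})"
        )
    rows = []
    for t in range(stack.n_frames):
        for c in range(stack.n_channels):
            img = stack.pixels[t, c]
            row = {
                "frame": t,
                "channel": c,
                "I_full": np.nan,
                "I_min_minD": np.nan,
                "I_max_minD": np.nan,
                "valid": False,
            }
            if masks.valid[t]:
                try:
                    row["I_full"] = float(img.mean())
                    row["I_min_minD"] = masked_mean_zero_removed(
                        img, masks.complement_mask[t], drop_zeros
                    )
                    row["I_max_minD"] = masked_mean_zero_removed(
                        img, masks.wave_mask[t], drop_zeros
                    )
                    row["valid"] = True
                except ValueError:
                    pass
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df["valid"].any():
        raise ValueError("no valid frames")
    return WaveIntensityStats(frame=df, channel_names=list(stack.channel_names))


def contrast(stats: WaveIntensityStats, channel: int | str) -> np.ndarray:
    """Per-frame wave contrast ``(I_min(MinD) − I_max(MinD)) / I_max(MinD)``.

    Positive when the channel is anticorrelated with the organizer
    (signal accumulates in the organizer minima); the organizer itself,
    measured on its own masks, gives a negative value. Frames with a
    nonpositive denominator yield NaN.
    """
    i_min = stats.values(channel, "I_min_minD")
    i_max = stats.values(channel, "I_max_minD")
    out = np.full(i_min.shape, np.nan)
    ok = i_max > 0
    out[ok] = (i_min[ok] - i_max[ok]) / i_max[ok]
    return out


def intensity_ratio(
    stats_with: WaveIntensityStats,
    stats_without: WaveIntensityStats,
    channel: int | str,
) -> dict[str, float]:
    """Ratio of mean intensities between two conditions (e.g. cargo in
    the presence over the absence of the organizer), per statistic."""
    out = {}
    for col in ("I_full", "I_min_minD", "I_max_minD"):
        num = stats_with.values(channel, col)
        den = stats_without.values(channel, col)
        if num.size == 0 or den.size == 0:
            raise ValueError("empty statistics")
        d = float(np.nanmean(den))
        if d <= 0:
            raise ValueError(f"nonpositive denominator for {col}")
        out[col] = float(np.nanmean(num)) / d
    return out


def normalize_to_reference(
    values: np.ndarray | float,
    reference_value: float,
    fluorescent_fraction: float = 1.0,
):
    """Normalize intensities to a fluorescent reference standard and
    correct for the fraction of molecules that are fluorescent.

    The measured intensity underestimates total protein by the labeled
    fraction, hence the division: ``value / reference / fraction``.
    """
    if reference_value <= 0:
        raise ValueError("reference must be positive")
    if not 0 < fluorescent_fraction <= 1:
        raise ValueError("fluorescent_fraction must lie in (0, 1]")
    return np.asarray(values, dtype=np.float64) / reference_value / fluorescent_fraction


def pool_experiments(grouped_values: dict[str, "np.ndarray | list"]) -> PooledResult:
    """Pool per-image values into per-experiment means, then an
    unweighted grand mean and sample SD across experiments.

    Each key is an independent experiment; each value the per-image
    means from that experiment. SD is reported only for ≥ 2 experiments.
    """
    if not grouped_values:
        raise ValueError("need at least one experiment group")
    means = {}
    n_images = 0
    for name, vals in grouped_values.items():
        arr = np.asarray(vals, dtype=np.float64)
        if arr.size == 0:
            raise ValueError(f"experiment group {name!r} is empty")
        means[name] = float(arr.mean())
        n_images += arr.size
    mvals = np.array(list(means.values()))
    sd = float(mvals.std(ddof=1)) if len(mvals) >= 2 else None
    return PooledResult(
        group_means=means,
        grand_mean=float(mvals.mean()),
        sd=sd,
        n_experiments=len(mvals),
        n_images=n_images,
    )


def coverage_fraction(density_per_um2: float, footprint_nm2: float) -> float:
    """Percent of membrane area covered by molecules of the given
    footprint at the given surface density (1 µm² = 10⁶ nm²)."""
    if density_per_um2 < 0:
        raise ValueError("density must be nonnegative")
    if footprint_nm2 <= 0:
        raise ValueError("footprint must be positive")
    return density_per_um2 * footprint_nm2 / 1e6 * 100.0


def stats_table(stats: WaveIntensityStats) -> pd.DataFrame:
    """Long-format CSV-ready table with per-frame contrast appended."""
    df = stats.frame.copy()
    df["contrast"] = (df["I_min_minD"] - df["I_max_minD"]) / df["I_max_minD"]
    df.loc[~df["valid"], "contrast"] = np.nan
    df["channel_name"] = [stats.channel_names[c] for c in df["channel"]]
    return df
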