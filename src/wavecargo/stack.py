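"""Multi-frame, multi-channel image stacks with physical calibration.

The :class:`ImageStack` is the common currency of every analysis stage:
a ``(frame, channel, row, col)`` float array plus the pixel size (µm/px)
and frame interval (s) needed to express results in physical units.

On disk a stack is a multi-page TIFF with channel-major interleave per
frame: page order is ``frame0/ch0, frame0/ch1, ..., frame1/ch0, ...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Pixel data indexed (frame, channel, row, col) with calibration.

    Parameters
    ----------
    pixels : ndarray, shape (T, C, H, W)
        Nonnegative intensities (any dtype; analysis uses float64).
    pixel_size : float
        Lateral calibration in µm per pixel; strictly positive.
    frame_interval : float
        Time between frames in seconds; strictly positive.
    channel_names : list of str
        One name per channel, e.g. ``["organizer", "cargo"]``.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be 4-D (frame, channel, row, col), got {self.pixels.ndim}-D"
            )
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be strictly positive")
        if np.any(np.asarray(self.pixels) < 0):
            raise ValueError("intensities must be nonnegative")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.pixels.shape[1])]
        if len(self.channel_names) != self.pixels.shape[1]:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.pixels.shape

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        if not 0 <= channel < self.n_channels:
            raise KeyError(f"channel index {channel} out of range [0, {self.n_channels})")
        return int(channel)

    def channel(self, channel: int | str) -> np.ndarray:
        """Return the (T, H, W) array for one channel."""
        return self.pixels[:, self.channel_index(channel)]

    def scaled(self, factor: float) -> "ImageStack":
        return replace(self, pixels=self.pixels * factor)


def write_stack(path, stack: ImageStack, scale: float | None = None) -> None:
    """Write a stack as a multi-page 16-bit TIFF (channel-major interleave).

    ``scale`` maps intensity units to the uint16 range; by default the
    stack maximum is mapped to 60000 so moderate over-range noise does
    not clip.
    """
    pix = np.asarray(stack.pixels, dtype=np.float64)
    if scale is None:
        peak = float(pix.max())
        scale = 60000.0 / peak if peak > 0 else 1.0
    pages = np.clip(pix * scale, 0, 65535).astype(np.uint16)
    t, c, h, w = pages.shape
    tifffile.imwrite(
        path,
        pages.reshape(t * c, h, w),
        metadata={
            "axes": "QYX",
            "wavecargo_n_channels": c,
            "wavecargo_pixel_size_um": stack.pixel_size,
            "wavecargo_frame_interval_s": stack.frame_interval,
            "wavecargo_channel_names": ",".join(stack.channel_names),
            "wavecargo_scale": scale,
        },
    )


def read_stack(
    path,
    n_channels: int | None = None,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    channel_names: list[str] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Pages are de-interleaved channel-major (all channels of frame 0, then
    frame 1, ...). Calibration is taken from metadata written by
    :func:`write_stack` when present, else from the arguments; missing
    both is an error.
    """
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
        elif tif.imagej_metadata:
            meta = dict(tif.imagej_metadata)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]

    if n_channels is None:
        n_channels = int(meta.get("wavecargo_n_channels", 0)) or None
    if n_channels is None:
        raise ValueError("n_channels not in metadata and not supplied")
    if n_pages % n_channels:
        raise ValueError(
            f"page count {n_pages} is not divisible by channel count {n_channels}"
        )
    pix = pages.reshape(n_pages // n_channels, n_channels, *pages.shape[1:]).astype(
        np.float64
    )

    if pixel_size is None:
        pixel_size = meta.get("wavecargo_pixel_size_um")
    if frame_interval is None:
        frame_interval = meta.get("wavecargo_frame_interval_s")
    if pixel_size is None or frame_interval is None:
        raise ValueError(
            "pixel_size / frame_interval missing from both metadata and arguments"
        )
    if channel_names is None and "wavecargo_channel_names" in meta:
        channel_names = str(meta["wavecargo_channel_names"]).split(",")

    return ImageStack(
        pixels=pix,
        pixel_size=float(pixel_size),
        frame_interval=float(frame_interval),
        channel_names=channel_names or [],
    )
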