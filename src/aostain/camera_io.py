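"""Camera-aware micrograph I/O and preprocessing.

Widefield fluorescence images come from an 8-bit Bayer-sensor colour
camera operated with linear response (gamma 1), fixed colour balance and a
fixed dark offset.  Because the sensor records only one colour per photo
site and the firmware fills the missing colours by nearest-neighbour
copying within each 2x2 tile, chromatic resolution is half the pixel
count; analysis therefore downsamples by a factor of two in each dimension
before computing statistics.

The processing chain implemented here is::

    load_image -> downsample -> subtract_dark

after which the channels are ready for masking and ratiometrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .exceptions import DimensionError, FormatError, ParameterError, StateError

__all__ = ["CameraConfig", "ChannelStack", "load_image", "save_image",
           "downsample", "subtract_dark"]

# TIFF compression tags that discard information; lossless schemes pass.
_LOSSY_COMPRESSIONS = {6, 7, 34892}  # OJPEG, JPEG, lossy JPEG (DNG)


@dataclass(frozen=True)
class CameraConfig:
    """Sensor/acquisition model for the widefield camera.

    Attributes
    ----------
    dark_level : float
        Dark (bias) offset in counts, identical for all three channels;
        measured with the dust cover on.  Subtracted before any ratio.
    bayer_group : tuple
        Composition of one 2x2 sensor tile; two green, one red, one blue
        photosite.  Recorded to document why x2 downsampling is applied.
    color_balance : tuple
        (red, blue) balance multipliers as configured on the camera.
        Informational provenance only — the analysis operates on images as
        saved and never undoes the balance.
    gamma : float
        Response exponent; must be 1 (linear) for ratios of counts to be
        ratios of intensities.
    bit_depth : int
        Full-scale count of the stored image (255 for 8-bit).
    """

    dark_level: float = 12.0
    bayer_group: tuple[str, str, str, str] = ("green", "green", "red", "blue")
    color_balance: tuple[float, float] = (550.0, 800.0)
    gamma: float = 1.0
    bit_depth: int = 255

    def __post_init__(self) -> None:
        if self.gamma != 1:
            raise ParameterError(
                f"gamma must be 1 (linear response), got {self.gamma}"
            )
        if not (0 <= self.dark_level < self.bit_depth):
            raise ParameterError(
                f"dark_level must lie in [0, bit_depth), got {self.dark_level}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CameraConfig":
        """Load a config from YAML (keys dark_level, gamma, color_balance, bit_depth)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("dark_level", "gamma", "bit_depth"):
            if key in raw:
                kwargs[key] = raw[key]
        if "color_balance" in raw:
            kwargs["color_balance"] = tuple(raw["color_balance"])
        return cls(**kwargs)


@dataclass(frozen=True)
class ChannelStack:
    """Three equal-shaped channel rasters plus a processing provenance trail."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise DimensionError("channel rasters must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def dark_subtracted(self) -> bool:
        return any(step.startswith("subtract_dark") for step in self.provenance)

    def channels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.red, self.green, self.blue


def load_image(path: str | Path, config: CameraConfig | None = None) -> ChannelStack:
    """Read an uncompressed 8-bit RGB TIFF into a ChannelStack.

    No value transformation is applied; channels are returned as float64
    copies of the stored counts.

    Raises
    ------
    FormatError
        For grayscale/non-RGB images, bit depths other than 8, or lossy
        compression.
    DimensionError
        For odd image dimensions (incomplete Bayer groups).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        comp = page.compression
        if int(comp) in _LOSSY_COMPRESSIONS:
            raise FormatError(f"{path.name}: lossy compression ({comp!r}) is not supported")
        data = page.asarray()
    if data.ndim != 3 or data.shape[2] < 3:
        raise FormatError(f"{path.name}: expected an RGB image, got shape {data.shape}")
    if data.dtype != np.uint8:
        raise FormatError(f"{path.name}: expected 8-bit data, got {data.dtype}")
    h, w = data.shape[:2]
    if h % 2 or w % 2:
        raise DimensionError(f"{path.name}: dimensions must be even, got {h}x{w}")
    chans = [data[:, :, i].astype(np.float64) for i in range(3)]
    return ChannelStack(red=chans[0], green=chans[1], blue=chans[2],
                        provenance=(f"load:{path}",))


def save_image(stack_or_array, path: str | Path) -> Path:
    """Write an uncompressed 8-bit RGB TIFF.

    Accepts either a ChannelStack (values are rounded and clipped to
    [0, 255]) or an (H, W, 3) uint8 array.
    """
    path = Path(path)
    if isinstance(stack_or_array, ChannelStack):
        rgb = np.stack(stack_or_array.channels(), axis=-1)
        rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    else:
        rgb = np.asarray(stack_or_array)
        if rgb.dtype != np.uint8 or rgb.ndim != 3 or rgb.shape[2] != 3:
            raise FormatError("expected an (H, W, 3) uint8 array")
    tifffile.imwrite(path, rgb, compression=None, photometric="rgb")
    return path


def _block_mean(channel: np.ndarray) -> np.ndarray:
    h, w = channel.shape
    return channel.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def downsample(stack: ChannelStack) -> ChannelStack:
    """Halve both dimensions by 2x2 block averaging.

    The Bayer tile pattern means each 2x2 group carries a single true
    chromatic sample per colour; the block mean collapses the firmware's
    duplicated values back to the sensor's real resolution while
    preserving mean intensity (plain decimation would privilege one
    sub-pixel of the tile).
    """
    h, w = stack.shape
    if h % 2 or w % 2:
        raise DimensionError(f"dimensions must be even to downsample, got {h}x{w}")
    return ChannelStack(
        red=_block_mean(stack.red),
        green=_block_mean(stack.green),
        blue=_block_mean(stack.blue),
        provenance=stack.provenance + ("downsample:2x2-mean",),
    )


def subtract_dark(stack: ChannelStack, config: CameraConfig) -> ChannelStack:
    """Subtract the camera dark offset from every channel, clipping at zero.

    Clipping: photon counts are non-negative by construction, so the rare
    pixels that fall below the dark level (read noise) are set to 0 rather
    than carried as negative intensities.

    Raises
    ------
    StateError
        If the stack has already been dark-subtracted (the offset must be
        removed exactly once).
    """
    if stack.dark_subtracted:
        raise StateError("stack is already dark-subtracted")
    dark = float(config.dark_level)
    return ChannelStack(
        red=np.maximum(stack.red - dark, 0.0),
        green=np.maximum(stack.green - dark, 0.0),
        blue=np.maximum(stack.blue - dark, 0.0),
        provenance=stack.provenance + (f"subtract_dark:{dark:g}",),
    )


def preprocess(path: str | Path, config: CameraConfig | None = None) -> ChannelStack:
    """Full preprocessing chain: load, downsample, dark-subtract."""
    cfg = config or CameraConfig()
    return subtract_dark(downsample(load_image(path, cfg)), cfg)
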