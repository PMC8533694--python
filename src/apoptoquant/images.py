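"""Calibrated image containers shared across the pipeline.

A confocal acquisition enters the pipeline as a 3D :class:`ImageStack`
(z, y, x), is flattened to a 2D :class:`CalibratedImage` by z-projection,
and leaves segmentation as a :class:`BinaryMask`.  All three carry the
lateral pixel size in micrometres because object-size filters are
specified in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "CalibratedImage", "BinaryMask"]

#: accepted integer bit depths; anything else is stored as float
INTEGER_DEPTHS = (8, 16)


@dataclass
class ImageStack:
    """A single-channel 3D intensity volume with physical calibration.

    Parameters
    ----------
    voxels:
        Array of shape ``(n_z, height, width)`` with non-negative intensities.
    pixel_size_um:
        Lateral calibration in micrometres per pixel (x and y assumed equal).
    z_step_um:
        Axial spacing, informational only.
    bit_depth:
        8, 16 or the string ``"float"``.  Integer depths bound intensities by
        ``2**bit_depth - 1``.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float = 1.0
    bit_depth: int | str = 16
    image_id: str = ""
    channel: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a (z, y, x) array with >= 1 slice")
        if self.pixel_size_um is None or not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        if self.bit_depth in INTEGER_DEPTHS:
            limit = 2 ** int(self.bit_depth) - 1
            if np.any(self.voxels > limit):
                raise ValueError(
                    f"intensities exceed 2**{self.bit_depth}-1 for the stated bit depth"
                )

    @property
    def n_slices(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]


@dataclass
class CalibratedImage:
    """A 2D floating-point image with calibration and processing provenance."""

    pixels: np.ndarray
    pixel_size_um: float
    image_id: str = ""
    channel: str = ""
    group: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D (y, x) array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    def with_pixels(self, pixels: np.ndarray, step: str) -> "CalibratedImage":
        """Return a copy holding ``pixels`` with ``step`` appended to provenance."""
        return CalibratedImage(
            pixels=pixels,
            pixel_size_um=self.pixel_size_um,
            image_id=self.image_id,
            channel=self.channel,
            group=self.group,
            provenance=[*self.provenance, step],
        )


@dataclass
class BinaryMask:
    """Boolean foreground mask produced by thresholding or ROI rasterization."""

    pixels: np.ndarray
    pixel_size_um: float = 1.0
    image_id: str = ""
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != bool:
            self.pixels = self.pixels.astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.pixels.shape)  # type: ignore[return-value]

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        if self.shape != other.shape:
            raise ValueError("mask shapes differ")
        return BinaryMask(
            pixels=self.pixels & other.pixels,
            pixel_size_um=self.pixel_size_um,
            image_id=self.image_id,
            threshold_used=self.threshold_used,
        )
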