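"""Noise reduction and z-projection.

Rank/linear filtering runs per slice *before* projection, mirroring the
protocol this package automates: a median filter of radius 1 erases isolated
aberrant-high pixels (their value never enters the neighbourhood median),
whereas a mean filter spreads them into their neighbours.  Projection then
flattens the monolayer stack to the 2D image on which thresholds are set.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .images import CalibratedImage, ImageStack

__all__ = ["mean_filter", "median_filter", "z_project", "PROJECTION_METHODS"]

PROJECTION_METHODS = ("average", "max", "sum")

_Image = Union[ImageStack, CalibratedImage]


def _windowed(pixels: np.ndarray, radius: int) -> np.ndarray:
    """(h, w, k, k) view of replicate-padded square neighbourhoods."""
    padded = np.pad(np.asarray(pixels, dtype=float), radius, mode="edge")
    k = 2 * radius + 1
    return sliding_window_view(padded, (k, k))


def _mean_plane(pixels: np.ndarray, radius: int) -> np.ndarray:
    return _windowed(pixels, radius).mean(axis=(-2, -1))


def _median_plane(pixels: np.ndarray, radius: int) -> np.ndarray:
    # rank selection over an odd-sized window: ndimage is exact and fast;
    # mode="nearest" is replicate-edge padding
    return ndimage.median_filter(
        np.asarray(pixels, dtype=float), size=2 * radius + 1, mode="nearest"
    )


def _apply_filter(img: _Image, radius: int, plane_filter, name: str) -> _Image:
    if not isinstance(radius, (int, np.integer)) or radius < 1:
        raise ValueError("radius must be an integer >= 1")
    if isinstance(img, ImageStack):
        out = np.stack([plane_filter(plane, radius) for plane in img.voxels])
        return ImageStack(
            voxels=out,
            pixel_size_um=img.pixel_size_um,
            z_step_um=img.z_step_um,
            bit_depth="float",
            image_id=img.image_id,
            channel=img.channel,
            group=img.group,
        )
    if isinstance(img, CalibratedImage):
        out = plane_filter(img.pixels, radius)
        return img.with_pixels(out, f"{name}_filter(r={radius})")
    raise TypeError(f"unsupported image type {type(img).__name__}")


def mean_filter(img: _Image, radius: int = 1) -> _Image:
    """Arithmetic mean over the (2r+1)x(2r+1) Chebyshev neighbourhood.

    Each output pixel is the mean of its value and those of all pixels within
    Chebyshev distance ``radius``, per slice, with replicate-edge padding.
    Aberrant high values are attenuated but leak into every window that
    contains them, artificially raising neighbour intensities.
    """
    return _apply_filter(img, radius, _mean_plane, "mean")


def median_filter(img: _Image, radius: int = 1) -> _Image:
    """Median over the (2r+1)x(2r+1) Chebyshev neighbourhood.

    The neighbourhood median is insensitive to a single extreme value, so an
    isolated hot pixel is removed outright (for ``radius=1`` the median of
    one extreme and eight background values is a background value) while
    object edges are preserved.
    """
    return _apply_filter(img, radius, _median_plane, "median")


def z_project(stack: ImageStack, method: str = "max") -> CalibratedImage:
    """Reduce a stack to 2D by per-pixel ``average``, ``max`` or ``sum`` over z.

    Max projection keeps the brightest value along each z-column, enhancing
    contrast between monolayer objects and background; average dilutes signal
    confined to a few slices; sum equals ``n_slices`` times the average.
    """
    if method not in PROJECTION_METHODS:
        raise ValueError(f"unknown projection method {method!r}; use one of {PROJECTION_METHODS}")
    vox = stack.voxels.astype(float)
    if method == "average":
        out = vox.mean(axis=0)
    elif method == "max":
        out = vox.max(axis=0)
    else:
        out = vox.sum(axis=0)
    return CalibratedImage(
        pixels=out,
        pixel_size_um=stack.pixel_size_um,
        image_id=stack.image_id,
        channel=stack.channel,
        group=stack.group,
        provenance=[f"z_project({method})"],
    )
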