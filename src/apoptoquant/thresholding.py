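"""Intensity histograms, automatic threshold algorithms and binarization.

Thresholding is the step with the most dramatic effect on quantification
accuracy: the chosen cutoff T defines the foreground (pixels strictly above
T turn white) and therefore the objects that get counted and measured.

Four classic histogram algorithms are implemented here from their defining
equations, operating on an :class:`IntensityHistogram` rather than on raw
pixels so the same code serves 8-bit, 12-bit-in-16 and float images:

``otsu``
    maximizes the between-class variance w0*w1*(mu0-mu1)^2 over all split
    points (computed in exact integer arithmetic — counts are integers — so
    the lowest-tie rule is deterministic, not float-luck).
``moments``
    Tsai's moment-preserving selection: find the two-level image whose first
    three moments match the input's, and place T at the bin where the
    cumulative fraction reaches the background fraction p0.
``isodata``
    iterate T <- (mean below + mean above) / 2 to a fixed point.
``intermode``
    smooth the histogram with a 3-bin moving average until exactly two local
    modes remain; T is the midpoint of the two modes.

A per-experiment consensus ("median of the medians per group") is provided
for applying one unique threshold to every image without letting a group
with a larger headcount dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .images import BinaryMask, CalibratedImage

__all__ = [
    "IntensityHistogram",
    "ThresholdRecord",
    "DegenerateHistogramError",
    "compute_histogram",
    "auto_threshold",
    "consensus_threshold",
    "binarize",
    "AUTO_METHODS",
]

AUTO_METHODS = ("otsu", "moments", "isodata", "intermode")

#: all admissible ThresholdRecord methods
THRESHOLD_METHODS = ("manual", *AUTO_METHODS, "consensus")


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has fewer than two occupied bins."""


@dataclass
class IntensityHistogram:
    """Binned intensity counts over a stated range.

    ``bin_edges`` has ``n_bins + 1`` ascending values; bin *i* covers
    ``[edges[i], edges[i+1])`` except the last bin, which is closed so the
    image maximum is counted.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    total: int
    source_range: tuple[float, float]
    degenerate: bool = False  # constant source: single-value range, flagged

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.bin_edges.ndim != 1:
            raise ValueError("counts and bin_edges must be 1D")
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need n_bins + 1 edges")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != int(self.total):
            raise ValueError("sum(counts) must equal total")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def occupied(self) -> np.ndarray:
        return np.flatnonzero(self.counts > 0)

    @classmethod
    def from_counts(
        cls, counts: Sequence[int], low: float = 0.0, high: float | None = None
    ) -> "IntensityHistogram":
        """Build a histogram directly from bin counts (unit-width bins by default)."""
        counts = np.asarray(counts)
        if high is None:
            high = low + len(counts)
        edges = np.linspace(low, high, len(counts) + 1)
        return cls(edges, counts, int(counts.sum()), (low, high))


def compute_histogram(
    img: CalibratedImage | np.ndarray,
    n_bins: int = 256,
    mask: BinaryMask | np.ndarray | None = None,
) -> IntensityHistogram:
    """Equal-width histogram of the (optionally ROI-masked) image.

    The range spans [min, max] of the selected pixels; values equal to the
    maximum fall in the last bin.  Restricting the histogram to a region of
    interest keeps bright artifacts outside the zone from weighing on
    algorithmic threshold determination.
    """
    pixels = img.pixels if isinstance(img, CalibratedImage) else np.asarray(img, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if mask is not None:
        m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
        if m.shape != pixels.shape:
            raise ValueError("mask shape does not match image")
        pixels = pixels[m]
        if pixels.size == 0:
            raise ValueError("mask selects no pixels")
    vmin = float(pixels.min())
    vmax = float(pixels.max())
    if vmin == vmax:
        # constant source: all counts in the first bin over a unit range,
        # flagged degenerate so auto-thresholding refuses it downstream
        counts, edges = np.histogram(pixels, bins=n_bins, range=(vmin, vmin + 1.0))
        return IntensityHistogram(
            edges, counts, int(counts.sum()), (vmin, vmax), degenerate=True
        )
    counts, edges = np.histogram(pixels, bins=n_bins, range=(vmin, vmax))
    return IntensityHistogram(edges, counts, int(counts.sum()), (vmin, vmax))


@dataclass
class ThresholdRecord:
    """The binarization cutoff chosen for one image x channel by one method."""

    image_id: str
    channel: str
    group: str
    method: str
    value: float
    operator_id: str | None = None

    def __post_init__(self) -> None:
        if self.method not in THRESHOLD_METHODS:
            raise ValueError(f"unknown threshold method {self.method!r}")
        self.value = float(self.value)


def _require_splittable(hist: IntensityHistogram) -> None:
    if hist.degenerate:
        raise DegenerateHistogramError("histogram flagged degenerate (constant source)")
    if len(hist.occupied) < 2:
        raise DegenerateHistogramError(
            "histogram has a single occupied bin: no foreground/background split exists"
        )


def _otsu_index(counts: np.ndarray) -> int:
    """Exact Otsu split: lowest bin index t maximizing between-class variance.

    With integer counts n_i and bin indices as values, the between-class
    variance at split t is proportional to (S0*N1 - S1*N0)^2 / (N0*N1) with
    N0,S0 the count/index-sum at bins <= t and N1,S1 above.  Comparing these
    as exact Fractions removes floating-point ties entirely.
    """
    counts = [int(c) for c in counts]
    n = len(counts)
    total_n = sum(counts)
    total_s = sum(i * c for i, c in enumerate(counts))
    best_t, best_val = None, Fraction(-1)
    n0 = s0 = 0
    for t in range(n - 1):
        n0 += counts[t]
        s0 += t * counts[t]
        n1 = total_n - n0
        if n0 == 0 or n1 == 0:
            continue
        s1 = total_s - s0
        val = Fraction((s0 * n1 - s1 * n0) ** 2, n0 * n1)
        if val > best_val:
            best_val, best_t = val, t
    assert best_t is not None
    return best_t


def _moments_index(counts: np.ndarray) -> int:
    """Tsai moment-preserving split on bin indices.

    Matches the first three moments of the histogram with a two-level
    distribution; the threshold is the first bin where the cumulative
    fraction reaches the background fraction p0.
    """
    p = counts.astype(float) / counts.sum()
    idx = np.arange(len(p), dtype=float)
    m1 = float(np.sum(idx * p))
    m2 = float(np.sum(idx**2 * p))
    m3 = float(np.sum(idx**3 * p))
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateHistogramError("zero-variance histogram: moments are degenerate")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise DegenerateHistogramError("moment equations have no real two-level solution")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise DegenerateHistogramError("two-level moments collapse to one level")
    p0 = (z1 - m1) / (z1 - z0)  # fraction of pixels assigned below threshold
    cum = np.cumsum(p)
    hit = np.flatnonzero(cum >= p0 - 1e-12)
    return int(hit[0]) if hit.size else len(p) - 1


def _isodata_value(hist: IntensityHistogram, max_iter: int = 10_000) -> float:
    """Fixed point of T <- (mean below + mean above)/2 on bin lower edges."""
    values = hist.bin_edges[:-1]
    counts = hist.counts.astype(float)
    t = float(np.sum(values * counts) / counts.sum())
    for _ in range(max_iter):
        below = values <= t
        above = ~below
        nb, na = counts[below].sum(), counts[above].sum()
        if nb == 0 or na == 0:
            # step toward the interior of the occupied range and retry
            occ = values[hist.counts > 0]
            t = float((occ.min() + occ.max()) / 2.0)
            below = values <= t
            above = ~below
            nb, na = counts[below].sum(), counts[above].sum()
            if nb == 0 or na == 0:
                raise DegenerateHistogramError("isodata cannot split this histogram")
        new_t = 0.5 * (
            float(np.sum(values[below] * counts[below]) / nb)
            + float(np.sum(values[above] * counts[above]) / na)
        )
        if abs(new_t - t) < 1e-9:
            return new_t
        t = new_t
    raise DegenerateHistogramError("isodata failed to reach a fixed point")


def _local_modes(h: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima (plateau-aware via tiny index tilt)."""
    modes = []
    n = len(h)
    for i in range(n):
        left = h[i - 1] if i > 0 else -np.inf
        right = h[i + 1] if i < n - 1 else -np.inf
        if h[i] > left and h[i] > right:
            modes.append(i)
    return np.asarray(modes, dtype=int)


def _intermode_index(counts: np.ndarray, max_iter: int = 10_000) -> float:
    """Smooth with a 3-bin moving average until bimodal; midpoint of the modes."""
    h = counts.astype(float)
    for _ in range(max_iter):
        modes = _local_modes(h)
        if len(modes) == 2:
            return float((modes[0] + modes[1]) / 2.0)
        # replicate-padded 3-bin moving average
        padded = np.pad(h, 1, mode="edge")
        h = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    raise DegenerateHistogramError("intermode smoothing did not reach bimodality")


def auto_threshold(hist: IntensityHistogram, method: str) -> float:
    """Threshold intensity from a histogram; foreground is pixels strictly > T.

    Bin-index results (otsu, moments) are mapped to intensity units as the
    selected bin's lower edge; isodata returns its continuous fixed point and
    intermode the intensity at the fractional midpoint index.  Optimum ties
    break to the lowest bin.
    """
    if method not in AUTO_METHODS:
        raise ValueError(f"unknown method {method!r}; use one of {AUTO_METHODS}")
    _require_splittable(hist)
    edges = hist.bin_edges
    if method == "otsu":
        return float(edges[_otsu_index(hist.counts)])
    if method == "moments":
        return float(edges[_moments_index(hist.counts)])
    if method == "isodata":
        return _isodata_value(hist)
    frac_idx = _intermode_index(hist.counts)
    return float(edges[0] + frac_idx * hist.bin_width)


def _median(values: Sequence[float]) -> float:
    return float(np.median(np.asarray(values, dtype=float)))


def consensus_threshold(records: Iterable[ThresholdRecord]) -> float:
    """Median of per-group threshold medians.

    Taking the median per group first prevents a group with a larger
    headcount of images from dominating the unique consensus value.
    Even-length medians are the mean of the two central values.
    """
    records = list(records)
    if not records:
        raise ValueError("no threshold records")
    channels = {r.channel for r in records}
    if len(channels) > 1:
        raise ValueError(f"records mix channels {sorted(channels)}")
    by_group: dict[str, list[float]] = {}
    for r in records:
        if not r.group:
            raise ValueError(f"record {r.image_id} has an empty group")
        by_group.setdefault(r.group, []).append(r.value)
    group_medians = [_median(v) for v in by_group.values()]
    return _median(group_medians)


def binarize(img: CalibratedImage, threshold: float, strict: bool = True) -> BinaryMask:
    """Turn pixels above ``threshold`` white (foreground) and the rest black.

    ``strict=True`` (default) uses the strictly-greater convention: a pixel
    exactly at T stays background.  Set ``strict=False`` for >= semantics.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    fg = img.pixels > threshold if strict else img.pixels >= threshold
    return BinaryMask(
        pixels=fg,
        pixel_size_um=img.pixel_size_um,
        image_id=img.image_id,
        threshold_used=float(threshold),
    )
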