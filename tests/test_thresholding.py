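"""Histogram construction, auto-threshold algorithms and binarization.

Each algorithm is checked against an independent oracle: Otsu against an
exact-rational exhaustive scan of the between-class variance, IsoData
against a fixed-point iteration started elsewhere, and Moments against a
polynomial-root solution of the Tsai moment equations.
"""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apoptoquant import (
    BinaryMask,
    CalibratedImage,
    DegenerateHistogramError,
    IntensityHistogram,
    ThresholdRecord,
    auto_threshold,
    binarize,
    compute_histogram,
    consensus_threshold,
)

# ---------------------------------------------------------------------------
# oracles


def otsu_scan_oracle(counts):
    """Lowest split index maximizing between-class variance, in exact rationals."""
    counts = [int(c) for c in counts]
    n = len(counts)
    best_t, best = None, Fraction(-1)
    for t in range(n - 1):
        n0 = sum(counts[: t + 1])
        n1 = sum(counts[t + 1 :])
        if n0 == 0 or n1 == 0:
            continue
        mu0 = Fraction(sum(i * counts[i] for i in range(t + 1)), n0)
        mu1 = Fraction(sum(i * counts[i] for i in range(t + 1, n)), n1)
        val = Fraction(n0, 1) * Fraction(n1, 1) * (mu0 - mu1) ** 2
        if val > best:
            best, best_t = val, t
    return best_t


def isodata_oracle(counts):
    """Fixed point of T <- (mean below + mean above)/2, started at the overall mean."""
    values = np.arange(len(counts), dtype=float)
    counts = np.asarray(counts, dtype=float)
    t = float((values * counts).sum() / counts.sum())
    for _ in range(10_000):
        below = values <= t
        nb, na = counts[below].sum(), counts[~below].sum()
        if nb == 0 or na == 0:
            t += 0.5
            continue
        new_t = 0.5 * (
            (values[below] * counts[below]).sum() / nb
            + (values[~below] * counts[~below]).sum() / na
        )
        if abs(new_t - t) < 1e-10:
            return new_t
        t = new_t
    raise AssertionError("oracle did not converge")


def moments_roots_oracle(counts):
    """Tsai selection solved via numpy polynomial roots."""
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    i = np.arange(len(p), dtype=float)
    m1, m2, m3 = (i * p).sum(), (i**2 * p).sum(), (i**3 * p).sum()
    cd = m2 - m1**2
    c0 = (-(m2**2) + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    z = np.sort(np.roots([1.0, c1, c0]).real)
    p0 = (z[1] - m1) / (z[1] - z[0])
    return int(np.flatnonzero(np.cumsum(p) >= p0 - 1e-12)[0])


def random_histograms(rng, n, n_bins=256):
    """Mixture-of-two-lumps integer histograms plus sparse uniform noise."""
    for _ in range(n):
        counts = np.zeros(n_bins, dtype=int)
        for _lump in range(2):
            center = rng.integers(10, n_bins - 10)
            width = rng.integers(2, 25)
            size = int(rng.integers(50, 3000))
            samples = np.clip(
                rng.normal(center, width, size).round().astype(int), 0, n_bins - 1
            )
            np.add.at(counts, samples, 1)
        sprinkle = rng.integers(0, n_bins, size=rng.integers(0, 40))
        np.add.at(counts, sprinkle, 1)
        if len(np.flatnonzero(counts)) >= 2:
            yield counts


# ---------------------------------------------------------------------------
# compute_histogram


def test_histogram_extreme_values(calibrated):
    img = calibrated([[0.0, 0.0], [255.0, 255.0]])
    hist = compute_histogram(img, n_bins=256)
    assert hist.counts[0] == 2
    assert hist.counts[-1] == 2
    assert hist.total == 4


def test_histogram_respects_mask(calibrated):
    img = calibrated([[0.0, 0.0], [255.0, 255.0]])
    mask = BinaryMask(np.array([[True, True], [False, False]]))
    hist = compute_histogram(img, n_bins=256, mask=mask)
    assert hist.total == 2
    assert hist.counts[0] == 2
    # constant masked region: flagged, refused by auto-thresholding
    assert hist.degenerate
    with pytest.raises(DegenerateHistogramError):
        auto_threshold(hist, "otsu")


def test_histogram_16bit_binning(calibrated):
    img = calibrated([[0.0, 4095.0]])
    hist = compute_histogram(img, n_bins=256)
    assert hist.bin_width == pytest.approx(4095.0 / 256.0)
    assert hist.counts[0] == 1 and hist.counts[-1] == 1
    # direct binning oracle over all bins
    oracle, _ = np.histogram([0.0, 4095.0], bins=256, range=(0.0, 4095.0))
    assert np.array_equal(hist.counts, oracle)


def test_histogram_empty_mask_rejected(calibrated):
    img = calibrated(np.arange(4.0).reshape(2, 2))
    with pytest.raises(ValueError):
        compute_histogram(img, mask=np.zeros((2, 2), dtype=bool))


def test_constant_image_flagged(calibrated):
    hist = compute_histogram(calibrated(np.full((3, 3), 5.0)))
    assert hist.degenerate and hist.total == 9
    with pytest.raises(DegenerateHistogramError):
        auto_threshold(hist, "isodata")


# ---------------------------------------------------------------------------
# auto_threshold


def spikes(n_bins=256, **at):
    counts = np.zeros(n_bins, dtype=int)
    for pos, c in at.items():
        counts[int(pos[1:])] = c
    return IntensityHistogram.from_counts(counts)


def test_otsu_equal_spikes_lowest_tie():
    hist = spikes(b50=100, b200=100)
    assert auto_threshold(hist, "otsu") == 50.0


def test_isodata_equal_spikes_fixed_point():
    hist = spikes(b50=100, b200=100)
    assert auto_threshold(hist, "isodata") == pytest.approx(125.0)


def test_moments_equal_spikes():
    hist = spikes(b50=100, b200=100)
    assert auto_threshold(hist, "moments") == 50.0


@pytest.mark.parametrize("method", ["otsu", "moments", "isodata", "intermode"])
def test_single_occupied_bin_rejected(method):
    hist = spikes(b77=1000)
    with pytest.raises(DegenerateHistogramError):
        auto_threshold(hist, method)


def test_otsu_matches_exhaustive_scan(rng):
    for counts in random_histograms(rng, 60):
        hist = IntensityHistogram.from_counts(counts)
        assert auto_threshold(hist, "otsu") == float(otsu_scan_oracle(counts))


def test_isodata_matches_fixed_point_oracle(rng):
    for counts in random_histograms(rng, 30):
        hist = IntensityHistogram.from_counts(counts)
        got = auto_threshold(hist, "isodata")
        assert got == pytest.approx(isodata_oracle(counts), abs=1e-6)
        # and the returned value really is a fixed point
        values = np.arange(len(counts), dtype=float)
        c = counts.astype(float)
        below = values <= got
        fp = 0.5 * (
            (values[below] * c[below]).sum() / c[below].sum()
            + (values[~below] * c[~below]).sum() / c[~below].sum()
        )
        assert got == pytest.approx(fp, abs=1e-6)


def test_moments_matches_tsai_roots_oracle(rng):
    for counts in random_histograms(rng, 30):
        hist = IntensityHistogram.from_counts(counts)
        assert auto_threshold(hist, "moments") == float(moments_roots_oracle(counts))


@pytest.mark.parametrize("method", ["otsu", "moments", "isodata", "intermode"])
def test_methods_split_separated_gaussians(method, rng):
    """For two well-separated modes every method lands between the means."""
    lo = np.clip(rng.normal(60, 6, 4000).round(), 0, 255).astype(int)
    hi = np.clip(rng.normal(190, 8, 2000).round(), 0, 255).astype(int)
    counts = np.bincount(np.concatenate([lo, hi]), minlength=256)
    hist = IntensityHistogram.from_counts(counts)
    t = auto_threshold(hist, method)
    assert 60.0 < t < 190.0


@pytest.mark.parametrize("method", ["otsu", "moments", "isodata", "intermode"])
def test_count_scaling_invariance(method, rng):
    counts = next(iter(random_histograms(rng, 1)))
    h1 = IntensityHistogram.from_counts(counts)
    h2 = IntensityHistogram.from_counts(counts * 7)
    assert auto_threshold(h1, method) == pytest.approx(auto_threshold(h2, method))


# ---------------------------------------------------------------------------
# consensus


def records(group_values, channel="c1"):
    out = []
    for group, values in group_values.items():
        for i, v in enumerate(values):
            out.append(
                ThresholdRecord(
                    image_id=f"{group}_{i}", channel=channel, group=group,
                    method="manual", value=v,
                )
            )
    return out


def test_consensus_median_of_medians():
    recs = records({"A": [100, 110, 120], "B": [200]})
    assert consensus_threshold(recs) == pytest.approx(155.0)


def test_consensus_single_group_is_group_median():
    assert consensus_threshold(records({"A": [100, 110, 120, 300]})) == pytest.approx(115.0)


def test_consensus_headcount_invariance():
    """Duplicating every record within one group must not move the consensus."""
    base = {"A": [100, 110, 120], "B": [200, 210, 190]}
    inflated = {"A": base["A"] * 3, "B": base["B"]}
    assert consensus_threshold(records(base)) == consensus_threshold(records(inflated))


def test_consensus_group_relabel_invariance():
    a = consensus_threshold(records({"A": [1, 2, 3], "B": [10.0]}))
    b = consensus_threshold(records({"B": [1, 2, 3], "A": [10.0]}))
    assert a == b


def test_consensus_rejects_mixed_channels():
    recs = records({"A": [100]}) + records({"B": [200]}, channel="c2")
    with pytest.raises(ValueError):
        consensus_threshold(recs)


def test_consensus_rejects_empty():
    with pytest.raises(ValueError):
        consensus_threshold([])


# ---------------------------------------------------------------------------
# binarize


def test_binarize_strictly_greater(calibrated):
    img = calibrated([[99.0, 100.0, 101.0]])
    mask = binarize(img, 100.0)
    assert mask.pixels.tolist() == [[False, False, True]]


def test_binarize_degenerate_thresholds(calibrated):
    img = calibrated([[1.0, 2.0], [3.0, 4.0]])
    assert not binarize(img, 4.0).pixels.any()
    assert binarize(img, 0.5).pixels.all()


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    t1=st.floats(-10, 300, allow_nan=False),
    t2=st.floats(-10, 300, allow_nan=False),
    seed=st.integers(0, 2**16),
)
def test_binarize_antitone_in_threshold(t1, t2, seed):
    """Raising T can only shrink the foreground: mask(T2) subset of mask(T1)."""
    lo, hi = min(t1, t2), max(t1, t2)
    pixels = np.random.default_rng(seed).uniform(0, 255, size=(8, 8))
    img = CalibratedImage(pixels, 0.5)
    m_lo = binarize(img, lo).pixels
    m_hi = binarize(img, hi).pixels
    assert np.all(m_hi <= m_lo)
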