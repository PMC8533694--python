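"""Group summaries, rank-sum comparisons, and threshold concordance.

Per-image readouts (count or stained area) are compared between experimental
groups with the two-sided Wilcoxon/Mann-Whitney rank-sum test; raw p-values
are reported without multiple-testing correction.  Threshold concordance
between two raters (or a rater and an algorithm) is assessed by ordinary
least squares of one threshold series on the other.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _scistats

from .thresholding import ThresholdRecord

__all__ = [
    "GroupResult",
    "rank_sum_test",
    "summarize_group",
    "concordance",
    "threshold_histogram_figure",
]


@dataclass
class GroupResult:
    """Per-group readout values and their five-number summary."""

    group: str
    values: list[float]
    mean: float
    sd: float
    min: float
    max: float
    median: float
    n: int


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Uses exact enumeration when both samples have at most 10 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.  Returns (U statistic of ``a``, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    res = _scistats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def summarize_group(values: Sequence[float], group: str = "") -> GroupResult:
    """Mean, sample SD (n-1 denominator; 0 for a single value), min, max, median."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("cannot summarize an empty group")
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupResult(
        group=group,
        values=vals,
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
        median=float(np.median(arr)),
        n=int(arr.size),
    )


def concordance(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS of y on x: (slope, intercept, R^2, two-sided slope p).

    R^2 is the squared Pearson correlation; p tests slope = 0.  Used to ask
    whether two threshold-determination series are consistent with each other
    (a systematic offset with high R^2 is benign; no relationship is not).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.all(x == x[0]):
        raise ValueError("x is constant: slope is undefined")
    res = _scistats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def threshold_histogram_figure(
    records: Iterable[ThresholdRecord], path: str | Path, n_bins: int = 20
) -> tuple[Path, Path]:
    """Histogram of obtained threshold values: a PNG plus a CSV of bin counts.

    The CSV (same stem, ``.csv`` suffix) holds bin_low, bin_high, count rows
    so the distribution is testable and diff-able without image comparison.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    records = list(records)
    if not records:
        raise ValueError("no threshold records to plot")
    values = np.asarray([r.value for r in records], dtype=float)
    if values.min() == values.max():
        edges = np.linspace(values.min() - 0.5, values.max() + 0.5, 2)
        counts = np.array([values.size])
    else:
        counts, edges = np.histogram(values, bins=n_bins)

    png_path = Path(path)
    png_path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="black")
    ax.set_xlabel("threshold value")
    ax.set_ylabel("number of images")
    ax.set_title("Distribution of determined thresholds")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)

    csv_path = png_path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_low", "bin_high", "count"])
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            writer.writerow([f"{lo:.6g}", f"{hi:.6g}", int(c)])
    return png_path, csv_path
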