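"""Two-phase batch workflow: threshold determination, then quantification.

Phase 1 opens every manifest image, filters and z-projects it, and either
computes an algorithmic threshold per image or exports preview images plus a
template table for offline manual determination.  Phase 2 consumes only
files (raw images + the threshold table + optional ROI polygons): it applies
per-image or consensus thresholds, restricts to the region of interest,
quantifies particles, and emits per-group summaries and pairwise rank-sum
comparisons for both the count and area readouts.

The phase separation is deliberate: deleting all in-memory state between the
phases changes nothing, and identical config + seed + inputs give
byte-identical CSV outputs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

from . import io as aio
from .images import CalibratedImage
from .preprocess import mean_filter, median_filter, z_project
from .quantify import QuantResult, RegionOfInterest, quantify_image
from .stats import rank_sum_test, summarize_group, threshold_histogram_figure
from .thresholding import (
    AUTO_METHODS,
    ThresholdRecord,
    auto_threshold,
    compute_histogram,
    consensus_threshold,
)

__all__ = ["PipelineConfig", "run_threshold_phase", "run_quantify_phase"]

THRESHOLD_TABLE = "thresholds.csv"
RESULTS_SUMMARY = "results_summary.csv"
RESULTS_DETAIL = "results_particles.csv"
GROUP_SUMMARY = "group_summary.csv"
COMPARISONS = "comparisons.csv"


@dataclass
class PipelineConfig:
    """Declarative description of a full run (serializable to YAML)."""

    manifest: str
    out_dir: str
    channel: str = ""
    filter_method: str = "median"  # median | mean | none
    filter_radius: int = 1
    projection: str = "max"  # average | max | sum
    threshold_mode: str = "algorithm:otsu"  # manual_table | algorithm:<name> | consensus_from_table
    threshold_table: str | None = None  # external table for manual/consensus modes
    consensus_fraction: float = 1.0
    n_bins: int = 256
    roi_dir: str | None = None
    min_diameter_um: float | None = 2.0
    max_diameter_um: float | None = None
    circ_min: float = 0.0
    circ_max: float = 1.0
    connectivity: int = 8
    calibration_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.filter_method not in ("median", "mean", "none"):
            raise ValueError(f"unknown filter method {self.filter_method!r}")
        mode = self.threshold_mode
        if mode.startswith("algorithm:"):
            name = mode.split(":", 1)[1]
            if name not in AUTO_METHODS:
                raise ValueError(f"unknown threshold algorithm {name!r}")
        elif mode not in ("manual_table", "consensus_from_table"):
            raise ValueError(f"unknown threshold mode {mode!r}")
        if not 0.0 < self.consensus_fraction <= 1.0:
            raise ValueError("consensus_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    def parameters(self) -> dict:
        return asdict(self)


def _load_projected(cfg: PipelineConfig, entry: aio.ManifestEntry, root: Path) -> CalibratedImage:
    stack = aio.read_stack(
        root / entry.path,
        series=entry.series,
        channel=entry.channel,
        calibration=cfg.calibration_um,
        group=entry.group,
        image_id=entry.image_id,
    )
    if cfg.filter_method == "median":
        stack = median_filter(stack, cfg.filter_radius)
    elif cfg.filter_method == "mean":
        stack = mean_filter(stack, cfg.filter_radius)
    return z_project(stack, cfg.projection)


def _select_entries(cfg: PipelineConfig, manifest: aio.Manifest) -> list[aio.ManifestEntry]:
    entries = manifest.entries
    if cfg.channel:
        entries = [e for e in entries if e.channel == cfg.channel]
        if not entries:
            raise ValueError(f"manifest has no entries for channel {cfg.channel!r}")
    return sorted(entries, key=lambda e: e.image_id)


def run_threshold_phase(cfg: PipelineConfig) -> dict[str, Path]:
    """Phase 1: process every image and determine (or template) thresholds."""
    manifest = aio.read_manifest(cfg.manifest)
    root = Path(cfg.manifest).parent
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = _select_entries(cfg, manifest)

    outputs: dict[str, Path] = {}
    records: list[ThresholdRecord] = []
    notes: list[str] = []

    if cfg.threshold_mode.startswith("algorithm:"):
        method = cfg.threshold_mode.split(":", 1)[1]
        for entry in entries:
            img = _load_projected(cfg, entry, root)
            hist = compute_histogram(img, n_bins=cfg.n_bins)
            value = auto_threshold(hist, method)
            records.append(
                ThresholdRecord(
                    image_id=entry.image_id,
                    channel=entry.channel,
                    group=entry.group,
                    method=method,
                    value=value,
                )
            )
            notes.append(f"{entry.image_id}: {method} threshold {value:.6g}")
        outputs["thresholds"] = aio.write_threshold_table(records, out / THRESHOLD_TABLE)
        png, csv_path = threshold_histogram_figure(records, out / "threshold_histogram.png")
        outputs["histogram_png"], outputs["histogram_csv"] = png, csv_path
    else:
        # manual / consensus: export previews and a template for the operator
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        preview_dir = out / "previews"
        preview_dir.mkdir(parents=True, exist_ok=True)
        for entry in entries:
            img = _load_projected(cfg, entry, root)
            plt.imsave(preview_dir / f"{entry.image_id}.png", img.pixels, cmap="gray")
            records.append(
                ThresholdRecord(
                    image_id=entry.image_id,
                    channel=entry.channel,
                    group=entry.group,
                    method="manual",
                    value=float("nan"),
                )
            )
            notes.append(f"{entry.image_id}: preview exported for manual determination")
        outputs["template"] = aio.write_threshold_table(
            records, out / "thresholds_template.csv", allow_empty_values=True
        )
        outputs["previews"] = preview_dir

    record = aio.RunRecord(
        parameters={"phase": "threshold", **cfg.parameters()}, notes=notes
    )
    outputs["run_log"] = aio.write_run_record(record, out / "run_part1.txt")
    return outputs


def _resolve_thresholds(
    cfg: PipelineConfig, entries: list[aio.ManifestEntry], out: Path
) -> tuple[dict[str, float], list[str]]:
    """Per-image threshold map from the table (or one consensus value for all)."""
    table_path = cfg.threshold_table or out / THRESHOLD_TABLE
    if not Path(table_path).exists():
        raise FileNotFoundError(
            f"no threshold table at {table_path}; run the threshold phase or provide one"
        )
    records = aio.read_threshold_table(table_path)
    by_image = {r.image_id: r for r in records}
    notes: list[str] = []

    if cfg.threshold_mode == "consensus_from_table":
        ids = sorted(by_image)
        n_used = max(1, math.ceil(cfg.consensus_fraction * len(ids)))
        used = [by_image[i] for i in ids[:n_used]]
        unique = consensus_threshold(used)
        notes.append(
            f"consensus threshold {unique:.6g} (median of per-group medians, "
            f"{n_used}/{len(ids)} images)"
        )
        return {e.image_id: unique for e in entries}, notes

    thresholds: dict[str, float] = {}
    for e in entries:
        if e.image_id not in by_image or not np.isfinite(by_image[e.image_id].value):
            raise ValueError(f"no threshold available for image {e.image_id!r}")
        thresholds[e.image_id] = by_image[e.image_id].value
    return thresholds, notes


def _load_roi(cfg: PipelineConfig, image_id: str) -> RegionOfInterest | None:
    if cfg.roi_dir is None:
        return None
    roi_path = Path(cfg.roi_dir) / f"{image_id}.csv"
    if not roi_path.exists():
        raise FileNotFoundError(f"ROI file missing for image {image_id!r}: {roi_path}")
    rows = []
    with open(roi_path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"x", "y"} <= set(reader.fieldnames):
            raise ValueError(f"ROI file {roi_path} must have x,y columns")
        for row in reader:
            rows.append((float(row["x"]), float(row["y"])))
    return RegionOfInterest(np.asarray(rows))


def run_quantify_phase(cfg: PipelineConfig) -> dict[str, Path]:
    """Phase 2: apply thresholds, restrict to ROIs, quantify and summarize."""
    manifest = aio.read_manifest(cfg.manifest)
    root = Path(cfg.manifest).parent
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = _select_entries(cfg, manifest)
    thresholds, notes = _resolve_thresholds(cfg, entries, out)

    results: list[QuantResult] = []
    for entry in entries:
        img = _load_projected(cfg, entry, root)
        roi = _load_roi(cfg, entry.image_id)
        res = quantify_image(
            img,
            thresholds[entry.image_id],
            roi=roi,
            min_diameter_um=cfg.min_diameter_um,
            max_diameter_um=cfg.max_diameter_um,
            circ_range=(cfg.circ_min, cfg.circ_max),
            connectivity=cfg.connectivity,
        )
        results.append(res)
        notes.append(
            f"{entry.image_id}: T={thresholds[entry.image_id]:.6g} "
            f"count={res.count} area={res.total_area_um2:.6g}"
        )

    outputs: dict[str, Path] = {}
    outputs["summary"], outputs["detail"] = aio.write_results_table(
        results, out / RESULTS_SUMMARY, out / RESULTS_DETAIL
    )

    groups = sorted({r.group for r in results})
    readouts = {
        "count": {g: [float(r.count) for r in results if r.group == g] for g in groups},
        "area": {g: [r.total_area_um2 for r in results if r.group == g] for g in groups},
    }
    group_summary_path = out / GROUP_SUMMARY
    with open(group_summary_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "readout", "n", "mean", "sd", "min", "max", "median"])
        for readout, by_group in readouts.items():
            for g in groups:
                s = summarize_group(by_group[g], group=g)
                writer.writerow(
                    [g, readout, s.n, repr(s.mean), repr(s.sd), repr(s.min), repr(s.max), repr(s.median)]
                )
    outputs["group_summary"] = group_summary_path

    comparisons_path = out / COMPARISONS
    with open(comparisons_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group_a", "group_b", "readout", "threshold_mode", "U", "p"])
        for readout, by_group in readouts.items():
            for ga, gb in combinations(groups, 2):
                u, p = rank_sum_test(by_group[ga], by_group[gb])
                writer.writerow([ga, gb, readout, cfg.threshold_mode, repr(u), repr(p)])
    outputs["comparisons"] = comparisons_path

    record = aio.RunRecord(parameters={"phase": "quantify", **cfg.parameters()}, notes=notes)
    outputs["run_log"] = aio.write_run_record(record, out / "run_part2.txt")
    return outputs
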