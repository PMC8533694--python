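"""File formats: calibrated TIFF stacks, manifests, tables and run logs.

The interchange standard is multi-page TIFF (ImageJ-flavoured metadata) for
images and plain CSV for every table, so a whole analysis is reproducible
from files alone: each persisted row carries image_id and group.  The run
log is a human-readable ``key: value`` text file that captures every
parameter needed to repeat a run identically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .images import ImageStack
from .quantify import QuantResult
from .thresholding import ThresholdRecord

__all__ = [
    "Manifest",
    "ManifestEntry",
    "RunRecord",
    "read_stack",
    "write_stack",
    "read_manifest",
    "write_manifest",
    "write_threshold_table",
    "read_threshold_table",
    "write_results_table",
    "read_results_summary",
    "write_run_record",
    "read_run_record",
]

THRESHOLD_COLUMNS = ["image_id", "channel", "group", "method", "value", "operator_id"]
SUMMARY_COLUMNS = ["image_id", "group", "count", "total_area_um2", "threshold_used"]
DETAIL_COLUMNS = [
    "image_id",
    "group",
    "label",
    "area_px",
    "area_um2",
    "centroid_x",
    "centroid_y",
    "bbox_x0",
    "bbox_y0",
    "bbox_x1",
    "bbox_y1",
    "perimeter_um",
    "circularity",
    "equiv_diameter_um",
]


@dataclass
class ManifestEntry:
    path: str
    series: int
    channel: str
    image_id: str
    group: str


@dataclass
class Manifest:
    """Explicit mapping of image files to channels and experimental groups."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if not e.group:
                raise ValueError(f"manifest entry {e.image_id!r} has an empty group")
            key = (e.image_id, e.channel)
            if key in seen:
                raise ValueError(f"duplicate image_id+channel in manifest: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def groups(self) -> list[str]:
        return sorted({e.group for e in self.entries})


def default_image_id(path: str | Path, series: int) -> str:
    """Stable identifier ``<filestem>:s<series>``."""
    return f"{Path(path).stem}:s{series}"


# ---------------------------------------------------------------------------
# image stacks


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as an ImageJ-flavoured TIFF with um-per-pixel calibration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.voxels
    if stack.bit_depth == 8:
        data = data.astype(np.uint8)
    elif stack.bit_depth == 16:
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata={"unit": "um", "spacing": stack.z_step_um, "axes": "ZYX"},
    )
    return path


_MICRON_UNITS = ("um", "µm", "micron", "micrometer")


def _resolution_um_per_px(tif: "tifffile.TiffFile", page: "tifffile.TiffPage") -> float | None:
    """Pixel size in um from resolution tags, if a micron unit is declared.

    TIFF writers emit a placeholder resolution of 1 pixel/unit with
    ResolutionUnit NONE even for uncalibrated data, so the tags are only
    trusted when the ImageJ metadata declares a micrometre unit.
    """
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is None or yres is None:
        return None
    unit = str((tif.imagej_metadata or {}).get("unit", "")).lower()
    if unit not in _MICRON_UNITS:
        return None
    xr = xres.value[0] / xres.value[1]
    yr = yres.value[0] / yres.value[1]
    if xr <= 0 or yr <= 0:
        return None
    if abs(xr - yr) > 1e-9 * max(xr, yr):
        raise ValueError("non-uniform x/y pixel size in TIFF metadata")
    return 1.0 / xr


def read_stack(
    path: str | Path,
    series: int = 0,
    channel: str = "",
    calibration: float | None = None,
    group: str = "",
    image_id: str | None = None,
) -> ImageStack:
    """Read a (single-channel) TIFF series into an :class:`ImageStack`.

    Calibration comes from the file's resolution metadata unless overridden;
    a file lacking calibration and an override is rejected because all size
    filters downstream are in micrometres.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if series >= len(tif.series):
            raise ValueError(f"series {series} not present in {path.name}")
        ser = tif.series[series]
        data = np.asarray(ser.asarray())
        pixel_size = _resolution_um_per_px(tif, ser.pages[0])
        z_step = 1.0
        if tif.imagej_metadata:
            z_step = float(tif.imagej_metadata.get("spacing", 1.0))
    if calibration is not None:
        pixel_size = float(calibration)
    if pixel_size is None:
        raise ValueError(
            f"{path.name} carries no pixel-size metadata; pass an explicit calibration"
        )
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim == 4:  # (C|T, Z, Y, X) or (Z, C, Y, X): select the channel index
        try:
            c = int(channel) if channel != "" else 0
        except ValueError as exc:
            raise ValueError(
                "multi-channel file: channel must be a numeric index"
            ) from exc
        axes = getattr(ser, "axes", "")
        if "C" in axes:
            data = np.take(data, c, axis=axes.index("C"))
        else:
            data = data[c]
    if data.ndim != 3:
        raise ValueError(f"cannot interpret {path.name} as a (z, y, x) stack")
    if np.issubdtype(data.dtype, np.uint8):
        depth: int | str = 8
    elif np.issubdtype(data.dtype, np.integer):
        depth = 16
    else:
        depth = "float"
    return ImageStack(
        voxels=data,
        pixel_size_um=float(pixel_size),
        z_step_um=z_step,
        bit_depth=depth,
        image_id=image_id if image_id is not None else default_image_id(path, series),
        channel=channel,
        group=group,
    )


# ---------------------------------------------------------------------------
# manifests


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "series", "channel", "image_id", "group"])
        for e in manifest.entries:
            writer.writerow([e.path, e.series, e.channel, e.image_id, e.group])
    return path


def read_manifest(path: str | Path) -> Manifest:
    df = pd.read_csv(path, dtype=str).fillna("")
    entries = [
        ManifestEntry(
            path=row["path"],
            series=int(row["series"] or 0),
            channel=row["channel"],
            image_id=row["image_id"],
            group=row["group"],
        )
        for _, row in df.iterrows()
    ]
    return Manifest(entries)


# ---------------------------------------------------------------------------
# threshold tables


def write_threshold_table(
    records: Sequence[ThresholdRecord], path: str | Path, allow_empty_values: bool = False
) -> Path:
    """One CSV row per (image, channel) threshold determination."""
    if not records:
        raise ValueError("no threshold records to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(THRESHOLD_COLUMNS)
        for r in records:
            value = "" if (allow_empty_values and np.isnan(r.value)) else repr(float(r.value))
            writer.writerow([r.image_id, r.channel, r.group, r.method, value, r.operator_id or ""])
    return path


def read_threshold_table(path: str | Path) -> list[ThresholdRecord]:
    df = pd.read_csv(path, dtype={"image_id": str, "channel": str, "group": str})
    missing = [c for c in THRESHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed threshold table: missing columns {missing}")
    dup = df.duplicated(subset=["image_id", "channel"])
    if dup.any():
        offenders = df.loc[dup, ["image_id", "channel"]].to_records(index=False).tolist()
        raise ValueError(f"duplicated image_id+channel rows: {offenders}")
    records = []
    for _, row in df.fillna({"channel": "", "group": ""}).iterrows():
        value = row["value"]
        if pd.isna(value):
            raise ValueError(
                f"threshold table {Path(path).name} has no value for image {row['image_id']!r}"
            )
        op = row.get("operator_id")
        records.append(
            ThresholdRecord(
                image_id=str(row["image_id"]),
                channel=str(row["channel"]),
                group=str(row["group"]),
                method=str(row["method"]),
                value=float(value),
                operator_id=None if pd.isna(op) or op == "" else str(op),
            )
        )
    return records


# ---------------------------------------------------------------------------
# results tables


def write_results_table(
    results: Sequence[QuantResult], summary_path: str | Path, detail_path: str | Path
) -> tuple[Path, Path]:
    """Write per-image summary and per-particle detail CSVs (header-only if empty)."""
    summary_path, detail_path = Path(summary_path), Path(detail_path)
    summary_path.parent.mkdir(parents=True, exist_ok=True)
    detail_path.parent.mkdir(parents=True, exist_ok=True)
    with open(summary_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SUMMARY_COLUMNS)
        for r in results:
            writer.writerow(
                [r.image_id, r.group, r.count, repr(float(r.total_area_um2)), r.threshold_used]
            )
    with open(detail_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DETAIL_COLUMNS)
        for r in results:
            for p in r.particles:
                writer.writerow(
                    [
                        r.image_id,
                        r.group,
                        p.label,
                        p.area_px,
                        repr(float(p.area_um2)),
                        p.centroid[0],
                        p.centroid[1],
                        *p.bbox,
                        p.perimeter_um,
                        p.circularity,
                        p.equiv_diameter_um,
                    ]
                )
    return summary_path, detail_path


def read_results_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str, "group": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed results summary: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# run records


@dataclass
class RunRecord:
    """Parameters and notes sufficient to re-run a pipeline phase identically."""

    parameters: dict
    timestamp: str = ""
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("a run record must contain at least one parameter")
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")


def write_run_record(record: RunRecord, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"timestamp: {record.timestamp}"]
    for key in sorted(record.parameters):
        lines.append(f"param {key}: {record.parameters[key]}")
    for note in record.notes:
        lines.append(f"note: {note}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_run_record(path: str | Path) -> RunRecord:
    parameters: dict = {}
    notes: list[str] = []
    timestamp = ""
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "timestamp":
            timestamp = value
        elif key.startswith("param "):
            parameters[key[len("param "):]] = value
        elif key == "note":
            notes.append(value)
    return RunRecord(parameters=parameters, timestamp=timestamp, notes=notes)
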