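"""Synthetic ground-truth scenes for validating the quantification pipeline.

Real calibration data for this protocol are not distributable, so every
claim is exercised on generated monolayer-tissue scenes with known truth.
Two staining geometries are emulated:

* **nuclear** — punctate, TUNEL-like: soft-edged spots the size of a nucleus
  (default 3.5 um diameter), optionally placed with enforced separation so
  the true object count is recoverable exactly;
* **cytosolic** — cleaved-caspase-like: whole-cell discs (default 7 um)
  whose centers come from a parent-offspring (Thomas-like) clustered point
  process, so adjacent apoptotic cells overlap and merge into single
  binarized objects — the mechanism that flattens the count readout as the
  apoptotic rate rises.

Three defect classes are injectable on top of the biological signal:
diffuse Gaussian background noise, isolated aberrant-high pixels, and
grouped aberrant-high pixels smaller than the object-size limit.  Ground
truth (per-object masks, union area) is computed from the noiseless,
defect-free render, so defect-removal efficacy is measurable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .images import ImageStack
from .io import Manifest, ManifestEntry, write_manifest, write_stack

__all__ = ["SceneSpec", "GroundTruth", "simulate_scene", "inject_artifacts", "simulate_experiment"]

#: logistic edge softness of rendered objects, in pixels
EDGE_SOFTNESS_PX = 0.7

#: mean offspring per cluster parent in the cytosolic point process
OFFSPRING_PER_PARENT = 5.0


@dataclass
class SceneSpec:
    """Everything needed to generate one calibrated scene deterministically.

    ``event_rate`` is apoptotic events per 1000 um^2 of field; when zero,
    ``n_cells`` fixes the object count directly.  ``cluster_strength`` in
    [0, 1] moves placement from uniform-with-separation (0) to strongly
    aggregated (1).  ``hot_pixel_rate`` is isolated aberrant pixels per
    kilo-voxel of the stack; ``hot_cluster_rate`` is grouped-aberrant-pixel
    patches per image.
    """

    shape: tuple[int, int, int] = (8, 512, 512)  # (n_z, h, w)
    pixel_size_um: float = 0.5
    staining: str = "nuclear"
    n_cells: int = 25
    event_rate: float = 0.0
    cluster_strength: float = 0.0
    object_diameter_um: float | None = None  # default 3.5 nuclear / 7.0 cytosolic
    signal_level: float = 1800.0
    background_level: float = 200.0
    noise_sd: float = 30.0
    hot_pixel_rate: float = 0.0
    hot_cluster_rate: float = 0.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.staining not in ("nuclear", "cytosolic"):
            raise ValueError("staining must be 'nuclear' or 'cytosolic'")
        if self.object_diameter_um is None:
            self.object_diameter_um = 3.5 if self.staining == "nuclear" else 7.0
        for name in ("event_rate", "hot_pixel_rate", "hot_cluster_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.cluster_strength <= 1.0:
            raise ValueError("cluster_strength must be in [0, 1]")
        if not self.object_diameter_um > 2.0 * self.pixel_size_um:
            raise ValueError("object diameter must exceed 2 pixels")
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("shape must be (n_z, h, w) with positive extents")

    @property
    def dynamic_max(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def field_area_um2(self) -> float:
        _, h, w = self.shape
        return h * w * self.pixel_size_um**2

    def n_objects(self) -> int:
        if self.event_rate > 0:
            return int(round(self.event_rate * self.field_area_um2 / 1000.0))
        return int(self.n_cells)


@dataclass
class GroundTruth:
    """True object count, true stained area (union, overlaps once) and masks."""

    true_count: int
    true_area_um2: float
    object_masks: list[np.ndarray] = field(default_factory=list)
    defect_locations: dict = field(default_factory=dict)

    def union_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        for m in self.object_masks:
            out |= m
        return out


# ---------------------------------------------------------------------------
# placement


def _place_separated(
    rng: np.random.Generator, n: int, h: int, w: int, radius_px: float
) -> np.ndarray:
    """Uniform centers with pairwise distance >= 2*radius + 3 px (masks stay
    separated by at least one background pixel after thresholding)."""
    margin = radius_px + 4.0
    min_dist = 2.0 * radius_px + 3.0
    centers: list[tuple[float, float]] = []
    for _ in range(20_000):
        if len(centers) == n:
            break
        cy = rng.uniform(margin, h - 1 - margin)
        cx = rng.uniform(margin, w - 1 - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_dist**2 for y, x in centers):
            centers.append((cy, cx))
    if len(centers) < n:
        raise ValueError(f"cannot place {n} separated objects in a {h}x{w} field")
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _place_clustered(
    rng: np.random.Generator, n: int, h: int, w: int, radius_px: float, strength: float
) -> np.ndarray:
    """Thomas-like parent-offspring process; offspring spread shrinks with strength."""
    margin = radius_px + 4.0
    n_parents = max(1, int(np.ceil(n / OFFSPRING_PER_PARENT)))
    parents = np.column_stack(
        [
            rng.uniform(margin, h - 1 - margin, n_parents),
            rng.uniform(margin, w - 1 - margin, n_parents),
        ]
    )
    # offspring displacement SD in pixels: ~2 object diameters when loose,
    # ~0.4 diameters when strongly aggregated
    diam_px = 2.0 * radius_px
    sd = diam_px * (2.0 - 1.6 * strength)
    assignment = rng.integers(0, n_parents, n)
    offsets = rng.normal(0.0, sd, size=(n, 2))
    centers = parents[assignment] + offsets
    centers[:, 0] = np.clip(centers[:, 0], margin, h - 1 - margin)
    centers[:, 1] = np.clip(centers[:, 1], margin, w - 1 - margin)
    return centers


# ---------------------------------------------------------------------------
# rendering


def _render_objects(
    spec: SceneSpec, centers: np.ndarray, h: int, w: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Noiseless 2D amplitude field in [0, 1] plus per-object half-max masks."""
    radius_px = spec.object_diameter_um / 2.0 / spec.pixel_size_um
    reach = int(np.ceil(radius_px + 6 * EDGE_SOFTNESS_PX))
    amplitude = np.zeros((h, w), dtype=float)
    masks: list[np.ndarray] = []
    for cy, cx in centers:
        y0, y1 = max(0, int(cy) - reach), min(h, int(cy) + reach + 1)
        x0, x1 = max(0, int(cx) - reach), min(w, int(cx) + reach + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        r = np.hypot(yy - cy, xx - cx)
        profile = 1.0 / (1.0 + np.exp((r - radius_px) / EDGE_SOFTNESS_PX))
        np.maximum(amplitude[y0:y1, x0:x1], profile, out=amplitude[y0:y1, x0:x1])
        mask = np.zeros((h, w), dtype=bool)
        mask[y0:y1, x0:x1] = profile >= 0.5
        masks.append(mask)
    return amplitude, masks


def _z_band(n_z: int) -> tuple[int, int]:
    """Contiguous slice band occupied by the monolayer (~40% of the stack, centred)."""
    band = max(1, int(round(0.4 * n_z)))
    start = (n_z - band) // 2
    return start, start + band


def simulate_scene(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Generate one calibrated stack plus its ground truth.

    Objects occupy a contiguous central z-band (monolayer geometry); the
    per-object truth mask is the half-maximum set of that object's noiseless
    profile, so binarizing the noiseless scene at the mid-level between
    background and signal recovers the truth.  Noise and injected defects are
    added *after* ground truth is frozen.
    """
    rng = np.random.default_rng(spec.seed)
    n_z, h, w = spec.shape
    n = spec.n_objects()
    radius_px = spec.object_diameter_um / 2.0 / spec.pixel_size_um

    if n == 0:
        centers = np.empty((0, 2))
    elif spec.cluster_strength == 0.0:
        centers = _place_separated(rng, n, h, w, radius_px)
    else:
        centers = _place_clustered(rng, n, h, w, radius_px, spec.cluster_strength)

    amplitude, masks = _render_objects(spec, centers, h, w)
    union = np.zeros((h, w), dtype=bool)
    for m in masks:
        union |= m
    truth = GroundTruth(
        true_count=n,
        true_area_um2=float(union.sum()) * spec.pixel_size_um**2,
        object_masks=masks,
        defect_locations={"hot_pixels": [], "hot_clusters": []},
    )

    z0, z1 = _z_band(n_z)
    stack = np.full((n_z, h, w), spec.background_level, dtype=float)
    signal = (spec.signal_level - spec.background_level) * amplitude
    stack[z0:z1] += signal[None, :, :]
    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, size=stack.shape)
    np.clip(stack, 0.0, spec.dynamic_max, out=stack)

    image = ImageStack(
        voxels=np.round(stack).astype(np.uint16 if spec.bit_depth == 16 else np.uint8),
        pixel_size_um=spec.pixel_size_um,
        bit_depth=spec.bit_depth,
        image_id=f"synthetic:seed{spec.seed}",
        channel=spec.staining,
    )
    if spec.hot_pixel_rate > 0 or spec.hot_cluster_rate > 0:
        image, inventory = inject_artifacts(image, spec)
        truth.defect_locations = inventory
    return image, truth


# ---------------------------------------------------------------------------
# defects


def _candidate_background(stack: ImageStack, spec: SceneSpec, clearance: int) -> np.ndarray:
    """2D mask of positions far (Chebyshev >= clearance) from any bright pixel."""
    from scipy import ndimage

    bright_2d = (stack.voxels > spec.background_level + 5 * spec.noise_sd + 1).any(axis=0)
    size = 2 * clearance + 1
    excluded = ndimage.maximum_filter(bright_2d.astype(np.uint8), size=size) > 0
    candid = ~excluded
    candid[:clearance, :] = candid[-clearance:, :] = False
    candid[:, :clearance] = candid[:, -clearance:] = False
    return candid


def inject_artifacts(
    stack: ImageStack, spec: SceneSpec
) -> tuple[ImageStack, dict[str, list]]:
    """Add isolated hot pixels and sub-limit hot clusters; return their inventory.

    Hot pixels are set to 97% of the dynamic range with all 8 in-plane
    neighbours untouched; hot clusters are 3x3 connected patches (equivalent
    diameter ~1.7 um at 0.5 um/px, below a 2 um size limit).  Defect counts
    are deterministic: ``round(rate * kilo_voxels)`` and ``round(rate)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 911]))
    n_z, h, w = stack.voxels.shape
    n_hot = int(round(spec.hot_pixel_rate * stack.voxels.size / 1000.0))
    n_clusters = int(round(spec.hot_cluster_rate))
    inventory: dict[str, list] = {"hot_pixels": [], "hot_clusters": []}
    if n_hot == 0 and n_clusters == 0:
        return stack, inventory

    voxels = stack.voxels.astype(float).copy()
    hot_value = 0.97 * spec.dynamic_max
    candid = _candidate_background(stack, spec, clearance=3)

    def take_position(extent: int) -> tuple[int, int]:
        """Draw a candidate position and block out its surroundings."""
        free = np.flatnonzero(candid)
        if free.size == 0:
            raise ValueError("field too crowded to place an isolated defect")
        pos = int(free[rng.integers(0, free.size)])
        y, x = divmod(pos, w)
        y0, y1 = max(0, y - extent), min(h, y + extent + 1)
        x0, x1 = max(0, x - extent), min(w, x + extent + 1)
        candid[y0:y1, x0:x1] = False
        return y, x

    for _ in range(n_hot):
        y, x = take_position(extent=4)
        z = int(rng.integers(0, n_z))
        voxels[z, y, x] = hot_value
        inventory["hot_pixels"].append((z, y, x))

    for _ in range(n_clusters):
        y, x = take_position(extent=6)
        z = int(rng.integers(0, n_z))
        coords = [(z, y + dy, x + dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
        for cz, cy, cx in coords:
            voxels[cz, cy, cx] = hot_value
        inventory["hot_clusters"].append(coords)

    dtype = stack.voxels.dtype
    out = ImageStack(
        voxels=np.round(voxels).astype(dtype) if np.issubdtype(dtype, np.integer) else voxels,
        pixel_size_um=stack.pixel_size_um,
        z_step_um=stack.z_step_um,
        bit_depth=stack.bit_depth,
        image_id=stack.image_id,
        channel=stack.channel,
        group=stack.group,
    )
    return out, inventory


# ---------------------------------------------------------------------------
# experiments


def simulate_experiment(
    spec_a: SceneSpec,
    spec_b: SceneSpec,
    n_images: int,
    seed: int,
    out_dir: str | Path,
    group_names: tuple[str, str] = ("groupA", "groupB"),
    overwrite: bool = False,
) -> Manifest:
    """Write a two-group experiment: TIFF stacks, ground-truth CSV and manifest.

    Per-image seeds are derived deterministically from the master seed, so the
    same call reproduces byte-identical files.
    """
    import csv

    if n_images < 1:
        raise ValueError("need at least one image per group")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)

    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_images) % (2**31)
    entries: list[ManifestEntry] = []
    truth_rows = []
    for g, (spec, gname) in enumerate(zip((spec_a, spec_b), group_names)):
        for i in range(n_images):
            img_seed = int(child_seeds[g * n_images + i])
            s = dataclasses.replace(spec, seed=img_seed)
            stack, truth = simulate_scene(s)
            image_id = f"{gname}_{i:03d}"
            stack.image_id = image_id
            stack.group = gname
            fname = f"{image_id}.tif"
            write_stack(stack, out_dir / fname)
            entries.append(
                ManifestEntry(
                    path=fname, series=0, channel=spec.staining, image_id=image_id, group=gname
                )
            )
            truth_rows.append(
                {
                    "image_id": image_id,
                    "group": gname,
                    "true_count": truth.true_count,
                    "true_area_um2": truth.true_area_um2,
                    "seed": img_seed,
                }
            )

    with open(out_dir / "ground_truth.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["image_id", "group", "true_count", "true_area_um2", "seed"]
        )
        writer.writeheader()
        writer.writerows(truth_rows)
    manifest = Manifest(entries)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
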