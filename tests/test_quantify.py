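"""ROI rasterization, component labeling, measurement and size filtering."""

import numpy as np
import pytest

from apoptoquant import (
    BinaryMask,
    ParticleRecord,
    RegionOfInterest,
    filter_particles,
    label_components,
    measure_particles,
    quantify_image,
    rasterize_roi,
)

# ---------------------------------------------------------------------------
# oracles


def point_in_polygon_oracle(px, py, vertices, eps=1e-9):
    """Even-odd ray casting plus explicit on-boundary inclusion."""
    n = len(vertices)
    # boundary check: distance from point to each closed segment
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        dx, dy = x2 - x1, y2 - y1
        L2 = dx * dx + dy * dy
        t = 0.0 if L2 == 0 else max(0.0, min(1.0, ((px - x1) * dx + (py - y1) * dy) / L2))
        if (px - (x1 + t * dx)) ** 2 + (py - (y1 + t * dy)) ** 2 <= eps:
            return True
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def flood_fill_count(mask, connectivity):
    """BFS component count oracle."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = mask.shape
    count = 0
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                count += 1
                queue = [(sy, sx)]
                seen[sy, sx] = True
                while queue:
                    y, x = queue.pop()
                    for dy, dx in steps:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            queue.append((ny, nx))
    return count


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


# ---------------------------------------------------------------------------
# rasterize_roi


def test_full_frame_rectangle_covers_everything():
    roi = RegionOfInterest([(0, 0), (9, 0), (9, 7), (0, 7)])
    mask = rasterize_roi(roi, (8, 10))
    assert mask.pixels.all()


def test_degenerate_polygons_rejected():
    with pytest.raises(ValueError):
        RegionOfInterest([(0, 0), (5, 5)])
    with pytest.raises(ValueError):
        RegionOfInterest([(0, 0), (5, 5), (0, 0)])  # zero area


def test_triangle_matches_ray_casting_oracle():
    vertices = [(1.0, 1.0), (8.5, 2.0), (3.0, 8.0)]
    roi = RegionOfInterest(vertices)
    mask = rasterize_roi(roi, (10, 10)).pixels
    for y in range(10):
        for x in range(10):
            assert mask[y, x] == point_in_polygon_oracle(x, y, vertices), (x, y)


# ---------------------------------------------------------------------------
# label_components


def test_diagonal_adjacency_depends_on_connectivity():
    mask = np.zeros((4, 4), dtype=bool)
    mask[1, 1] = mask[2, 2] = True
    assert label_components(mask, 8).max() == 1
    assert label_components(mask, 4).max() == 2


def test_empty_mask_has_no_components():
    assert label_components(np.zeros((5, 5), dtype=bool)).max() == 0


@pytest.mark.parametrize("connectivity", [4, 8])
def test_label_count_matches_flood_fill(connectivity, rng):
    for _ in range(20):
        mask = rng.random((32, 32)) < 0.35
        labels = label_components(BinaryMask(mask), connectivity)
        assert labels.max() == flood_fill_count(mask, connectivity)


def test_bad_connectivity():
    with pytest.raises(ValueError):
        label_components(np.zeros((2, 2), dtype=bool), 6)


# ---------------------------------------------------------------------------
# measure_particles


def test_square_particle_measurements():
    mask = np.zeros((5, 5), dtype=bool)
    mask[1:3, 1:3] = True
    (rec,) = measure_particles(label_components(mask), pixel_size_um=0.5)
    assert rec.area_px == 4
    assert rec.area_um2 == pytest.approx(1.0)
    assert rec.centroid == (1.5, 1.5)
    assert rec.bbox == (1, 1, 3, 3)


def test_single_pixel_particle():
    mask = np.zeros((3, 3), dtype=bool)
    mask[1, 1] = True
    (rec,) = measure_particles(label_components(mask), pixel_size_um=0.5)
    assert rec.area_px == 1
    assert rec.equiv_diameter_um == pytest.approx(2 * np.sqrt(0.25 / np.pi))
    assert rec.circularity == 1.0


def test_digital_disc_circularity():
    mask = disc_mask((64, 64), 32, 32, 20)
    (rec,) = measure_particles(label_components(mask), pixel_size_um=0.5)
    assert 0.9 <= rec.circularity <= 1.0
    # area within 1% of the analytic circle
    assert rec.area_px == pytest.approx(np.pi * 20**2, rel=0.01)


# ---------------------------------------------------------------------------
# filter_particles


def particle(area_px, pixel_size=0.5, circ=1.0):
    area = area_px * pixel_size**2
    return ParticleRecord(
        label=1, area_px=area_px, area_um2=area, centroid=(0, 0), bbox=(0, 0, 1, 1),
        perimeter_um=1.0, circularity=circ,
        equiv_diameter_um=2 * np.sqrt(area / np.pi),
    )


def test_two_micron_diameter_limit_knife_edge():
    # 12 px at 0.5 um/px: 3.0 um^2, d = 1.954 um -> removed
    # 13 px: 3.25 um^2, d = 2.034 um -> kept
    small, big = particle(12), particle(13)
    kept = filter_particles([small, big], min_diameter_um=2.0)
    assert kept == [big]


def test_no_limits_is_identity():
    parts = [particle(a) for a in (1, 5, 40)]
    assert filter_particles(parts) == parts


def test_inverted_bounds_rejected():
    with pytest.raises(ValueError):
        filter_particles([particle(5)], min_diameter_um=3.0, max_diameter_um=2.0)


def test_min_size_filter_is_monotone():
    parts = [particle(a) for a in (3, 8, 13, 30, 80)]
    prev_count, prev_area = len(parts), sum(p.area_um2 for p in parts)
    for lim in (0.5, 1.0, 2.0, 3.0, 5.0):
        kept = filter_particles(parts, min_diameter_um=lim)
        area = sum(p.area_um2 for p in kept)
        assert len(kept) <= prev_count and area <= prev_area + 1e-12
        prev_count, prev_area = len(kept), area


def test_area_mode_filter():
    parts = [particle(a) for a in (4, 12, 40)]
    kept = filter_particles(parts, min_area_um2=2.9)
    assert [p.area_px for p in kept] == [12, 40]


# ---------------------------------------------------------------------------
# quantify_image


def two_disc_image(calibrated, gap=True):
    pixels = np.zeros((40, 40))
    pixels[disc_mask((40, 40), 12, 12, 6)] = 200.0
    cx = 28 if gap else 20
    pixels[disc_mask((40, 40), 12, cx, 6)] = 200.0
    return calibrated(pixels)


def test_separated_discs_count_two(calibrated):
    res = quantify_image(two_disc_image(calibrated, gap=True), 100.0, min_diameter_um=2.0)
    assert res.count == 2


def test_overlapping_discs_merge_into_one(calibrated):
    sep = quantify_image(two_disc_image(calibrated, gap=True), 100.0)
    merged = quantify_image(two_disc_image(calibrated, gap=False), 100.0)
    assert merged.count == 1
    assert merged.total_area_um2 < sep.total_area_um2


def test_area_conservation_with_size_filter(calibrated, rng):
    """Foreground area = surviving + filtered-out particle areas, exactly."""
    pixels = (rng.random((50, 50)) < 0.25) * 300.0
    img = calibrated(pixels)
    all_parts = quantify_image(img, 100.0)
    kept = quantify_image(img, 100.0, min_diameter_um=1.2)
    fg_area = float((pixels > 100).sum()) * 0.25
    assert all_parts.total_area_um2 == pytest.approx(fg_area, abs=1e-9)
    removed = {p.label for p in all_parts.particles} - {p.label for p in kept.particles}
    removed_area = sum(p.area_um2 for p in all_parts.particles if p.label in removed)
    assert kept.total_area_um2 + removed_area == pytest.approx(fg_area, abs=1e-9)


def test_roi_restriction_equals_pre_masking(calibrated, rng):
    pixels = rng.uniform(0, 255, size=(30, 30))
    img = calibrated(pixels)
    roi = RegionOfInterest([(3, 3), (26, 5), (24, 27), (5, 24)])
    via_roi = quantify_image(img, 128.0, roi=roi)
    roi_mask = rasterize_roi(roi, (30, 30)).pixels
    masked = calibrated(np.where(roi_mask, pixels, 0.0))
    direct = quantify_image(masked, 128.0)
    assert via_roi.count == direct.count
    assert via_roi.total_area_um2 == pytest.approx(direct.total_area_um2)
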