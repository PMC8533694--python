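"""Why the count readout flattens for cytosolic staining at high apoptosis rates.

Cytosolic (whole-cell) staining merges adjacent apoptotic cells into single
binarized objects.  This script doubles the event density between two small
groups of clustered scenes and compares how well each readout reflects the
true 2x difference.
"""

import numpy as np

from apoptoquant import SceneSpec, median_filter, quantify_image, rank_sum_test, simulate_scene, z_project


def run_group(event_rate, seeds):
    counts, areas, true_counts = [], [], []
    for seed in seeds:
        spec = SceneSpec(shape=(6, 320, 320), staining="cytosolic",
                         event_rate=event_rate, cluster_strength=0.9, seed=seed)
        stack, truth = simulate_scene(spec)
        img = z_project(median_filter(stack, 1), "max")
        res = quantify_image(img, (spec.background_level + spec.signal_level) / 2,
                             min_diameter_um=2.0)
        counts.append(res.count)
        areas.append(res.total_area_um2)
        true_counts.append(truth.true_count)
    return np.array(counts), np.array(areas), np.array(true_counts)


hi = run_group(2.4, range(100, 110))
lo = run_group(1.2, range(200, 210))

true_ratio = hi[2].mean() / lo[2].mean()
count_ratio = hi[0].mean() / lo[0].mean()
area_ratio = hi[1].mean() / lo[1].mean()
_, p_area = rank_sum_test(hi[1], lo[1])
_, p_count = rank_sum_test(hi[0], lo[0])

print(f"true event ratio (high/low density):   {true_ratio:.2f}")
print(f"count-readout group ratio:             {count_ratio:.2f}   (p = {p_count:.3g})")
print(f"area-readout  group ratio:             {area_ratio:.2f}   (p = {p_area:.3g})")
print()
print("The count ratio is attenuated toward 1 because clustered apoptotic")
print("cells fuse into single objects, and they fuse more often at the higher")
print("density; the stained-area readout tracks the true difference.")
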