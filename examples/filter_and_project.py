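"""How rank filtering handles aberrant hot pixels, and what z-projection does.

Builds a tiny 5x5 image with one aberrant-high pixel and compares the mean
and median filters, then projects a 3-slice column three ways.
"""

import numpy as np

from apoptoquant import CalibratedImage, ImageStack, mean_filter, median_filter, z_project

pixels = np.zeros((5, 5))
pixels[2, 2] = 90.0
img = CalibratedImage(pixels, pixel_size_um=0.5)

print("original centre row:   ", pixels[2])
print("mean filter r=1:       ", mean_filter(img, 1).pixels[2])
print("median filter r=1:     ", median_filter(img, 1).pixels[2])
print()
print("The mean filter spreads the 90 into a 3x3 block of 10s (every window")
print("containing it is lifted); the median filter erases it outright, because")
print("one extreme value never reaches the middle of a 9-value neighbourhood.")
print()

column = np.zeros((3, 1, 1))
column[:, 0, 0] = [0.0, 5.0, 3.0]
stack = ImageStack(column, pixel_size_um=0.5, bit_depth="float")
for method in ("average", "max", "sum"):
    print(f"z-projection {method:7s} of [0, 5, 3] -> {z_project(stack, method).pixels[0, 0]:.4g}")
print()
print("Max projection keeps the brightest slice and so preserves contrast for")
print("signal confined to a few slices of a monolayer; average dilutes it.")
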