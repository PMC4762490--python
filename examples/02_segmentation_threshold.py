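"""Histogram-peak global thresholding on a noisy rendered stack.

Renders a binary plate phantom as a grayscale micro-CT-like stack (dark
empty space at 20, bright mineralised tissue at 200, Gaussian noise), then
runs the VOI extraction -> histogram -> two-peak threshold -> binarization
chain and reports how faithfully the original structure is recovered.
"""

from cervidct import EllipseROI, make_plate_phantom, render_grayscale, segment

phantom = make_plate_phantom(0.2, 0.2, dims=(30, 100, 100),
                             voxel_size_um=20.0, axis=1)
stack = render_grayscale(phantom, bg_level=20, fg_level=200, noise_sd=10, seed=4)

roi = EllipseROI(center_mm=(1.0, 1.0), semi_minor_mm=0.5, semi_major_mm=0.8)
binary, descriptor, diag = segment(stack, roi, slice_start=0, slice_count=30)

error = (binary.data[binary.mask] != phantom.data[:30][binary.mask]).mean()

print(f"VOI: ellipse {descriptor.area_mm2:.2f} mm^2 x {descriptor.slice_count} "
      f"slices x {descriptor.slice_thickness_mm} mm = {descriptor.volume_mm3:.1f} mm^3")
print(f"empty-space peak at gray level {diag['empty_space_peak_level']}, "
      f"bone peak at {diag['bone_peak_level']}")
print(f"global threshold = mean of the peaks = {diag['threshold_level']}")
print(f"voxel disagreement with the generating phantom: {100 * error:.3f} %")
print("\nWith peaks separated by ~18 noise SDs the arithmetic-mean threshold "
      "recovers the structure almost perfectly (<0.5% voxel error).")
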