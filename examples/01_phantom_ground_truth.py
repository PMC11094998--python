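"""Generate a synthetic axial torso slice and print its analytic ground truth.

The phantom is an elliptical soft-tissue contour (here with a 15 mm
posterior rib-hump bulge) containing a bony vertebral body and spinous
process.  Because the contour is analytic, the marker positions, the
distances L12 (body centre → spinous tip) and L13 (body centre → skin) and
the quadrant area fractions are known exactly — they are the reference
every measured value is judged against.
"""

import math

from vertemetry import PhantomSpec, make_phantom

spec = PhantomSpec(
    hump_amplitude_mm=15.0,
    hump_center_rad=math.pi / 2 + 0.5,   # hump on the posterior-left chest wall
    vertebra_center_mm=(5.0, 28.0),      # 5 mm left, 28 mm posterior of centre
    process_length_mm=55.0,
)
slice_, truth = make_phantom(spec, seed=42)

print(f"image: {slice_.shape} px at {slice_.spacing_mm} mm/px")
print(f"truth L12 = {truth.L12_mm:.2f} mm   (spinous-process marker distance)")
print(f"truth L13 = {truth.L13_mm:.2f} mm   (skin-crossing distance)")
print("quadrant fractions (a1 ant-right, a2 ant-left, a3 post-left, a4 post-right):")
print("  " + ", ".join(f"{f:.4f}" for f in truth.quadrant_fractions))
f_back, f_left = truth.aspects
print(f"aspects: f_back = {f_back:.4f}, f_left = {f_left:.4f}")
print("f_back < 0.5: the vertebra sits posterior of the contour's area midline.")
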