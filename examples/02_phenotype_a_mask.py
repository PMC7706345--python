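"""Compute Depth50/Width50 from a binary root mask.

Constructs two toy masks in the full-scale frame (1536 px = 60 cm) —
one vertical root under the hill and one horizontal root at 5 cm depth —
and runs the phenotyping pipeline (fold about the hill, skeletonize,
cumulative-length quantiles).
"""

import numpy as np

from trenchroot import DEFAULT_FRAME, phenotype_image

frame = DEFAULT_FRAME  # 25.6 px/cm; hill at column 768

vertical = np.zeros(frame.shape, np.uint8)
vertical[:512, 768] = 1  # straight down to 20 cm
p = phenotype_image(vertical, frame=frame, hill_column=768)
print(f"vertical root to 20 cm:  Depth50 = {p.depth50_cm:.2f} cm, "
      f"Width50 = {p.width50_cm:.2f} cm, length = {p.total_root_length_cm:.1f} cm")
print("  -> half of a uniform vertical run lies above 10 cm; the root hugs the hill")

horizontal = np.zeros(frame.shape, np.uint8)
horizontal[128, 768:1280] = 1  # 5 cm deep, spanning 20 cm outward
p = phenotype_image(horizontal, frame=frame, hill_column=768)
print(f"horizontal root at 5 cm: Depth50 = {p.depth50_cm:.2f} cm, "
      f"Width50 = {p.width50_cm:.2f} cm, length = {p.total_root_length_cm:.1f} cm")
print("  -> all length sits at 5 cm depth; half of it within 10 cm of the hill")
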