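"""Generate one synthetic trench-profile sample and inspect its truth.

Builds a desk-scale (384 px = 60 cm at 6.4 px/cm) synthetic wall with 12
roots whose maximum depths follow an exponential law censored at 60 cm,
then prints the analytically known root-distribution truth.
"""

from trenchroot import TEST_FRAME
from trenchroot.synth import SynthConfig, generate_sample

cfg = SynthConfig(n_roots=12,
                  depth_law={"kind": "truncated_exponential", "rate_per_cm": 0.1},
                  seed=42)
image, mask, truth = generate_sample(cfg, TEST_FRAME)

print(f"image shape: {image.pixels.shape}  (rows = depth, row 0 = soil surface)")
print(f"mask root pixels: {int(mask.pixels.sum())}")
print(f"truth Depth50: {truth.depth50_cm:.2f} cm   "
      f"(depth containing 50% of total root length)")
print(f"truth Width50: {truth.width50_cm:.2f} cm   "
      f"(distance from the hill containing 50% of root length)")
print(f"truth root length: {truth.total_root_length_cm:.1f} cm")
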