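"""Individualized reach targets and game impact heights.

Builds the standardized high/middle/low targets for one participant from
their body dimensions, checks the inverse geometry, and derives the five
impact heights for each game level from baseline lumbar flexion.
"""

import numpy as np

import dodgekin as dk

dims = dk.BodyDimensions(hip_height=1.0, trunk_length=0.5, arm_length=0.7,
                         eye_height=1.6, shin_height=0.45)
baseline = dk.LumbarBaseline(lumbar_flexion_high=15.0, lumbar_flexion_mid=30.0,
                             lumbar_flexion_low=60.0)

print("Standardized targets (shoulder at 90 deg, elbow extended):")
for name, theta in (("high", 15.0), ("middle", 30.0), ("low", 60.0)):
    target = dk.standardized_target_location(dims, dk.TargetSpec(theta))
    back = dk.recover_hip_flexion(dims, target)
    print(f"  {name:6s} hip flexion {theta:4.0f} deg -> "
          f"AP {target[0]:.3f} m, vertical {target[2]:.3f} m "
          f"(inverse recovers {back:.4f} deg)")

print("\nImpact heights IH0..IH4 (m) per game level:")
for level in (1, 2, 3):
    ih = dk.impact_heights_for_level(dims, baseline, level)
    print(f"  level {level}: " + "  ".join(f"{h:.3f}" for h in ih.heights))

# IH0 is always eye height; IH4 drops level by level as the required lumbar
# flexion grows, which is exactly how the game progressively coaxes deeper
# forward bending out of the player.
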