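"""One noisy synthetic reach through the kinematic reduction chain.

Simulates a reach with 1 mm marker noise, re-estimates segment poses and
Euler joint angles from the markers, and compares recovered excursions with
the generator's ground truth.
"""

import numpy as np

import dodgekin as dk

dims = dk.BodyDimensions(1.0, 0.5, 0.7, 1.6, 0.45)
model = dk.BodyModel(dims)
target = np.array([0.45, 0.0, 0.85])  # mid-sagittal, below standing hand

trial = dk.simulate_reach(dims, target, dk.StrategyProfile(), seed=1,
                          noise_std=0.001, model=model)
gt = trial.ground_truth
print(f"ground-truth movement time: {gt.movement_time_ms:.0f} ms, "
      f"COM displacement (AP, ML, vert): "
      f"{np.round(gt.com_displacement, 3)} m")

series = dk.compute_joint_angles(trial.trajectories, model.clusters,
                                 model.chain)
print(f"{'joint':9s} {'recovered':>10s} {'truth':>8s} {'error':>8s}  (deg)")
for s in series:
    rec = (s.flexion_extension[gt.contact_index]
           - s.flexion_extension[gt.onset_index])
    truth = gt.excursions[s.joint_name]
    print(f"{s.joint_name:9s} {rec:10.2f} {truth:8.2f} {rec - truth:8.2f}")

# With 1 mm marker noise a single trial's excursions come back within a
# couple of degrees; averaged over many seeds the per-joint bias is below
# half a degree, and the residuals shrink to machine precision when
# noise_std=0.
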