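# Methods notes

## Coordinate and angle conventions

All data are held in meters in a right-handed frame with AP = +x (forward),
ML = +y (leftward), vertical = +z (up). Joint rotations are decomposed with
an intrinsic Euler sequence about the parent segment's axes: flexion-
extension about ML, then lateral bending about AP, then axial rotation
about vertical (Y-X-Z). Intrinsic-vs-extrinsic and the axis assignment are
package choices (the common biomechanical reading of the named sequence)
and are configurable through the `sequence` argument of the decomposition
functions. Frames whose middle angle is within 0.5° of ±90° are flagged
(near gimbal lock the first/third angles trade off and excursions become
unreliable); the planar reaching tasks modeled here stay far from that
region. Each joint definition carries a `flexion_sign` so that the reported
flexion matches the anatomically positive direction (e.g. knee flexion is a
negative parent-relative rotation about +ML in this chain).

## Rigid pose estimation

Segment poses come from a closed-form least-squares (Kabsch) fit of each
cluster's template to the observed markers, batched over frames via stacked
3×3 SVDs, with the determinant forced to +1 so near-planar noisy clusters
cannot flip into reflections. Frames with fewer than three valid (non-NaN)
markers, or with a collinear valid subset, are flagged unresolvable and
propagate NaN through joint angles, COM and the per-trial records rather
than being silently filled. Missing marker samples may be linearly
interpolated beforehand, but only across gaps of ≤ 5 frames (50 ms at
100 Hz); longer gaps are left missing so the affected trial is excluded
with a visible flag.

## Filtering and event detection

Fingertip position is smoothed and differentiated with a Savitzky–Golay
filter, default 41 points and order 4 at a 0.01 s sampling interval (the
sample plus 20 neighbors each side); velocity is the fitted polynomial's
derivative, and speed its Euclidean norm. Within half a window of the
series edges the polynomial fitted to the nearest full window is evaluated
instead of a symmetric fit, so no event-relevant samples are discarded.
The filter is exact for polynomials up to degree 4 on interior samples,
which the tests assert at machine precision.

Movement onset is the last sample at or below 5% of peak speed searching
backward from the peak; target contact mirrors this forward. The threshold
is applied to speed (the norm), not a signed component — the protocol text
leaves this open and the norm is the conventional choice. If the threshold
is never reached the search clamps to the window edge and flags the trial.
The per-trial search window is bounded by the launch schedule: warning time
(300 ms before launch) to impact + 0.5 s; the peak is the global speed
maximum inside that window, and trials whose peak speed is below
0.15 m/s are flagged undetectable (quiet standing never triggers events).
Ties at the threshold resolve to the sample closest to the peak, which the
backward/forward searches produce by construction.

## Whole-body center of mass

A 14-segment model: head+neck, trunk (pelvis consolidated, hip to
shoulder), and bilateral upper arms, forearms, hands, thighs, shanks and
feet. Mass fractions and COM locations (fraction of segment length from the
proximal end) are Winter's standard values, shipped as
`src/dodgekin/data/winter_segments.csv`; the table is injectable so
alternative parameter sets can be swapped in, and its fractions must sum to
1 ± 0.01. The whole-body COM is the mass-weighted mean of segment COMs
renormalized by the summed fractions of the segments present. Left-side
endpoints reuse the right-side chain under the mid-sagittal symmetry
assumption of this protocol (bilateral reaches with both hands on the
ball); data violating that symmetry would need left-side clusters.

## Target geometry and impact heights

The standardized-reach forward model is a planar two-link chain: trunk
vector at the hip-flexion angle from vertical, arm vector perpendicular to
it (shoulder at 90°, elbow extended). Its vertical coordinate is strictly
decreasing in hip flexion on (0°, 90°), so the inverse is a bracketed
Brent root-find, accurate to well below 1e-6°. Impact heights: IH0 = eye
height at every level; IH4 = the forward-model hand height at the trunk
inclination implied by that level's baseline lumbar flexion (the
lumbar-to-inclination mapping is injectable, identity by default, because
the exact conversion used by the original software is not documented);
IH1–IH3 linearly interpolated, matching the evenly spaced distributions
shown for the task. IH4 is floored at shin height − 0.05 m ("approximately
the shins" is not quantified; 5 cm below the measured shin landmark is the
package's cutoff).

## Game engine

Inter-launch intervals are uniform on mean ± halfwidth (3.3 ± 0.3 s read
as bounded jitter; the true distribution is unstated). Each set contains
exactly 3 balls per impact height, one at each lateral offset, in a
seeded random permutation; duck trials occur exactly at IH0. One static
bonus ball follows each game-level set (6 per game). The practice level
uses 2 sets of 15 like the game levels (its ball count is otherwise
undocumented, and this count makes the published starting-balance
arithmetic exact: 30 balls at each of 1/2/5/10 ¢ plus six 25 ¢ bonus balls
= 690 ¢). Losses equal rewards, which is what makes the all-failure
balance exactly zero. Ball flight is straight-line constant-speed — impact
geometry, not flight realism, is what the analysis consumes. Block success
is center-to-center distance between the hand-held ball and the launched
ball ≤ two ball radii (0.12 m each, a 24 cm regulation ball) at any
instant of flight; duck success is the head top below the path's lower
edge minus a 0.05 m margin at crossing time (no explicit duck geometry is
documented; this is the package's rule).

## Synthetic generator

The generator is the package's test bed, not a biomechanical simulator. It
drives the sagittal linkage with minimum-jerk joint programs: the strategy
profile's apportionment weights fix the *direction* of the joint-excursion
vector and a single scale is solved (bracketed root-find) so the fingertip
meets the target height; reaches above the standing hand height are
carried by the arm weights alone, since postural flexion cannot raise the
hand. `forward_bias` then adds ankle lean solved to shift the contact hand
AP position by exactly that many meters, and `crouch_bias` adds a squat
pattern (ankle:knee:hip = 0.5:1:0.5, trunk near vertical) solved to drop
the COM by that amount. Biases apply to block trials only; duck trials use
a pure squat that clears the ball path — mirroring the empirical absence
of display-condition effects on ducking. Markers are rigidly attached
4-marker clusters per segment plus fingertip/ankle/left-hand point
markers, with isotropic Gaussian noise (default σ = 0.5 mm, roughly 5×
the optical system's nominal resolution) and no temporal autocorrelation
or soft-tissue artifact — real marker error is autocorrelated and
pose-dependent, so passing recovery tests bounds algorithmic error, not
real-data accuracy.

Ground-truth events are defined operationally: the Savitzky–Golay speed
and 5% rule applied to the *noiseless* fingertip trajectory. Excursions,
COM displacement and hand position are then read off the noiseless program
at those samples. This choice makes recovery tests isolate the
marker → pose → signal chain (on noiseless markers the pipeline matches
ground truth to machine precision); the filter and detectors themselves
are validated independently against analytic polynomial, derivative and
brute-force-scan oracles. Defining ground truth from the continuous
profile instead would mix filter bias into every recovery comparison.

## Problem sizes and numerical choices

End-to-end tests run a reduced round — one ball per impact height per set,
no practice (30 launched balls, ~100 s of 100 Hz data) — and the
Monte-Carlo noise study uses 100 seeded single reaches; recovery on
noiseless data is at machine precision, so these sizes do not limit what
the tests demonstrate. Root-finds use Brent's method on sign-change
brackets located by coarse grid scans (61 points), tolerance 1e-10 in the
solved variable. All schedule and noise randomness flows through
`numpy.random.default_rng` seeds; identical seeds give byte-identical
schedules, marker data and result tables.

## Known limitations

Planar (sagittal) joint programs: lateral bending and axial rotation are
exercised only through the rotation-algebra unit tests, not the end-to-end
generator. No anatomical-landmark calibration or functional joint centers:
joint centers are fixed points in segment frames supplied by the body
model. No kinetics, balance control or muscle dynamics. Inferential
statistics (the original study's MANOVA/post-hocs) are deliberately out of
scope; summaries stop at means, SDs, counts and paired condition
differences. Human-subject effect sizes are not reproducible here — the
strategy profiles are configurable emulations used for direction checks,
not fits to the published data.
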