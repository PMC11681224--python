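# Methods

## Measurement model

The runner is treated as a single rigid blob whose geometric centroid proxies
the body's centre of mass. Four fixed, synchronized cameras each observe one
25-m segment of a straight 100-m track; within a segment the world-to-image
mapping is assumed affine in the horizontal pixel coordinate, so two marker
columns per camera suffice to calibrate it. Position is therefore recovered
per frame, per camera, as

    location = (x_centroid - M_end_px) * m_per_px + segment_offset,
    m_per_px = span / (M_start_px - M_end_px),

with a *signed* metres-per-pixel factor so mirrored camera orientations work
unchanged. No lens-distortion or perspective correction is applied: a runner
at a different depth than the marker line, or near the edge of a wide-angle
view, acquires a position error the model cannot see. This is a known
limitation of the two-point scale, accepted for its robustness and
zero-calibration-effort deployment.

## Detection

Foreground is `|F - B| > tau` on grayscale frames (absolute difference, so
clothing darker *or* lighter than the track is detected), `tau = 40` of 255.
The binary mask is cleaned with a `3x3` median filter — implemented as an
exact integer majority vote, which for binary images equals the sliding-window
median — with edge replication at the borders, chosen so the filter cannot
manufacture foreground at frame edges. Components are labelled with
8-connectivity (diagonal limb pixels stay attached); components under
`min_blob_area_px = 25` pixels are discarded as noise, and the largest
survivor wins, ties broken by the smaller bounding-box top-left corner. A
frame with no survivor yields a missing value, not an error: the runner is
simply not in that view.

Thresholding uses the strict inequality (`> tau`), and the centroid is the
arithmetic mean of the component's pixel coordinates rather than its
bounding-box centre; the mean is less sensitive to a few stray limb pixels.

## Fusion

Segment tracks are only trusted within their nominal 25-m range plus 1 m of
slack (the centroid legitimately crosses a marker line mid-stride). Stitching
picks, per frame, the reporting camera whose segment midpoint is nearest the
reported location; exact ties go to the lower-offset camera. This replaces a
sum of piecewise maps that would be ill-defined whenever two cameras report
simultaneously — precisely the handover frames. Interior gaps are filled by
linear interpolation against frame index (the minimal assumption over a
4-frame-scale gap); leading/trailing gaps take the nearest present value so
no motion is manufactured before the start signal. The filled series is
smoothed by a centred moving average, default window 5 frames, with the
window shrinking symmetrically at the ends — this preserves linear trends
exactly and adds no phase lag. Fused locations are clamped to
`[0, track_length]`.

## Speed and subtasks

Speed is the secant over a `w = 4`-frame window (0.133 s at 30 Hz),
`v_i = (loc[i+w] - loc[i]) / (t[i+w] - t[i])`, with `dt` taken from actual
timestamps so variable frame rates degrade gracefully. **Each sample is
anchored at the window midpoint** (mean of the end times and end locations).
The secant measures the average speed across the window; anchoring it at the
leading frame would date it half a window early, and during the acceleration
phase (dv/dt up to ~5 m/s^2) that systematic shift biases the first-bin mean
by several percent. Midpoint anchoring makes the residual bias second-order
in the window length; the end-to-end tests confirm sub-2% recovery in every
bin including V1.

Subtask speeds V1..V10 are arithmetic means of the samples whose anchored
location falls in each 10-m bin. Bins are half-open `[start, end)` with the
final bin closed at 100 m, so every sample is counted exactly once even when
it lands on a boundary. An empty bin reports a missing mean with
`n_samples = 0`. The whole-run time interpolates the 0-m and 100-m crossings
of the sample locations (extrapolating with the nearest secant slope when the
samples start past 0 or stop short of 100, which they do by at most half a
window); for a constant-speed track this reproduces `distance/time` to
machine precision.

Report tables round speeds half-up to 3 decimals; internal values keep full
precision. Cohort summaries compute each athlete's speed first (rounded to
3 decimals) and then average, the order conventional summary tables use.

## Agreement statistics

Pearson r is computed from centred dot products, clamped to `[-1, 1]`, with
values within floating-point rounding of +/-1 reported as exactly +/-1 (a
series against itself must give 1.0). The 95% CI uses the Fisher z
transform; the p-value is two-sided from the t distribution with n-2 df
(one- vs two-sided being otherwise ambiguous, the conservative choice).
Agreement bands are applied to |r| — agreement strength is a magnitude — and
the printed band edges are made contiguous as
low < 0.50 <= moderate < 0.70 <= high < 0.90 <= very high, so the bands
partition `[-1, 1]`. Bland-Altman uses the conventional fixed 1.96 multiplier
(not a small-sample t quantile) with the n-1 SD; `n_outside_loa` counts
differences strictly outside the limits.

## Synthetic generator

The generator defines the conditions under which the pipeline is validated:

- **Velocity profile** — `v(t) = v_max (1 - exp(-t/tau))` until the runner
  reaches `decel_onset_m`, then exponential decay at `decel_rate` per second;
  position by trapezoidal integration at the frame rate. The three-phase
  structure (acceleration, maximum velocity, deceleration) is standard sprint
  kinematics; the specific functional form is this package's choice for being
  smooth and two-parameter per phase. Defaults v_max 8 m/s, tau 1.5 s, onset
  70 m, 3 %/s finish a 100 m in ~14.2 s at 7.0 m/s average — a trained
  collegiate sprinter, consistent with the validation cohort.
- **Rendering** — a 16x60 px rectangle at gray level 28 on a uniform
  165 background (dark kit on a bright track), additive clipped Gaussian
  pixel noise (default sd 4, stress tests use 8), optional small moving
  distractor blobs kept below the blob-area floor by default (a hard mode
  raises them to exercise largest-blob arbitration), and marker columns at
  570/70 px giving 0.05 m/px over each 25-m segment. The background image
  carries its own independent noise draw, as a real pre-run capture would.
- **Ground truth** — the rasterized silhouette centroid per camera per frame,
  and per-bin true mean speeds from a fine-step (0.25 ms) integration where
  a bin's mean speed is bin width over time-in-bin.

What the generator does *not* emulate: articulated limbs (centroid jitter is
approximated by pixel noise), shadows, lighting drift, lens distortion,
perspective parallax, or imperfect camera synchronization. Passing tests
therefore demonstrate the correctness and noise robustness of the algorithm
chain, not field accuracy on real footage, where contrast and calibration
placement dominate the error budget.

## Numerical and design notes

- Detection's batch path processes whole frame stacks; a dedicated test pins
  it to the composition of the single-frame stage functions.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the render spec; identical (profile, spec, seed) triples are byte-identical.
- Degenerate inputs fail loudly and early: empty frame directories, mixed
  frame sizes, coincident markers, even filter windows, tracks with fewer
  than two detections (e.g. a zero-contrast runner) all raise with the
  offending camera or field named.
- End-to-end validation sizes: recovery tests run full-length 100-m sprints
  (~430-500 frames x 4 cameras) across 10 noise seeds for the constant and
  three-phase profiles; unit tests use 20-m two-camera runs.

## Known limitations

- A single runner is assumed; the largest-blob rule fails for a pacer or
  passer-by larger than the athlete.
- The two-point scale ignores depth: accuracy depends on the athlete running
  the marked line.
- Camera handover arbitration is heuristic; a systematic calibration offset
  between adjacent cameras would appear as a small step at 25/50/75 m.
- Whole-run time is interpolated from speed-sample locations and is accurate
  to about one frame; it is a convenience summary, not a timing-gate
  replacement.
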