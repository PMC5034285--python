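# Methods

## Tail deflection

The deflection statistic reduces the tail posture in one binarized frame
to a single signed number. The pipeline:

1. Fit the image-moment equivalent ellipse to the full silhouette
   (centroid + second-order central moments; axis lengths 4√λ).
2. Split the pixels into anterior and posterior halves by the sign of
   their projection onto the major axis. Each half's equivalent-ellipse
   minor axis is then (approximately) the perpendicular bisector of that
   half's chord, so for a circular bend the two minor axes intersect at
   the center of curvature.
3. R̄ = mean distance of all fish pixels to that intersection;
   deflection = L0/R̄ with L0 the resting body length, making the value
   dimensionless and, for an ideal arc, equal to L0·κ.
4. Sign: negative when the center of curvature lies on the larva's left
   (+90° from the head direction in the image plane).

Degenerate cases: minor axes within 1° of parallel mean R̄ → ∞ and
return exactly 0 (straight fish); an empty half after the split also
returns 0 with a warning. Frames empty after thresholding contribute 0
to a series with a logged frame index.

The head direction is needed only for the sign. When it is not supplied
explicitly, the head half is taken to be the pixel group with the
rounder equivalent ellipse (larger minor/major ratio): the head + yolk
blob is wider than the tail. On synthetic constant-width bodies this
heuristic is arbitrary, so fixtures either taper the body or pass
`head_direction` explicitly. Binarization is a fixed configured
threshold: the imaging preparation (pigment-free larva, infrared
illumination) is high-contrast, and determinism matters more here than
adaptivity.

Accuracy on rendered arcs: the measured deflection matches L0·κ within
~1% across κ·L0 ∈ [0.2, 1.5] at 20 px/mm, well inside the 10% the
downstream model identification needs. Resolutions below ~15 px/mm per
body width start to bias the split-ellipse geometry.

## ARX model

Each kinematic parameter (axial speed mm/s, lateral speed mm/s, yaw
speed rad/s — all body-frame, forward/left/CCW positive) is modeled as

    y(k) = −Σ_{i=1..N} a_i y(k−i) + Σ_{j=0..M} b_j x'(k−j) + e(k)

with a₀ ≡ 1 (causality) and x′ the input transform. Defaults follow the
identification on real free-swim data: lateral/yaw use the signed
deflection with N = M = 7 (35 ms at 200 Hz); axial uses |x| with N = 20
(100 ms), M = 7, because forward thrust is independent of beat side.
The sign convention (a-terms moved to the right-hand side with a minus)
is stored in every serialized model.

Fitting builds one design-matrix block per bout, each initialized at
rest (lags before the bout are zero — bouts start from quiescence), and
solves the pooled least-squares problem; rank-deficient systems take the
minimum-norm solution. Evaluation is free-run: the model is driven by
the deflection alone and its output fed back into its own lags, which is
the quantity that matters for dead reckoning. One-step-ahead
(teacher-forced) prediction is exposed separately.

`bootstrap_evaluate` splits at the bout level (never within a bout),
fits on the training concatenation, free-runs each test bout from rest
and pools all test frames into one R² per target; mean ± sd over
iterations is reported (default 100 iterations, 80/20).
`cross_amplitude_evaluate` median-splits bouts on max |deflection|
(stable sort, ties to "small") and evaluates each half's model on the
other.

Noise model of the synthetic generator: the error e(k) enters the
recurrence (equation error, fed back through the AR part) — the model
class under which least squares is consistent. To target a given
output-noise-to-signal variance ratio ρ, the equation-noise sd is set to
√(ρ·var(signal)) divided by the L2 gain of 1/A(z) (sum of squared
impulse response). For ρ = 1/3 the expected pooled free-run R² is the
variance ratio 1/(1+ρ)⁻¹-complement, i.e. 0.75, and the bootstrap
reproduces it to a few thousandths.

## Trajectory integration

Forward Euler at the native frame rate: heading advances by yaw·dt,
position by the body-frame velocity rotated at the current heading (body
x = heading, body y = body-left). At bout time scales (~300 ms, 200 Hz)
the O(dt) endpoint error on a maximally tight turn (v = 2 mm/s,
ω = π rad/s) is ~0.8% of the displacement — far below the model's own
prediction error. A midpoint variant (half-step heading) is available
and roughly two orders of magnitude more accurate.

Per-bout errors compare net heading change, movement direction (angle of
the net displacement relative to the initial heading) and displacement
magnitude between predicted and observed paths; aggregates are
root-mean-square over bouts (reported and labeled as RMS). Bouts with
zero observed displacement have no defined movement direction and are
excluded from that component with a logged count.

## Bout detection and classification

Detection thresholds a 15 ms moving average of |deflection| with
hysteresis: onset at the upward crossing of `on_threshold` (backtracked
to the preceding `off_threshold` crossing so slow attacks do not delay
the boundary), offset when the envelope stays below `off_threshold` for
`min_quiet_ms`; bouts shorter than `min_bout_ms` are dropped. Because
the smoothing window sees one frame of context beyond a segment,
re-detection on excised segments can shift boundaries by a frame; it
never splits or merges bouts.

The DTW distance uses the classic symmetric step pattern: absolute
difference local cost, diagonal steps (and the initial cell) weighted
twice, horizontal/vertical once, total cost normalized by n+m. Under
this normalization a single-cell comparison returns |s₁−s₂| and the
distance between equal-length series never exceeds their no-warp mean
absolute difference. The DP is validated against exhaustive enumeration
of all monotone warping paths on short series.

Fuzzy KNN (k = 5, fuzzifier m = 2, Keller weights d^(−2/(m−1))) pools
the k nearest prototypes per category; an exact match forces membership
1; argmax ties resolve in the canonical category order (scoot <
asymmetric scoot < routine turn < C bend < burst) with a logged flag.
Since the five categories are chirality-free while individual bouts bend
left or right, the default distance is the minimum over the query
segment and its mirror (`mirror_invariant=False` restores raw DTW).
Amplitude/duration normalization before DTW is deliberately off by
default.

Category-proportion comparisons run one 2×2 chi-squared test per
category (category vs rest × condition A vs B, no continuity
correction) with a Bonferroni factor of 5, matching per-category
significance reporting; a category absent from both conditions yields
p = 1.

## Virtual environments

Both tasks are simulated at the state level (angles, distances, apparent
sizes), not as rendered pixels — the behavioral logic depends only on
these quantities. World-frame state is always complete; the feedback
modes differ only in the display snapshot shown to the agent: `realtime`
refreshes every frame, `delayed` only while the predicted planar speed
|(axial, lateral)| is below 0.2 mm/s (i.e. between bouts), `open_loop`
never. A configurable display latency (default 0 for determinism; the
physical loop in such rigs is ~70 ms) can lag the feedback.

**OMR.** The grating drifts at 10 mm/s with a 10 mm period; each trial
starts with the grating direction at a uniformly random angle θ₀ ∈
(−180°, 180°] to the heading; stimulation lasts 6 s (120 trials per
session by default, with a 20 s steady period between trials that is not
simulated). The larva's axial displacement is amplified by a gain of 3
before application. Alignment metrics (fraction with |θ| < 30°, mean |θ|
per successive bout, latency vs initial angle) use only trials with at
least one bout, applied at the metrics layer so raw sessions stay
complete.

**Prey capture.** A 0.05 mm-radius prey appears 1.5 mm away at ±90°
azimuth (apparent size 2·arctan(r/d) ≈ 4°) and sweeps toward 0° at
20°/s; at the first bout onset the prey freezes in the world frame and
thereafter only the larva's predicted trajectory changes its displayed
azimuth and size (in delayed mode both are held during bouts). Capture:
distance ≤ 0.4 mm. Failure: |azimuth| > 90°. Timeout: the sweep reaches
0° with no bout. The azimuth is measured from the heading. One-third of
trials are delayed-feedback by default. The shuffled control re-scores
each realized path against prey at uniform random azimuths in ±90° at
1.5 mm and reports the mean capture fraction.

**Agents.** Scripted fixtures, no learning: an inert agent, a library
replay agent, a proportional controller for OMR and a prey seeker. The
turn-calibrated agents exploit the linearity of the lateral/yaw models:
the heading change of a scaled turn template scales with it exactly, so
the scale for a desired turn is computed once from the pipeline. The
seeker strikes when the (displayed) prey azimuth enters ±30° and then
alternates aiming turns with forward scoots; it typically captures in 3
bouts from 1.5 mm.

## Synthetic generator

`synth` defines the study conditions for all tests. Bout deflections are
sinusoids at a category-typical frequency (20–30 Hz band) under a
raised-cosine (Tukey α = 0.5) envelope, with the category's asymmetry
added as a same-envelope bias (turns keep a net one-sided bend); C bends
get a fast quarter-cycle attack and a weaker counter-oscillation;
100 ms of quiet pads each side. Per-category defaults (duration, peak,
asymmetry: scoot 0.30 s/0.55/0; asymmetric scoot 0.25/0.30/0.45;
routine turn 0.30/0.85/0.45; C bend 0.30/1.60/0.15; burst
0.55/1.25/0) were chosen once for qualitative resemblance to the five
canonical maneuvers and for clear inter-category separation; libraries
jitter duration ±15%, frequency ±2 Hz and peak ±10% per bout and draw
the bend side at random.

The ground-truth ARX triple uses modest stable poles (0.2–0.6) and
b-kernels scaled so a default scoot advances ~0.5 mm and a routine turn
re-orients by a few tens of degrees — the magnitudes of real bouts.
Rendering draws a constant-width (optionally tapering) band around a
circular-arc midline by distance thresholding, so the curvature, arc
center and band geometry are analytically known.

What the synthetic benchmarks show: that each stage is correct against
its mathematical definition and that the stages compose (render → track
→ identify → integrate → simulate closes the loop). What they do not
show: performance on real video (occlusion, uneven illumination,
pigment), real bout-to-bout kinematic variability beyond the linear ARX
class, or real animals' feedback policies — the scripted agents are
controllers, not larvae, so task success rates are upper bounds, not
behavioral predictions.

## Numerical choices and limitations

- Angles are stored wrapped to (−π, π] (degrees: (−180, 180]); files
  state units in the column names.
- Least squares via `numpy.linalg.lstsq` (minimum-norm on rank
  deficiency); free-run prediction via `scipy.signal.lfilter` with a
  1e12 overflow guard naming the first divergent frame; the generator's
  recurrence is an independent hand-rolled loop so the two routes
  cross-check each other.
- Random stable test systems draw coefficients directly at modest
  magnitude with rejection on root radius (< 0.95): dense random pole
  sets of order 20 produce astronomically large coefficients and
  ill-conditioned regressions that no identification method should be
  expected to invert exactly.
- Identification tests use white-noise inputs: 20–30 Hz narrowband bout
  waveforms are not persistently exciting enough to pin down 27
  coefficients to machine precision, though they are ample for the
  accuracy the task needs.
- One global seed fans out to all generators through fixed offsets;
  every CLI output embeds the config hash and seed.
- The library ships in two equivalent on-disk dialects (HDF5; CSV
  directory + JSON manifest), both round-tripping at full double
  precision.
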