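# Methods

This note documents the models and procedures implemented in `blinkglass`,
the defaults chosen where the method leaves details open, and what the
synthetic study conditions do and do not establish.

## Problem setting

A glasses-mounted camera images one eye via a hot mirror from the temple,
producing low-resolution, perspective-skewed, infrared-like frames at
~30 Hz. The goal is to measure eye closure — blinks, blink rate, and
PERCLOS — reliably enough to track driver drowsiness, and to quantify how
well the glass-derived measures agree with a research-grade video eye
tracker that reports pupil area at ~500 Hz and loses its samples whenever
the pupil is occluded.

## Keypoint regression network (LGN)

**Model.** Six eyelid landmarks (temporal corner, nasal corner, two
upper-lid, two lower-lid points) are regressed via heatmaps: the network
outputs one probability map per landmark at half the input resolution, and
the landmark is the argmax cell (ties broken at the lowest row-major index;
an all-zero map flags the landmark invalid). Ground-truth maps hold a 2-D
Gaussian, peak exactly 1.0, centred on the landmark position rounded to the
heatmap grid. The training loss is the squared pixel difference summed over
each map and averaged over the N = 6 landmarks.

**Architecture.** A stem convolution module (3×3 conv → batch norm → ReLU)
followed by 2×2 max-pooling takes the 128×128 input to 64×64. The trunk is
an hourglass built from nested two-branch residual blocks: the upper branch
applies three convolution modules at full resolution; the lower branch
max-pools to half resolution, applies three convolution modules and the
next nested block, and returns via 2× nearest-neighbour upsampling; the two
branches are added pixel-wise. Nesting depth is a constructor parameter
(default 4, so the innermost features live at 4×4 when the heatmaps are
64×64). A head module plus a 1×1 convolution emits the 6 maps. Channel
width is 12 throughout (~34k parameters — about two orders of magnitude
under the 5M "lightweight" budget). The input is single-channel; under
infrared illumination the camera's colour planes carry no independent
information.

**Training.** Plain SGD, initial learning rate 0.001 reduced by ×0.1 every
10 epochs; momentum 0.9 and no weight decay (unspecified upstream; standard
values). Batch size 16, 30 epochs by default. Per-image loss gradients are
summed over the batch. Two stabilizers make this fixed schedule reliable:
the final 1×1 regression convolution is zero-initialized (initial
predictions are flat, so early steps are small), and the global gradient
norm is clipped to 50 before each update — without them the summed heatmap
gradients (thousands of pixels per map) can blow up a plain-SGD run within
an epoch. The target Gaussian sigma is 3 heatmap pixels by default: broader
targets spread gradient signal and converge markedly faster under this
optimizer; sigma is configurable and the codec itself is exact for any
sigma > 0. Frames are scaled to [0,1] and standardized by the training
set's mean/sd (stored in the checkpoint so inference matches). All
randomness — weight init, batch order, synthetic data — flows from explicit
seeds; training is bit-reproducible.

Everything here, including backpropagation, is implemented on numpy float32
arrays; convolutions run as one BLAS matmul per kernel offset. A full
500-frame, 30-epoch run takes ≈8–9 minutes on one CPU core.

## From keypoints to signals

The open-eye area is the absolute shoelace area of the landmark hexagon
(temporal corner → upper-lid pair → nasal corner → lower-lid pair), in px².
The eye aspect ratio (EAR) — mean of the two upper/lower lid-pair distances
over the corner distance — is provided as an alternative; on the renderer's
geometry the two measures are strictly co-monotone in eyelid aperture.

## Blink detection

**Glass (area) signal.** The 30 Hz area signal is linearly interpolated
onto a uniform 250 Hz grid (invalid samples bridged linearly). A sample is
a candidate blink minimum if it is the minimum within ±50 ms and dips below
the local baseline — a centred rolling median, 2 s window, edges
replicate-padded — by at least 30% of that baseline (`min_depth_fraction`,
default 0.3; rejects noise dips). Candidates closer than 100 ms are
clustered and the deepest (earliest on ties) represents the cluster. From
each minimum the signal is scanned backward and forward, at most 1 s each
way, for the *stable point* where it stops increasing: `plateau_len` = 3
consecutive one-sample differences ≤ 0, with the boundary placed at the
plateau sample nearest the minimum. A plateau only qualifies once the
signal has recovered at least half the blink depth — otherwise the flat
trough of the blink itself would stop the scan. Overlapping events are
merged, keeping the deepest minimum. On noiseless synthetic blinks the
recovered start/end are within one 30 Hz sample of truth (the information
limit of the 30 Hz signal).

**Pupil signal.** Each maximal missing-sample run is extended backward and
forward to the same kind of stable point, without scanning across a
neighbouring missing run (so rapid double blinks stay distinct; any
residual overlap between consecutive events is split at its midpoint). The
extended interval strictly contains the missing run except at recording
boundaries, where it is clamped. The event minimum is placed at the middle
of the missing run.

Blinks longer than 2.0 s are excluded (strictly longer; a 2.0 s event is
kept).

## Drowsiness metrics

PERCLOS and blink rate are computed over a 60 s window advanced in 0.1 s
steps; windows are referenced by centre and partial windows at the edges
are dropped, giving exactly ⌊(T−60)/0.1⌋+1 windows. A blink is counted in a
window when its minimum falls inside (half-open interval); counts scale to
blinks/min. Each blink contributes a closure interval of 20% of its
duration centred on its minimum — the standard surrogate for "eyelids
covering >80% of the eye" when only event times are available — and PERCLOS
is the percentage of the window covered by the union of closure intervals.
An alternative PERCLOS computed directly from the area signal (area below
20% of a rolling open-eye baseline) is provided for comparison.

Cross-device agreement uses greedy one-to-one matching of reference blinks
to candidate blinks by temporal overlap (any positive overlap by default; a
majority-overlap rule is available), and Pearson correlation of the paired
metric series (values paired by nearest window centre within 0.05 s).
Recordings are aligned on the extended eyes-closed epoch at the start of a
session: the closure end is the linearly-interpolated time at which each
signal first recovers to 90% of its open baseline (95th percentile of valid
samples), a definition that lands at the same physical instant for both
the area and the pupil signal; the clock offset is the difference of the
two closure-end times.

## Synthetic data generator

**Frames.** The eyelid boundary is modelled as two parabolic arcs meeting
at the corners, opening symmetrically about the eye axis to
`0.3 × eye width × openness` half-aperture; lid keypoints sit at 1/3 and
2/3 arc length (computed numerically). The temple-camera viewpoint is a
horizontal shear of `tan(skew)` applied to image and keypoints alike, so
annotations stay exactly on the rendered boundary. Intensities mimic
infrared contrast (bright sclera, dark iris disk, mid skin), smoothed by a
1 px Gaussian, with additive Gaussian sensor noise. Frames are 128×128 by
default (the camera's true resolution is not public; the size is
configurable). Dataset sampling draws openness uniformly on [0,1], width,
shear (±25°), noise and intensity levels from plausible ranges, with a
cosmetic male/female split mirroring a mixed-subject dataset; the train/eval
split is drawn once from the dataset seed.

**Recordings.** A normalized openness waveform f(t) is 1 except during
blinks: linear closing (100 ms) to a residual `trough_fraction` (0.02),
flat trough (50 ms), linear reopening (150 ms) — plausible blink
kinematics; the upstream work gives no generative model. The 30 Hz area
signal is `baseline_area × f + noise` (baseline 2500 px², matching the
rendered eye's scale); the 500 Hz pupil signal is `pupil_baseline × f`,
with samples marked missing while f < 0.1 (the pupil-visibility threshold),
which places every missing run strictly inside its eyelid excursion —
exactly the asymmetry between the two real devices. An optional initial
eyes-closed epoch (e.g. 15 s) supports alignment. Episodes may not overlap;
truth events carry exact start/minimum/end times.

**What the generator does not emulate.** Head movement and camera slip,
gaze-dependent eye-shape changes, eyelash/glare artifacts, tracker noise
bursts or dropouts outside blinks, partial blinks that the pupil tracker
still sees, and asymmetric upper/lower lid motion. Consequently, passing
the synthetic suite establishes the correctness and internal consistency of
the algorithms — codec fidelity, detector boundary accuracy to the
sampling-rate limit, metric arithmetic, cross-device logic — but not
field performance on human recordings, where detector thresholds
(`min_depth_fraction` above all) would need validation.

## Problem sizes and numerical choices

The shipped study conditions: 600 generated frames (500 train / 100 eval)
for the training run; blink recordings of 120 s with 20 blinks (detector
stress test, noise 2% of baseline), ten paired 260 s recordings with 50
blinks each (cross-device comparison), and twenty 45 s recordings with a
15 s initial closure (alignment). Detector and codec checks run against
independent brute-force oracles (exhaustive argmax, naive double-loop loss,
every-sample blink detection, 1 ms PERCLOS grid occupancy).

Degenerate inputs are defined rather than left to chance: a fully closed
eye renders all six landmarks collinear and the hexagon area 0; uniform
heatmaps decode to (0,0) by the tie rule; constant signals contain no
blinks; an empty reference event list makes the agreement fraction
undefined (reported as missing rather than 0 or 1).

## Known limitations

* The argmax decoder quantizes landmarks to the heatmap grid (±1 cell =
  2 px at the default resolutions); sub-pixel refinement is out of scope.
* The blink detectors assume a locally stable open-eye baseline; slow
  drifts wider than the rolling-median window would bias the depth rule.
* PERCLOS from the 20%-of-duration surrogate is definition-sensitive:
  the glass and pupil pipelines estimate slightly different durations,
  which bounds their PERCLOS correlation away from 1 even on clean data.
* Training hyperparameters are tuned for the synthetic dataset's
  difficulty; real annotated frames may need more epochs or width.
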