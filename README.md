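# blinkglass

Eyelid-keypoint regression and drowsiness metrics for wearable near-eye
cameras.

A camera mounted on the temple of a glasses frame (imaging the eye via a hot
mirror) sees the eye from a sharply skewed angle, at low resolution, under
infrared illumination. `blinkglass` implements the complete processing chain
that turns such frames into drowsiness measures, for researchers building or
validating wearable eye-closure monitors:

1. **Keypoint regression.** A lightweight hourglass CNN (the *LGN*) maps a
   128×128 grayscale frame to six Gaussian probability maps, one per eyelid
   landmark (two corners, two upper-lid and two lower-lid points). Each
   ground-truth map holds a 2-D Gaussian centred on the landmark, and
   training minimizes the mean-squared heatmap error

   L = (1/N) Σᵢ Σ₍h,w₎ ‖xᵢ(h,w) − xᵢ*(h,w)‖²,  N = 6,

   with SGD (lr 0.001, ×0.1 every 10 epochs). At inference each keypoint is
   the argmax of its map. The network (~34k parameters) trains and runs on a
   single CPU; all layers and backpropagation are implemented directly in
   numpy.
2. **Eye-area signal.** The six keypoints form a hexagon whose shoelace area
   is the open-eye area S(t), streamed at 30 Hz (an eye-aspect-ratio
   variant is also provided).
3. **Blink detection.** Two detectors: the glass detector up-samples S(t) to
   250 Hz, finds qualified local minima and scans outward for the *stable
   points* where the signal stops increasing (blink start/end); the
   reference detector takes a 500 Hz pupil-area signal whose samples go
   missing during full closure — the style of signal an EyeLink-class video
   eye tracker reports — and extends each missing run to the same kind of
   stable points, recovering the full eyelid excursion.
4. **Drowsiness metrics.** PERCLOS (percentage of eye closure, using 20% of
   each blink's duration as the closure period) and blink rate over a
   1-minute moving window advanced in 0.1 s steps; cross-device scoring via
   greedy one-to-one blink matching and Pearson correlation of the metric
   series; clock alignment from the extended eyes-closed epoch recorded at
   the start of a session.

Because datasets of this camera geometry are not publicly available, the
package ships a first-class synthetic generator: parametric near-eye frames
(parabolic eyelid arcs, iris disk, perspective shear, sensor noise) with
exact keypoint annotations, and paired 30 Hz area / 500 Hz pupil recordings
with ground-truth blink events.

## Worked example

```sh
# 1. synthesize a 200-frame annotated dataset and a 120 s recording pair
blinkglass synth --out work --n 200 --seed 7

# 2. train the keypoint network (30 epochs, single CPU)
blinkglass train --data work/dataset --out work/model.ckpt
# -> final train loss 3.6779; eval mean keypoint error 3.32 px, PCK 0.975

# 3. run the network over frames to get an eye-area CSV
blinkglass infer --checkpoint work/model.ckpt --frames work/dataset --out work/infer_area.csv

# 4. blink events + PERCLOS/blink-rate series + cross-device report
blinkglass metrics --area work/area.csv --pupil work/pupil.csv --out work/report
```

The `train` step prints the held-out keypoint accuracy: with the output
above, landmarks are recovered to 3.32 px on 128×128 frames and 97.5% of
them fall within 10% of the eye width of their true position (a 500-frame
training set brings the error down to about 1.5 px; see the acceptance
script). The
final `metrics` step prints the cross-device report:

```json
{
 "n_glass_blinks": 30,
 "n_pupil_blinks": 30,
 "recall_vs_pupil": 1.0,
 "blink_rate_pearson_r": 0.9996868187584117,
 "perclos_pearson_r": 0.98958575223836
}
```

Here every one of the 30 reference blinks was matched by a glass-detected
blink and the two devices' blink-rate series are nearly identical
(r = 0.9997). The PERCLOS correlation is slightly lower (r = 0.99) because
the two detectors estimate slightly different blink durations, to which
PERCLOS is sensitive by construction.

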