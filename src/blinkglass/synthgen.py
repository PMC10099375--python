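"""Synthetic near-eye data with ground truth.

The images and recordings a temple-mounted glass camera and a reference
eye tracker would produce are emulated here so every downstream stage can be
validated against exact ground truth:

* :func:`render_eye_frame` draws a parametric near-eye image — an eye
  opening bounded by two quadratic (parabolic) eyelid arcs between the
  corners, an iris disk, infrared-like intensity contrast, a shear that
  mimics the skewed temple-camera viewpoint, and sensor noise — and returns
  the six eyelid keypoints lying exactly on the rendered lid boundary
  (corners plus points at 1/3 and 2/3 arc length on each lid);
* :func:`generate_dataset` writes a reproducible annotated PNG dataset with
  a train/eval manifest;
* :func:`synth_blink_recording` produces a paired 30 Hz eye-area / 500 Hz
  pupil-area recording containing blinks with known start/minimum/end
  times.  Both signals follow the same normalized openness waveform
  (piecewise-linear close / trough / reopen); the pupil signal loses its
  samples while openness is below a visibility threshold, strictly inside
  the eyelid excursion — exactly the asymmetry between the two real
  devices.

All randomness flows from explicitly passed seeds; no global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .lgn import KeypointSet
from .ocular_signal import BlinkEvent, TimeSeries

__all__ = [
    "EyeShapeParams",
    "EyeFrame",
    "BlinkWaveformParams",
    "SyntheticRecording",
    "render_eye_frame",
    "generate_dataset",
    "load_manifest",
    "synth_blink_recording",
    "write_recording_csv",
    "read_recording_csv",
]


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EyeShapeParams:
    """Geometry and photometry of one synthetic near-eye frame.

    openness: eyelid aperture fraction, 0 (closed) to 1 (fully open).
    eye_width_px: corner-to-corner eye width in pixels.
    skew_deg: horizontal shear angle emulating the temple-camera viewpoint.
    noise_sd: additive intensity noise SD (on a 0..1 scale).
    skin / sclera / iris: intensity levels (0..1); under infrared the sclera
        is bright and the iris dark.
    image_size: (rows, cols) of the rendered frame.
    """

    openness: float = 1.0
    eye_width_px: float = 80.0
    skew_deg: float = 15.0
    noise_sd: float = 0.02
    skin: float = 0.55
    sclera: float = 0.85
    iris: float = 0.15
    image_size: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if not 0.0 <= self.openness <= 1.0:
            raise ValueError("openness must be in [0, 1]")
        if self.eye_width_px <= 0:
            raise ValueError("eye_width_px must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image dimensions must be positive")


@dataclass
class EyeFrame:
    """One grayscale near-eye image with a timestamp."""

    image: np.ndarray  # (H, W) uint8
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("frame must be a 2-D grayscale image")


# aperture half-height as a fraction of eye width at full openness
_APERTURE_RATIO = 0.3
# iris radius as a fraction of the eye half-width
_IRIS_RATIO = 0.62


def _arc_length_fractions(a: float, p: float, fracs: np.ndarray) -> np.ndarray:
    """x-positions (relative to centre) at given arc-length fractions of the
    parabola y = p*(1 - (x/a)^2) for x in [-a, a], computed numerically."""
    x = np.linspace(-a, a, 2001)
    y = p * (1.0 - (x / a) ** 2)
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return np.interp(fracs * s[-1], s, x)


def render_eye_frame(params: EyeShapeParams, seed: int) -> tuple[EyeFrame, KeypointSet]:
    """Render one frame and its six ground-truth eyelid keypoints.

    The eyelid boundary consists of two parabolic arcs meeting at the
    corners, opening symmetrically about the horizontal eye axis.  Keypoints
    are the two corners plus the upper- and lower-lid points at 1/3 and 2/3
    arc length; the same shear that distorts the image is applied to them,
    so they remain exactly on the rendered boundary.  Deterministic for a
    fixed (params, seed) pair.
    """
    H, W = params.image_size
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    a = params.eye_width_px / 2.0
    p = params.openness * _APERTURE_RATIO * params.eye_width_px / 2.0
    shear = float(np.tan(np.radians(params.skew_deg)))

    # keypoints in unsheared eye coordinates (row, col)
    xk = _arc_length_fractions(a, p, np.array([1 / 3, 2 / 3]))
    yk = p * (1.0 - (xk / a) ** 2)
    pts = np.array(
        [
            [cy, cx - a],  # temporal corner
            [cy, cx + a],  # nasal corner
            [cy - yk[0], cx + xk[0]],  # upper lid 1/3
            [cy - yk[1], cx + xk[1]],  # upper lid 2/3
            [cy + yk[0], cx + xk[0]],  # lower lid 1/3
            [cy + yk[1], cx + xk[1]],  # lower lid 2/3
        ]
    )
    # shear columns by vertical distance from the eye axis
    pts[:, 1] += shear * (pts[:, 0] - cy)
    if (
        (pts[:, 0] < 0).any()
        or (pts[:, 0] > H - 1).any()
        or (pts[:, 1] < 0).any()
        or (pts[:, 1] > W - 1).any()
    ):
        raise ValueError("eye geometry does not fit inside the image")

    rows = np.arange(H, dtype=np.float64)[:, None]
    cols = np.arange(W, dtype=np.float64)[None, :]
    # invert the shear to evaluate the aperture in eye coordinates
    c_eye = cols - shear * (rows - cy)
    x = c_eye - cx
    y = rows - cy
    with np.errstate(invalid="ignore"):
        lid = p * (1.0 - (x / a) ** 2)
    inside = (np.abs(x) <= a) & (np.abs(y) <= lid)

    img = np.full((H, W), params.skin, dtype=np.float64)
    img[inside] = params.sclera
    iris_r = _IRIS_RATIO * a
    iris = inside & (x**2 + y**2 <= iris_r**2)
    img[iris] = params.iris
    img = gaussian_filter(img, sigma=1.0)

    rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    frame = EyeFrame(np.round(img * 255.0).astype(np.uint8))
    return frame, KeypointSet(pts)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

# per-"sex" shape priors: (width range, skin level range).  Purely cosmetic
# population structure mirroring a mixed-subject dataset.
_SEX_PRIORS = {
    "male": ((72.0, 92.0), (0.45, 0.60)),
    "female": ((62.0, 82.0), (0.50, 0.65)),
}


def _sample_params(rng: np.random.Generator, sex: str, image_size: tuple[int, int]) -> EyeShapeParams:
    (wlo, whi), (slo, shi) = _SEX_PRIORS[sex]
    return EyeShapeParams(
        openness=float(rng.uniform(0.0, 1.0)),
        eye_width_px=float(rng.uniform(wlo, whi)),
        skew_deg=float(rng.uniform(-25.0, 25.0)),
        noise_sd=float(rng.uniform(0.01, 0.04)),
        skin=float(rng.uniform(slo, shi)),
        sclera=float(rng.uniform(0.78, 0.92)),
        iris=float(rng.uniform(0.08, 0.22)),
        image_size=image_size,
    )


def generate_dataset(
    n: int,
    male_female_split: tuple[float, float] = (0.5, 0.5),
    out_dir: str | Path = ".",
    seed: int = 0,
    *,
    eval_fraction: float = 0.2,
    image_size: tuple[int, int] = (128, 128),
) -> dict:
    """Write ``n`` annotated frames plus a train/eval manifest; return the manifest.

    Each frame gets a PNG and a JSON annotation ``{"frame": ..., "keypoints":
    [[r, c] x 6]}``.  The eval split holds ``round(eval_fraction * n)``
    frames, disjoint from train, both reproducible from ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if abs(sum(male_female_split) - 1.0) > 1e-9:
        raise ValueError("male_female_split fractions must sum to 1")
    n_eval = int(round(eval_fraction * n))
    if n_eval >= n:
        raise ValueError(f"eval split ({n_eval}) must be smaller than n ({n})")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    n_male = int(round(male_female_split[0] * n))
    sexes = ["male"] * n_male + ["female"] * (n - n_male)
    rng.shuffle(sexes)
    eval_idx = set(rng.choice(n, size=n_eval, replace=False).tolist())

    entries = []
    for i in range(n):
        params = _sample_params(rng, sexes[i], image_size)
        frame_seed = int(rng.integers(0, 2**31 - 1))
        frame, kps = render_eye_frame(params, seed=frame_seed)
        name = f"frame_{i:05d}"
        Image.fromarray(frame.image).save(out / f"{name}.png")
        ann = {"frame": f"{name}.png", "keypoints": kps.points.tolist()}
        (out / f"{name}.json").write_text(json.dumps(ann))
        entries.append(
            {
                "frame": f"{name}.png",
                "annotation": f"{name}.json",
                "split": "eval" if i in eval_idx else "train",
                "sex": sexes[i],
                "openness": params.openness,
                "eye_width_px": params.eye_width_px,
            }
        )

    manifest = {
        "seed": seed,
        "n": n,
        "image_size": list(image_size),
        "entries": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_manifest(path: str | Path) -> dict:
    """Read a dataset manifest written by :func:`generate_dataset`."""
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    return json.loads(path.read_text())


# ---------------------------------------------------------------------------
# Blink recordings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlinkWaveformParams:
    """Generative settings for one paired eye-area / pupil-area recording.

    A blink at time ``t0`` closes the eye linearly over ``closing_ms`` down
    to ``trough_fraction`` of baseline, holds for ``trough_ms`` and reopens
    over ``opening_ms``.  The pupil is invisible (samples missing) while the
    normalized openness is below ``missing_threshold``; requires
    ``trough_fraction < missing_threshold`` so every blink hides the pupil.
    ``initial_closure_s > 0`` prepends an extended eyes-closed epoch used for
    cross-device alignment.
    """

    baseline_area: float = 2500.0
    blink_times: tuple[float, ...] = ()
    closing_ms: float = 100.0
    trough_ms: float = 50.0
    opening_ms: float = 150.0
    trough_fraction: float = 0.02
    noise_sd: float = 0.0
    rate_hz: float = 30.0
    duration_s: float = 60.0
    seed: int = 0
    pupil_rate_hz: float = 500.0
    pupil_baseline: float = 1000.0
    missing_threshold: float = 0.1
    initial_closure_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("closing_ms", "trough_ms", "opening_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.trough_fraction < 1.0:
            raise ValueError("trough_fraction must be in [0, 1)")
        if self.trough_fraction >= self.missing_threshold:
            raise ValueError("trough_fraction must be below missing_threshold")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.duration_s <= 0 or self.rate_hz <= 0 or self.pupil_rate_hz <= 0:
            raise ValueError("duration and rates must be positive")
        object.__setattr__(self, "blink_times", tuple(float(t) for t in self.blink_times))

    @property
    def blink_duration_s(self) -> float:
        return (self.closing_ms + self.trough_ms + self.opening_ms) / 1000.0

    def episodes(self) -> list[tuple[float, float]]:
        """(start, end) of every eyelid excursion, including the initial closure."""
        eps = []
        if self.initial_closure_s > 0:
            eps.append((0.0, self.initial_closure_s + self.opening_ms / 1000.0))
        for t0 in sorted(self.blink_times):
            eps.append((t0, t0 + self.blink_duration_s))
        return eps


@dataclass
class SyntheticRecording:
    """Paired glass / reference recording with ground-truth blink events."""

    area_series: TimeSeries
    pupil_series: TimeSeries
    truth_events: list[BlinkEvent]
    params: BlinkWaveformParams | None = None

    def shifted(self, offset_s: float) -> "SyntheticRecording":
        """A copy with all timestamps moved by ``offset_s``."""

        def shift(s: TimeSeries) -> TimeSeries:
            return TimeSeries(s.times + offset_s, s.values.copy(), s.valid.copy(), s.nominal_rate)

        return SyntheticRecording(
            shift(self.area_series),
            shift(self.pupil_series),
            [
                BlinkEvent(e.start_s + offset_s, e.min_s + offset_s, e.end_s + offset_s, e.source)
                for e in self.truth_events
            ],
            self.params,
        )


def _openness_waveform(params: BlinkWaveformParams, t: np.ndarray) -> np.ndarray:
    """Normalized openness f(t) in [trough_fraction, 1]."""
    f = np.ones_like(t)
    tf = params.trough_fraction
    cl = params.closing_ms / 1000.0
    tr = params.trough_ms / 1000.0
    op = params.opening_ms / 1000.0
    if params.initial_closure_s > 0:
        end = params.initial_closure_s
        closed = t <= end
        f[closed] = tf
        reopening = (t > end) & (t < end + op)
        f[reopening] = tf + (1.0 - tf) * (t[reopening] - end) / op
    for t0 in params.blink_times:
        seg = (t >= t0) & (t < t0 + cl)
        f[seg] = 1.0 - (1.0 - tf) * (t[seg] - t0) / cl
        seg = (t >= t0 + cl) & (t < t0 + cl + tr)
        f[seg] = tf
        seg = (t >= t0 + cl + tr) & (t < t0 + cl + tr + op)
        f[seg] = tf + (1.0 - tf) * (t[seg] - (t0 + cl + tr)) / op
    return f


def synth_blink_recording(params: BlinkWaveformParams) -> SyntheticRecording:
    """Generate a paired 30 Hz eye-area / 500 Hz pupil-area recording.

    Raises if blink episodes overlap each other (or the initial closure) or
    extend past the recording.
    """
    eps = params.episodes()
    for (s0, e0), (s1, e1) in zip(eps, eps[1:]):
        if s1 < e0:
            raise ValueError(f"blink episodes overlap: ({s0}, {e0}) and ({s1}, {e1})")
    if eps and (eps[0][0] < 0 or eps[-1][1] > params.duration_s):
        raise ValueError("blink episodes must lie within [0, duration_s]")

    rng = np.random.default_rng(params.seed)

    t_area = np.arange(int(np.floor(params.duration_s * params.rate_hz)) + 1) / params.rate_hz
    f_area = _openness_waveform(params, t_area)
    area = params.baseline_area * f_area
    if params.noise_sd > 0:
        area = np.clip(area + rng.normal(0.0, params.noise_sd, size=area.shape), 0.0, None)
    area_series = TimeSeries(t_area, area, nominal_rate=params.rate_hz)

    t_pup = np.arange(int(np.floor(params.duration_s * params.pupil_rate_hz)) + 1) / params.pupil_rate_hz
    f_pup = _openness_waveform(params, t_pup)
    valid = f_pup >= params.missing_threshold
    pupil = params.pupil_baseline * f_pup
    if params.noise_sd > 0:
        pupil_noise_sd = params.noise_sd * params.pupil_baseline / params.baseline_area
        pupil = pupil + rng.normal(0.0, pupil_noise_sd, size=pupil.shape)
    pupil = np.clip(pupil, 0.0, None)
    pupil[~valid] = 0.0
    pupil_series = TimeSeries(t_pup, pupil, valid, nominal_rate=params.pupil_rate_hz)

    cl = params.closing_ms / 1000.0
    tr = params.trough_ms / 1000.0
    truth = [
        BlinkEvent(
            t0,
            t0 + cl + tr / 2.0,
            t0 + params.blink_duration_s,
            source="truth",
        )
        for t0 in sorted(params.blink_times)
    ]
    return SyntheticRecording(area_series, pupil_series, truth, params)


# ---------------------------------------------------------------------------
# Recording I/O (CSV: time_s, value, valid)
# ---------------------------------------------------------------------------


def write_recording_csv(path: str | Path, s: TimeSeries) -> None:
    with open(path, "w") as fh:
        fh.write("time_s,value,valid\n")
        for t, v, ok in zip(s.times, s.values, s.valid):
            fh.write(f"{t:.6f},{v:.6f},{int(ok)}\n")


def read_recording_csv(path: str | Path, nominal_rate: float = 0.0) -> TimeSeries:
    times, values, valid = [], [], []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:3] != ["time_s", "value", "valid"]:
            raise ValueError(f"{path}: expected header time_s,value,valid")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
                valid.append(bool(int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
    return TimeSeries(np.array(times), np.array(values), np.array(valid), nominal_rate)
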