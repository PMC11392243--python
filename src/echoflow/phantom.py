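"""Synthetic beating-heart phantoms.

Generates A2C/A4C-like grayscale echo loops with a known, controllable
regional wall motion so that every downstream stage (segmentation, contour
kinematics, optical flow, temporal ConvNet, classification) can be exercised
and validated without any recorded data.

The phantom is a U-shaped (open-top) bright annulus — a stylised left
ventricular wall seen from an apical window — on a dark background:

* the annulus opens upward with a fixed 60 deg aperture (the mitral plane),
  leaving two distinct arms as a real apical LV contour has;
* the inner (endocardial) radius contracts radially and sinusoidally with
  period ``frames_per_cycle``; the contraction amplitude is set per angular
  sector, smoothly interpolated across sector boundaries so the motion field
  has no discontinuities;
* hypokinesia is simulated by scaling the amplitude of chosen sectors by a
  factor in [0, 1];
* a mild material-anchored texture moves with the wall (so motion is
  recoverable from brightness), and multiplicative Rayleigh speckle is
  applied last.  The speckle pattern is itself anchored to material
  coordinates (angle, depth-into-wall): ultrasound speckle is interference
  from sub-resolution scatterers fixed in the tissue, so the pattern moves
  with the wall rather than being redrawn each frame; a small additive
  sensor-noise term decorrelates frames slightly.

Sectors are ordered along the contour the same way the kinematics module
partitions it: indices 0-3 run base-to-apex down the left arm with angular
widths proportional to (2/7, 2/7, 2/7, 1/7) of the arm, and indices 4-7
mirror that on the right arm.  ``GroundTruth`` records the per-sector true
peak displacement and the per-frame wall mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

__all__ = [
    "PhantomConfig",
    "EchoSequence",
    "GroundTruth",
    "Subject",
    "PhantomConfigError",
    "N_SEGMENTS",
    "SEGMENT_FRACTIONS",
    "generate_sequence",
    "generate_cohort",
]

N_SEGMENTS = 8
#: base-to-apex arc-length fractions of one arm (three mid segments + apex cap)
SEGMENT_FRACTIONS = (2 / 7, 2 / 7, 2 / 7, 1 / 7)
_OPENING_HALF_DEG = 30.0  # half of the 60 deg basal aperture


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration field is invalid."""


@dataclass
class PhantomConfig:
    """Geometry, motion, and noise parameters of one phantom loop.

    ``hypokinetic_segments`` may be a set of sector indices (all scaled by
    ``hypokinesia_factor``) or a mapping ``{index: factor}`` with a factor per
    sector.
    """

    image_size: int = 224
    frames_per_cycle: int = 25
    n_cycles: int = 3
    wall_thickness: float | None = None   # pixels; default scales with image
    base_amplitude: float | None = None   # pixels of peak radial contraction
    rest_radius: float | None = None      # inner radius at rest; default scales
    hypokinetic_segments: frozenset | set | dict = field(default_factory=set)
    hypokinesia_factor: float = 0.3
    speckle_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.wall_thickness is None:
            self.wall_thickness = 0.08 * self.image_size
        if self.base_amplitude is None:
            self.base_amplitude = 0.045 * self.image_size
        if self.rest_radius is None:
            self.rest_radius = 0.30 * self.image_size

    def validate(self) -> None:
        if self.image_size < 16:
            raise PhantomConfigError("image_size must be >= 16")
        if self.frames_per_cycle < 2:
            raise PhantomConfigError("frames_per_cycle must be >= 2")
        if self.n_cycles < 1:
            raise PhantomConfigError("n_cycles must be >= 1")
        if not 0.0 <= self.hypokinesia_factor <= 1.0:
            raise PhantomConfigError("hypokinesia_factor must lie in [0, 1]")
        if self.base_amplitude >= self.image_size / 4:
            raise PhantomConfigError("base_amplitude must be < image_size/4")
        if self.speckle_sigma < 0:
            raise PhantomConfigError("speckle_sigma must be >= 0")
        if isinstance(self.hypokinetic_segments, dict):
            items = self.hypokinetic_segments.items()
            if any(not 0 <= s < N_SEGMENTS for s, _ in items):
                raise PhantomConfigError("hypokinetic_segments indices must be in [0, 8)")
            if any(not 0.0 <= f <= 1.0 for _, f in items):
                raise PhantomConfigError("hypokinetic_segments factors must lie in [0, 1]")
        elif any(not 0 <= s < N_SEGMENTS for s in self.hypokinetic_segments):
            raise PhantomConfigError("hypokinetic_segments indices must be in [0, 8)")

    def segment_factors(self) -> np.ndarray:
        """Per-sector amplitude scale (1 = normokinetic)."""
        f = np.ones(N_SEGMENTS)
        if isinstance(self.hypokinetic_segments, dict):
            for s, fac in self.hypokinetic_segments.items():
                f[s] = fac
        else:
            for s in self.hypokinetic_segments:
                f[s] = self.hypokinesia_factor
        return f


@dataclass
class EchoSequence:
    """Ordered grayscale frames of one view for one subject."""

    frames: np.ndarray          # (T, H, W) float32 in [0, 1]
    view: str                   # "A2C" or "A4C"
    subject_id: str
    label: str                  # "RWMA" or "non-RWMA"

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class GroundTruth:
    wall_masks: np.ndarray            # (T, H, W) bool
    segment_amplitudes: np.ndarray    # (8,) true peak displacement, pixels
    segment_labels: np.ndarray        # (8,) bool, True = hypokinetic
    center: tuple[float, float]       # (row, col) annulus center
    rest_radius: float
    wall_thickness: float


@dataclass
class Subject:
    subject_id: str
    label: str
    views: dict  # view tag -> (EchoSequence, GroundTruth)


def _contour_angles(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Image-plane angle alpha of every pixel, plus radius, about a center.

    alpha = atan2(dx, -dy): 0 points up (toward the aperture), +/-180 deg is
    the apex at the bottom; the left arm has alpha in [-180, -30] deg and the
    right arm alpha in [30, 180] deg.
    """
    cy, cx = 0.55 * size, 0.50 * size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    return np.degrees(np.arctan2(dx, -dy)), np.hypot(dy, dx)


def segment_of_angle(alpha_deg: np.ndarray) -> np.ndarray:
    """Map contour angle (deg) to sector index 0-7; aperture pixels get -1."""
    a = np.asarray(alpha_deg, dtype=float)
    out = np.full(a.shape, -1, dtype=int)
    arm = 180.0 - _OPENING_HALF_DEG  # angular span of one arm
    edges = np.concatenate([[0.0], np.cumsum(SEGMENT_FRACTIONS)]) * arm
    mag = np.abs(a) - _OPENING_HALF_DEG  # distance from base along the arm
    on_wall = mag >= 0
    idx = np.clip(np.searchsorted(edges, mag, side="right") - 1, 0, 3)
    left = a < 0
    out[on_wall & left] = idx[on_wall & left]
    out[on_wall & ~left] = 4 + idx[on_wall & ~left]
    return out


def _amplitude_profile(config: PhantomConfig, smooth_deg: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude A(alpha) on a fine angular grid, smoothed across sectors."""
    grid = np.arange(-180.0, 180.0, 0.25)
    seg = segment_of_angle(grid)
    factors = config.segment_factors()
    amp = np.where(seg >= 0, config.base_amplitude * factors[np.clip(seg, 0, None)], np.nan)
    # fill the aperture with the adjacent basal values so wrap-smoothing
    # does not bleed an arbitrary value into the base segments
    nanmask = np.isnan(amp)
    amp[nanmask] = np.interp(np.flatnonzero(nanmask), np.flatnonzero(~nanmask), amp[~nanmask])
    amp = gaussian_filter1d(amp, sigma=smooth_deg / 0.25, mode="wrap")
    return grid, amp


def _geometry(config: PhantomConfig, t: int, amp_grid: tuple[np.ndarray, np.ndarray],
              alpha: np.ndarray, radius: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smooth wall-occupancy weight in [0,1] and the inner radius map at frame t."""
    grid, amp = amp_grid
    phase = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / config.frames_per_cycle))
    a_of_pix = np.interp(alpha, grid, amp, period=360.0)
    r_in = config.rest_radius - a_of_pix * phase
    r_out = r_in + config.wall_thickness
    edge = 1.0  # px softness of wall edges
    w = (1.0 / (1.0 + np.exp(-(radius - r_in) / edge))
         * 1.0 / (1.0 + np.exp((radius - r_out) / edge)))
    # carve the basal aperture, with an edge softened in pixel units
    ap = (np.abs(alpha) - _OPENING_HALF_DEG) * np.maximum(radius, 1.0) * np.pi / 180.0
    w *= 1.0 / (1.0 + np.exp(-ap / edge))
    return w, r_in


def generate_sequence(config: PhantomConfig, view: str = "A4C",
                      subject_id: str = "phantom-0", label: str | None = None
                      ) -> tuple[EchoSequence, GroundTruth]:
    """Render one phantom loop and its ground truth.

    Deterministic for a fixed ``config.seed``.  The wall is brighter than the
    background before noise; the inner radius oscillates sinusoidally with
    period ``frames_per_cycle``; sectors listed in ``hypokinetic_segments``
    contract with their amplitude scaled down.
    """
    config.validate()
    if view not in ("A2C", "A4C"):
        raise PhantomConfigError(f"view must be 'A2C' or 'A4C', got {view!r}")
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    n_frames = config.frames_per_cycle * config.n_cycles
    alpha, radius = _contour_angles(size)
    amp_grid = _amplitude_profile(config)

    # material-anchored texture: phases are per-sequence random constants
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    n_ang = 9 if view == "A4C" else 7  # views differ in texture granularity
    wall_level, bg_level = 0.85, 0.08

    # scatterer field on a material (angle, depth-into-wall) grid, smoothed a
    # touch so it interpolates as speckle blobs rather than per-pixel salt
    n_depth = int(np.ceil(config.wall_thickness)) + 9
    scatter = rng.rayleigh(scale=1.0, size=(720, n_depth)) / np.sqrt(np.pi / 2)
    scatter = gaussian_filter1d(gaussian_filter1d(scatter, 1.0, axis=0, mode="wrap"),
                                0.8, axis=1, mode="nearest")
    sensor_sigma = 0.01  # small frame-decorrelated additive noise

    frames = np.empty((n_frames, size, size), dtype=np.float32)
    masks = np.empty((n_frames, size, size), dtype=bool)
    for t in range(n_frames):
        w, r_in = _geometry(config, t, amp_grid, alpha, radius)
        depth = radius - r_in  # material radial coordinate, moves with wall
        tex = 1.0 + 0.20 * np.sin(n_ang * np.radians(alpha) + ph1) \
                  * np.sin(2 * np.pi * depth / 6.0 + ph2)
        img = bg_level + (wall_level * tex - bg_level) * w
        masks[t] = w > 0.5
        if config.speckle_sigma > 0:
            a_idx = (alpha + 180.0) * (720 / 360.0)
            d_idx = np.clip(depth + 4.0, 0.0, n_depth - 1.0)
            ray = map_coordinates(scatter, [a_idx, d_idx], order=1,
                                  mode="grid-wrap")
            img = img * ((1 - config.speckle_sigma) + config.speckle_sigma * ray)
        img = img + rng.normal(0.0, sensor_sigma, size=(size, size))
        frames[t] = np.clip(img, 0.0, 1.0)

    factors = config.segment_factors()
    amplitudes = config.base_amplitude * factors
    if label is None:
        label = "RWMA" if np.any(factors < 1.0) else "non-RWMA"
    seq = EchoSequence(frames=frames, view=view, subject_id=subject_id, label=label)
    gt = GroundTruth(
        wall_masks=masks,
        segment_amplitudes=amplitudes,
        segment_labels=factors < 1.0,
        center=(0.55 * size, 0.50 * size),
        rest_radius=config.rest_radius,
        wall_thickness=config.wall_thickness,
    )
    return seq, gt


def wall_weight(config: PhantomConfig, t: int) -> np.ndarray:
    """The generator's own geometry at frame t (for mask-consistency checks)."""
    alpha, radius = _contour_angles(config.image_size)
    w, _ = _geometry(config, t, _amplitude_profile(config), alpha, radius)
    return w


def generate_cohort(n_rwma: int, n_normal: int, template: PhantomConfig | None = None,
                    seed: int = 0) -> list[Subject]:
    """Generate paired (A2C, A4C) loops for a labelled cohort.

    Every RWMA subject gets a hypokinetic territory of 2-4 *contiguous*
    sectors along the wall (infarcts follow coronary territories, which are
    spatially contiguous), applied in both views so at least one view shows
    the abnormality; normal subjects get none.  Per-subject geometry is
    jittered reproducibly from ``seed``.
    """
    if n_rwma < 0 or n_normal < 0:
        raise PhantomConfigError("cohort sizes must be >= 0")
    template = template or PhantomConfig()
    template.validate()
    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    labels = ["RWMA"] * n_rwma + ["non-RWMA"] * n_normal
    # sector indices in contiguous order along the contour (left base ->
    # apex -> right base); a territory is a run in this path
    path = [0, 1, 2, 3, 7, 6, 5, 4]
    for i, label in enumerate(labels):
        if label == "RWMA":
            k = int(rng.integers(2, 5))
            start = int(rng.integers(0, N_SEGMENTS - k + 1))
            segs = set(path[start:start + k])
        else:
            segs = set()
        views = {}
        for view in ("A2C", "A4C"):
            cfg = PhantomConfig(
                image_size=template.image_size,
                frames_per_cycle=template.frames_per_cycle,
                n_cycles=template.n_cycles,
                wall_thickness=template.wall_thickness * rng.uniform(0.9, 1.1),
                base_amplitude=template.base_amplitude * rng.uniform(0.85, 1.15),
                rest_radius=template.rest_radius * rng.uniform(0.92, 1.08),
                hypokinetic_segments=segs,
                hypokinesia_factor=template.hypokinesia_factor,
                speckle_sigma=template.speckle_sigma,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sid = f"subj-{i:03d}"
            views[view] = generate_sequence(cfg, view=view, subject_id=sid, label=label)
        subjects.append(Subject(subject_id=f"subj-{i:03d}", label=label, views=views))
    return subjects
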