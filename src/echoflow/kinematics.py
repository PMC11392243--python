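"""LV contour extraction, myocardial segment partition, displacement curves.

The wall mask's endocardial (inner) edge is traced as an ordered open curve
from the left end of the basal aperture, around the apex, to the right end.
The curve is split at its arc-length midpoint (the apex) into a left arm of
length L and a right arm of length R, and each arm is tiled base-to-apex by
three segments of length 2/7 of the arm plus an apical cap of 1/7 — eight
spans in total, matching the sector order of the phantom generator
(0-3 left base->apex, 4-7 right base->apex).

Per-segment displacement at frame t is the mean Euclidean distance between
arc-length-matched boundary points of frame t and frame 0 (positions are
matched by normalised arc length, which is deterministic and requires no
feature tracking).  The per-segment maximum over frames is the motion
amplitude summary a clinician would read off a displacement-curve panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates
from skimage.measure import label as cc_label

__all__ = [
    "LVContour",
    "SegmentPartition",
    "DisplacementCurves",
    "ContourError",
    "SEGMENT_IDS",
    "extract_contour",
    "contours_from_masks",
    "partition_segments",
    "displacement_curves",
    "plot_displacement_curves",
]

SEGMENT_IDS = ("L-basal", "L-mid", "L-apical", "L-apex-cap",
               "R-basal", "R-mid", "R-apical", "R-apex-cap")
_ARM_FRACTIONS = (2 / 7, 2 / 7, 2 / 7, 1 / 7)


class ContourError(ValueError):
    """Raised when a mask yields no usable single-component contour."""


@dataclass
class LVContour:
    points: np.ndarray      # (N, 2) ordered (row, col), left base -> apex -> right base
    arclen: np.ndarray      # (N,) cumulative arc length from the left end
    angles: np.ndarray      # (N,) unwrapped polar angle about the centroid, rad
    center: np.ndarray      # (2,) centroid (row, col) the angles refer to
    apex_index: int         # index splitting left/right arms (arc-length midpoint)

    @property
    def total_length(self) -> float:
        return float(self.arclen[-1])

    @property
    def left_arm_length(self) -> float:
        return float(self.arclen[self.apex_index])

    @property
    def right_arm_length(self) -> float:
        return self.total_length - self.left_arm_length


@dataclass
class SegmentPartition:
    """Arc-length spans per segment.

    ``spans`` holds, per segment id, ``(side, start, end)`` where start/end
    are side-local arc lengths measured from that side's basal end toward the
    apex, so left spans tile [0, L] and right spans tile [0, R].
    """

    spans: dict
    left_length: float
    right_length: float
    segment_ids: tuple = SEGMENT_IDS


@dataclass
class DisplacementCurves:
    values: np.ndarray      # (8, T) pixels, relative to frame 0
    maxima: np.ndarray      # (8,) per-segment peak displacement
    segment_ids: tuple = SEGMENT_IDS


def extract_contour(mask: np.ndarray, frame_index: int | None = None,
                    n_angles: int = 720, smooth_sigma: float = 2.0) -> LVContour:
    """Trace the inner (endocardial) edge of a U-shaped wall mask.

    The mask is unwrapped in polar coordinates about its centroid: for each
    ray the innermost wall radius is recorded; the largest angular gap is
    taken as the basal aperture, and the remaining arc is ordered from its
    left end through the apex to its right end.  Requires a non-empty,
    single-connected-component mask.
    """
    where = "" if frame_index is None else f" (frame {frame_index})"
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ContourError(f"empty mask{where}")
    _, n_comp = cc_label(mask, return_num=True)
    if n_comp != 1:
        raise ContourError(f"mask has {n_comp} connected components, expected 1{where}")

    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    max_r = float(np.hypot(rows - cy, cols - cx).max()) + 2.0
    thetas = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    radii = np.arange(1.0, max_r, 0.4)
    # sample the mask along every ray (rows x angles grid)
    rr = cy + radii[:, None] * (-np.cos(thetas))[None, :]
    cc = cx + radii[:, None] * (np.sin(thetas))[None, :]
    samp = map_coordinates(mask.astype(np.float32), [rr, cc], order=1,
                           mode="constant") > 0.5
    hit = samp.any(axis=0)
    inner = np.where(hit, radii[np.argmax(samp, axis=0)], np.nan)
    if hit.all():
        raise ContourError(f"mask has no basal aperture; closed annulus{where}")

    # largest circular gap of missing rays = the aperture
    miss = ~hit
    idx = np.flatnonzero(miss)
    gaps = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    if miss[0] and miss[-1] and len(gaps) > 1:  # merge wrap-around gap
        gaps[0] = np.concatenate([gaps[-1], gaps[0]])
        gaps.pop()
    gap = max(gaps, key=len)
    # walk the wall arc starting just after the gap, wrapping around
    start = (gap[-1] + 1) % n_angles
    order = (start + np.arange(n_angles)) % n_angles
    order = order[hit[order]]
    r = inner[order]
    # light circular-free smoothing along the open arc to tame mask jaggies
    if smooth_sigma > 0:
        r = gaussian_filter1d(r, smooth_sigma, mode="nearest")
    th = np.unwrap(thetas[order])
    pts = np.stack([cy - r * np.cos(th), cx + r * np.sin(th)], axis=1)
    if pts[0, 1] > pts[-1, 1]:  # ensure the walk starts at the left arm
        pts, th = pts[::-1], th[::-1]
    seglen = np.hypot(*(np.diff(pts, axis=0).T))
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    apex_index = int(np.searchsorted(arclen, arclen[-1] / 2.0))
    return LVContour(points=pts, arclen=arclen, angles=th,
                     center=np.array([cy, cx]), apex_index=apex_index)


def contours_from_masks(masks) -> list[LVContour]:
    """Extract one contour per frame, reporting the failing frame on error."""
    return [extract_contour(m, frame_index=i) for i, m in enumerate(masks)]


def partition_segments(contour: LVContour) -> SegmentPartition:
    """Tile each arm base->apex with spans of length (2/7, 2/7, 2/7, 1/7)·arm."""
    L, R = contour.left_arm_length, contour.right_arm_length
    if L <= 0 or R <= 0:
        raise ContourError(f"degenerate contour arms: L={L}, R={R}")
    spans = {}
    for side, length, ids in (("L", L, SEGMENT_IDS[:4]), ("R", R, SEGMENT_IDS[4:])):
        edges = np.concatenate([[0.0], np.cumsum(_ARM_FRACTIONS)]) * length
        for sid, s0, s1 in zip(ids, edges[:-1], edges[1:]):
            spans[sid] = (side, float(s0), float(s1))
    return SegmentPartition(spans=spans, left_length=L, right_length=R)


def _points_at(contour: LVContour, s: np.ndarray) -> np.ndarray:
    """Interpolate contour points at given arc lengths."""
    rows = np.interp(s, contour.arclen, contour.points[:, 0])
    cols = np.interp(s, contour.arclen, contour.points[:, 1])
    return np.stack([rows, cols], axis=1)


def _points_at_angle(contour: LVContour, a: np.ndarray) -> np.ndarray:
    """Interpolate contour points at given polar angles about the centroid."""
    th, pts = contour.angles, contour.points
    if th[0] > th[-1]:  # np.interp needs ascending abscissae
        th, pts = th[::-1], pts[::-1]
    # map each query into the contour's angular branch (span < 2*pi)
    a = th[0] + np.mod(a - th[0], 2.0 * np.pi)
    a = np.clip(a, th[0], th[-1])
    rows = np.interp(a, th, pts[:, 0])
    cols = np.interp(a, th, pts[:, 1])
    return np.stack([rows, cols], axis=1)


def displacement_curves(contours: list[LVContour], partition: SegmentPartition,
                        samples_per_segment: int = 24) -> DisplacementCurves:
    """Per-segment mean boundary displacement of every frame vs frame 0.

    Sample positions are laid out by arc length on the frame-0 contour (so
    segment spans are arc-length spans, as partitioned) and matched into
    every later frame by polar angle about the contour centroid.  For the
    predominantly radial motion of an LV wall this correspondence is exact
    and strictly local — unlike normalised-arc-length matching, it does not
    alias a strongly contracting region's length change into tangential
    pseudo-motion of its neighbours.  The curve is zero at frame 0 by
    construction and requires no feature tracking.
    """
    if len(contours) < 2:
        raise ValueError("need at least 2 frames of contours")
    ref = contours[0]
    len0 = ref.total_length
    qs, seg_of_sample = [], []
    for k, sid in enumerate(SEGMENT_IDS):
        side, s0, s1 = partition.spans[sid]
        local = np.linspace(s0, s1, samples_per_segment + 2)[1:-1]
        s_global = local if side == "L" else len0 - local
        qs.append(s_global / len0)
        seg_of_sample.append(np.full(local.shape, k))
    q = np.concatenate(qs)
    seg_of_sample = np.concatenate(seg_of_sample)

    anchors = _points_at(ref, q * len0)
    d0 = anchors - ref.center
    a0 = np.unwrap(np.arctan2(d0[:, 1], -d0[:, 0]))
    # evaluate frame 0 through the same angular lookup as every other frame,
    # so identical contours give exactly zero displacement
    p0 = _points_at_angle(ref, a0)
    values = np.zeros((len(SEGMENT_IDS), len(contours)))
    for t, ct in enumerate(contours[1:], start=1):
        pt = _points_at_angle(ct, a0)
        d = np.hypot(*(pt - p0).T)
        for k in range(len(SEGMENT_IDS)):
            values[k, t] = d[seg_of_sample == k].mean()
    return DisplacementCurves(values=values, maxima=values.max(axis=1))


def plot_displacement_curves(curves: DisplacementCurves, ax=None, title: str = ""):
    """Displacement-curve panel (one line per myocardial segment)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for k, sid in enumerate(curves.segment_ids):
        ax.plot(curves.values[k], label=sid, lw=1.2)
        tmax = int(curves.values[k].argmax())
        ax.plot(tmax, curves.maxima[k], "o", ms=3, color=ax.lines[-1].get_color())
    ax.set_xlabel("frame")
    ax.set_ylabel("displacement vs frame 0 (px)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, ncol=2)
    return ax
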