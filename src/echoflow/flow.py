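"""Dense optical-flow motion fields between consecutive masked echo frames.

The motion field E_t(u, v) between frames t and t+1 is estimated under the
standard brightness-constancy + local-smoothness assumptions with a coarse-
to-fine (pyramidal) iterative Lucas-Kanade scheme (scikit-image's dense
``optical_flow_ilk``).  Conventions, fixed so tests can assert signs:

* ``u`` is the horizontal component, positive rightward (increasing column);
* ``v`` is the vertical component, positive downward (increasing row);
* both are in pixels/frame, describing where content of frame t moved to in
  frame t+1; origin top-left, 0-based.

Fields are quantised for storage the way two-stream video networks store
their flow frames: each component is clipped to [-clip, clip] and mapped
affinely onto 8-bit [0, 255], so zero motion encodes to 128 and the
round-trip error is at most clip/255 px.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import optical_flow_ilk

from .phantom import EchoSequence

__all__ = [
    "FlowField",
    "FlowFrameEncoding",
    "FlowParams",
    "dense_flow",
    "flow_sequence",
    "encode_flow_frames",
    "decode_flow_frames",
]

DEFAULT_CLIP = 20.0  # px/frame; bounds quantisation error, covers wall speeds


@dataclass
class FlowParams:
    """Pyramidal iterative Lucas-Kanade parameters."""

    radius: int = 7          # local window radius, px
    num_warp: int = 10       # warps per pyramid level
    gaussian: bool = True    # gaussian window conditions the solve better
    prefilter: bool = False


@dataclass
class FlowField:
    u: np.ndarray   # (H, W) horizontal component, px/frame
    v: np.ndarray   # (H, W) vertical component, px/frame
    t: int          # index of the earlier frame

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class FlowFrameEncoding:
    x_frame: np.ndarray   # (H, W) uint8 encoding of u
    y_frame: np.ndarray   # (H, W) uint8 encoding of v
    clip: float
    t: int = 0

    @property
    def scale(self) -> float:
        """px/frame per code unit of the affine map code = (x+clip)/scale."""
        return 2.0 * self.clip / 255.0


def dense_flow(frame_t: np.ndarray, frame_t1: np.ndarray,
               params: FlowParams | None = None) -> FlowField:
    """Estimate the dense motion field from ``frame_t`` to ``frame_t1``.

    Identical frames yield a (near-)zero field; on zeroed (masked-out)
    background the window sees no gradients and the regularised solve returns
    zero motion.  Non-finite solver output is mapped to zero.
    """
    a = np.asarray(frame_t, dtype=np.float32)
    b = np.asarray(frame_t1, dtype=np.float32)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError(f"need same-shape 2-D frames, got {a.shape} vs {b.shape}")
    params = params or FlowParams()
    # reference = later frame: the solver returns, per pixel of frame_t1,
    # the offset back to its source in frame_t; negating gives forward motion
    vr, uc = optical_flow_ilk(
        b, a, radius=params.radius, num_warp=params.num_warp,
        gaussian=params.gaussian, prefilter=params.prefilter)
    u = np.nan_to_num(-uc, nan=0.0, posinf=0.0, neginf=0.0).astype(np.float32)
    v = np.nan_to_num(-vr, nan=0.0, posinf=0.0, neginf=0.0).astype(np.float32)
    # brightness constancy carries no information where both frames are blank
    # (the masked-out background); the pyramid would otherwise extrapolate
    # wall motion into it, so flow is defined only on supported pixels
    support = (a > 0) | (b > 0)
    u *= support
    v *= support
    return FlowField(u=u, v=v, t=0)


def flow_sequence(seq: EchoSequence | np.ndarray,
                  params: FlowParams | None = None) -> list[FlowField]:
    """Flow fields between every consecutive frame pair (n_frames - 1 fields)."""
    frames = seq.frames if isinstance(seq, EchoSequence) else np.asarray(seq)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    fields = []
    for t in range(frames.shape[0] - 1):
        try:
            f = dense_flow(frames[t], frames[t + 1], params)
        except Exception as e:  # annotate with the failing pair
            raise RuntimeError(f"optical flow failed at frame pair ({t}, {t + 1}): {e}") from e
        f.t = t
        fields.append(f)
    return fields


def encode_flow_frames(field: FlowField, clip: float = DEFAULT_CLIP) -> FlowFrameEncoding:
    """Quantise a flow field to an 8-bit (x, y) frame pair.

    Components are clipped to [-clip, clip] and mapped linearly onto
    [0, 255]; zero motion maps to code 128.
    """
    if clip <= 0:
        raise ValueError("clip must be > 0")

    def enc(c):
        code = (np.clip(c, -clip, clip) + clip) * (255.0 / (2.0 * clip))
        return np.round(code).astype(np.uint8)

    return FlowFrameEncoding(x_frame=enc(field.u), y_frame=enc(field.v),
                             clip=float(clip), t=field.t)


def decode_flow_frames(enc: FlowFrameEncoding) -> FlowField:
    """Invert the 8-bit encoding (to within clip/255 quantisation error)."""
    s = enc.scale
    return FlowField(u=enc.x_frame.astype(np.float32) * s - enc.clip,
                     v=enc.y_frame.astype(np.float32) * s - enc.clip,
                     t=enc.t)
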