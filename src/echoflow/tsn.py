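"""Temporal-segment motion-feature extractor.

Follows the sparse-sampling temporal segment scheme from video action
recognition: the flow-frame sequence of a loop is divided into k temporal
segments of equal duration (default k = 7); from each segment one snippet is
drawn — a stack of 5 consecutive (x, y) flow-frame pairs, i.e. a
10-channel image (224x224x10 at the default frame size); every snippet is
scored by one shared-parameter ConvNet F(T_k; W); the segmental consensus
g (element-wise average) combines the k score vectors; and the softmax of
the consensus G gives the video-level prediction:

    TSN(T_1..T_k) = softmax( mean_k F(T_k; W) )

Training minimises the categorical cross-entropy of the consensus,

    L(y, G) = -sum_i y_i (G_i - log sum_j exp G_j),

with a random snippet offset inside each segment per epoch; inference uses
the deterministic central offset.  Motion features are the activations of
the layer feeding the classification head — the flattened 4x4x64 output of
the backbone's last max-pooling stage, a 1024-vector — consensus-averaged
over the k snippets.

The backbone is a compact residual ConvNet sized for CPU training (first
convolution accepts 10 channels); snippets are built from the stored 8-bit
flow frames rescaled to zero-centred floats in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import nn
from .flow import FlowFrameEncoding

__all__ = [
    "Snippet",
    "ConsensusConfig",
    "SnippetScores",
    "MotionFeatureVector",
    "TemporalConvNet",
    "SNIPPET_PAIRS",
    "FEATURE_DIM",
    "sample_snippets",
    "snippet_scores",
    "segmental_consensus",
    "tsn_loss",
    "train_backbone",
    "extract_features",
]

SNIPPET_PAIRS = 5      # consecutive flow-frame pairs per snippet
FEATURE_DIM = 1024     # flattened 4x4x64 last-max-pool output


@dataclass
class ConsensusConfig:
    k: int = 7                       # temporal segments per loop
    consensus_fn: str = "average"
    sampling_mode: str = "center"    # "center" (inference) or "random" (training)

    def validate(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.consensus_fn != "average":
            raise ValueError(f"unknown consensus function {self.consensus_fn!r}")
        if self.sampling_mode not in ("center", "random"):
            raise ValueError(f"unknown sampling mode {self.sampling_mode!r}")


@dataclass
class Snippet:
    stack: np.ndarray      # (10, H, W) float32: 5 pairs x (x, y), zero-centred
    segment_index: int


@dataclass
class SnippetScores:
    scores: np.ndarray         # (k, C) per-snippet class scores F(T_k; W)
    consensus: np.ndarray      # (C,) aggregated score vector G
    probabilities: np.ndarray  # (C,) softmax of G


@dataclass
class MotionFeatureVector:
    values: np.ndarray   # (1024,)
    view: str


def _stack_pairs(encs: list[FlowFrameEncoding], start: int, seg: int) -> Snippet:
    chans = []
    for e in encs[start:start + SNIPPET_PAIRS]:
        chans.append(e.x_frame.astype(np.float32) / 127.5 - 1.0)
        chans.append(e.y_frame.astype(np.float32) / 127.5 - 1.0)
    return Snippet(stack=np.stack(chans), segment_index=seg)


def sample_snippets(flow_frames: list[FlowFrameEncoding],
                    config: ConsensusConfig | None = None,
                    seed: int | None = None) -> list[Snippet]:
    """Draw one 5-pair snippet from each of k equal-duration segments.

    In ``random`` mode the snippet offset within each segment is drawn from a
    generator seeded by ``seed`` (deterministic for a fixed seed); in
    ``center`` mode the central valid offset is used.  Sequences shorter than
    k x 5 pairs are rejected.
    """
    config = config or ConsensusConfig()
    config.validate()
    n = len(flow_frames)
    need = config.k * SNIPPET_PAIRS
    if n < need:
        raise ValueError(
            f"sequence has {n} flow-frame pairs; need at least k*{SNIPPET_PAIRS}={need}")
    rng = np.random.default_rng(seed)
    bounds = [int(round(i * n / config.k)) for i in range(config.k + 1)]
    snippets = []
    for s in range(config.k):
        lo, hi = bounds[s], bounds[s + 1]
        slack = (hi - lo) - SNIPPET_PAIRS
        if config.sampling_mode == "random":
            off = int(rng.integers(0, slack + 1))
        else:
            off = slack // 2
        snippets.append(_stack_pairs(flow_frames, lo + off, s))
    return snippets


def segmental_consensus(scores: np.ndarray, config: ConsensusConfig | None = None) -> np.ndarray:
    """Element-wise average of per-snippet score vectors (order-invariant)."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("empty score list")
    if scores.ndim == 1:
        scores = scores[None]
    config = config or ConsensusConfig()
    config.validate()
    return scores.mean(axis=0)


def tsn_loss(G: np.ndarray, y: np.ndarray) -> float:
    """Categorical cross-entropy of the consensus score vector.

    ``L(y, G) = -sum_i y_i (G_i - log sum_j exp G_j)`` — equal to the softmax
    cross-entropy (-log p_true) for a one-hot ``y``; always >= 0 and -> 0 as
    the true-class margin grows.
    """
    G = np.asarray(G, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if G.shape != y.shape:
        raise ValueError(f"G and y lengths differ: {G.shape} vs {y.shape}")
    return float(-(y * (G - logsumexp(G))).sum())


class TemporalConvNet:
    """Compact residual ConvNet scoring 10-channel flow snippets.

    conv(10->16, stride 2) -> pool -> residual(16) -> conv(16->32) -> pool ->
    residual(32) -> conv(32->64) -> max-pool to 4x4 -> flatten (1024) ->
    linear head (n_classes).  All snippets share the parameters W.
    """

    def __init__(self, n_classes: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.conv1 = nn.Conv2d(10, 16, 3, stride=2, rng=rng)
        self.relu1 = nn.ReLU()
        self.pool1 = nn.MaxPool2d()
        self.res1a = nn.Conv2d(16, 16, 3, rng=rng)
        self.res1r = nn.ReLU()
        self.res1b = nn.Conv2d(16, 16, 3, rng=rng)
        self.relu2 = nn.ReLU()
        self.conv2 = nn.Conv2d(16, 32, 3, rng=rng)
        self.relu3 = nn.ReLU()
        self.pool2 = nn.MaxPool2d()
        self.res2a = nn.Conv2d(32, 32, 3, rng=rng)
        self.res2r = nn.ReLU()
        self.res2b = nn.Conv2d(32, 32, 3, rng=rng)
        self.relu4 = nn.ReLU()
        self.conv3 = nn.Conv2d(32, 64, 3, rng=rng)
        self.relu5 = nn.ReLU()
        self.pool3 = nn.AdaptiveMaxPool2d((4, 4))
        self.head = nn.Linear(FEATURE_DIM, n_classes, rng=rng)

    def params(self):
        ps = []
        for layer in (self.conv1, self.res1a, self.res1b, self.conv2,
                      self.res2a, self.res2b, self.conv3, self.head):
            ps += layer.params()
        return ps

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(N, 10, H, W) -> (scores (N, C), features (N, 1024))."""
        if x.shape[1] != 10:
            raise ValueError(f"backbone expects 10 input channels, got {x.shape[1]}")
        h = self.pool1.forward(self.relu1.forward(self.conv1.forward(x)))
        r = self.res1b.forward(self.res1r.forward(self.res1a.forward(h)))
        h = self.relu2.forward(h + r)
        h = self.pool2.forward(self.relu3.forward(self.conv2.forward(h)))
        r = self.res2b.forward(self.res2r.forward(self.res2a.forward(h)))
        h = self.relu4.forward(h + r)
        h = self.relu5.forward(self.conv3.forward(h))
        h = self.pool3.forward(h)
        feats = h.reshape(h.shape[0], -1)
        self._featshape = h.shape
        return self.head.forward(feats), feats

    def backward(self, gscores: np.ndarray) -> None:
        g = self.head.backward(gscores).reshape(self._featshape)
        g = self.pool3.backward(g)
        g = self.conv3.backward(self.relu5.backward(g))
        g = self.relu4.backward(g)
        g_res = self.res2a.backward(self.res2r.backward(self.res2b.backward(g)))
        g = g + g_res
        g = self.conv2.backward(self.relu3.backward(self.pool2.backward(g)))
        g = self.relu2.backward(g)
        g_res = self.res1a.backward(self.res1r.backward(self.res1b.backward(g)))
        g = g + g_res
        self.conv1.backward(self.relu1.backward(self.pool1.backward(g)))


def snippet_scores(backbone: TemporalConvNet, snippets: list[Snippet],
                   config: ConsensusConfig | None = None) -> SnippetScores:
    """Score every snippet with the shared-parameter backbone and aggregate."""
    x = np.stack([s.stack for s in snippets]).astype(np.float32)
    scores, _ = backbone.forward(x)
    G = segmental_consensus(scores, config)
    return SnippetScores(scores=scores, consensus=G, probabilities=nn.softmax(G))


def train_backbone(backbone: TemporalConvNet, sequences: list[list[FlowFrameEncoding]],
                   labels: list[str], epochs: int = 10, seed: int = 0,
                   lr: float = 1e-3, config: ConsensusConfig | None = None,
                   positive: str = "RWMA") -> list[float]:
    """Fine-tune the backbone on labelled flow sequences.

    One optimisation step per loop per epoch: sample k random-offset
    snippets, score them, average into the consensus, apply the cross-entropy
    loss and backpropagate (each snippet receives 1/k of the consensus
    gradient, the shared-parameter segmental scheme).  Returns per-epoch mean
    losses; deterministic for fixed seed.
    """
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes present")
    cfg = ConsensusConfig(k=(config.k if config else 7), sampling_mode="random")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(backbone.params(), lr=lr)
    y_idx = np.asarray([1 if l == positive else 0 for l in labels])
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(sequences))
        losses = []
        for i in order:
            snips = sample_snippets(sequences[i], cfg, seed=int(rng.integers(2**31)))
            x = np.stack([s.stack for s in snips]).astype(np.float32)
            scores, _ = backbone.forward(x)
            G = segmental_consensus(scores)
            onehot = np.zeros(backbone.n_classes)
            onehot[y_idx[i]] = 1.0
            losses.append(tsn_loss(G, onehot))
            # dL/dG = softmax(G) - y ; dG/dscores_k = 1/k
            gG = (nn.softmax(G) - onehot) / len(snips)
            gscores = np.tile(gG[None], (len(snips), 1)).astype(np.float32)
            opt.zero_grad()
            backbone.backward(gscores)
            opt.step()
        history.append(float(np.mean(losses)))
    return history


def extract_features(backbone: TemporalConvNet, flow_frames: list[FlowFrameEncoding],
                     config: ConsensusConfig | None = None,
                     view: str = "A4C") -> MotionFeatureVector:
    """1024-d motion feature of one loop: consensus (average over the k
    center-sampled snippets) of the last-max-pool activations."""
    cfg = ConsensusConfig(k=(config.k if config else 7), sampling_mode="center")
    snips = sample_snippets(flow_frames, cfg)
    x = np.stack([s.stack for s in snips]).astype(np.float32)
    _, feats = backbone.forward(x)
    return MotionFeatureVector(values=feats.mean(axis=0).astype(np.float64), view=view)
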