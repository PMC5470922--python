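"""Frame-loop drivers: ViBe, depth-only ViBe (ViBe1D), and DEVB.

All three share the sample-model machinery of :mod:`devibe.model_core`;
DEVB additionally maintains a per-pixel reference-proximity model and
reclassifies foreground detections that fail the ghost test.

Random-stream contract: a run consumes a single seeded generator for
the sample model (initialization then, per frame, the five fixed-shape
update arrays), and DEVB consumes a *separate* child stream for the
depth model.  Because draws are mask-independent, DEVB with the ghost
test disabled (tau = inf) on constant-proximity depth reproduces a
plain ViBe run on the corresponding fused frames bit-exactly under the
same seed.

Per frame, classification sees the model as it stood at the end of the
previous frame; all of the frame's updates are applied afterwards in
one vectorized pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .depth_fusion import (
    PROXIMITY_SCALE,
    fused_working_frame,
    init_depth_model,
    is_ghost,
    to_proximity,
    update_depth_frame,
)
from .model_core import AlgoParams, classify_frame, init_model, update_frame

__all__ = ["FrameTriplet", "SegmentationResult", "run_vibe", "run_vibe1d", "run_devb"]

log = logging.getLogger(__name__)


@dataclass
class FrameTriplet:
    """One time step of an RGB-D sequence.

    color: (H, W, 3) uint8; depth: (H, W) uint16 millimeters (0 = hole);
    ground_truth: optional (H, W) boolean mask, True = foreground.
    """

    color: np.ndarray
    depth: np.ndarray
    ground_truth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.color = np.asarray(self.color)
        self.depth = np.asarray(self.depth)
        if self.color.ndim != 3 or self.color.shape[2] != 3:
            raise ValueError("color must be (H, W, 3)")
        if self.depth.shape != self.color.shape[:2]:
            raise ValueError("depth shape does not match color")
        if self.ground_truth is not None:
            self.ground_truth = np.asarray(self.ground_truth, dtype=bool)
            if self.ground_truth.shape != self.depth.shape:
                raise ValueError("ground truth shape does not match frames")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass
class SegmentationResult:
    """Output of a segmentation run.

    masks: (T, H, W) boolean, True = foreground; ghost_reclassified:
    per-frame count of foreground pixels flipped to background by the
    ghost test (all zeros for the ViBe baselines); params: echo of the
    parameters used.
    """

    masks: np.ndarray
    ghost_reclassified: list[int]
    params: AlgoParams

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.ghost_reclassified):
            raise ValueError("one ghost count per mask is required")


def _prepare_frames(frames: Sequence, k_hint: int | None = None) -> list[np.ndarray]:
    if len(frames) == 0:
        raise ValueError("at least one frame is required")
    out = []
    for f in frames:
        a = np.asarray(f, dtype=np.float32)
        if a.ndim == 2:
            a = a[..., None]
        if a.ndim != 3:
            raise ValueError("frames must be (H, W) or (H, W, k)")
        out.append(a)
    shape = out[0].shape
    if any(a.shape != shape for a in out):
        raise ValueError("all frames must share one shape")
    return out


def run_vibe(
    frames: Sequence,
    params: AlgoParams | None = None,
    rng: np.random.Generator | None = None,
) -> SegmentationResult:
    """Plain sample-based background subtraction on a frame sequence.

    ``frames`` may be 8-bit color frames (H, W, 3) or any fixed-k
    value frames on a compatible scale.  The model is initialized from
    frame 1 and frame 1 itself is classified against it (typically
    near-all-background), so the output has one mask per input frame.
    """
    params = params or AlgoParams()
    rng = rng or np.random.default_rng(params.seed)
    fs = _prepare_frames(frames)
    model = init_model(fs[0], params, rng)
    masks = np.empty((len(fs),) + fs[0].shape[:2], dtype=bool)
    for t, f in enumerate(fs):
        fg = classify_frame(model, f, params)
        update_frame(model, f, ~fg, params, rng)
        masks[t] = fg
        log.info("vibe frame %d: %d foreground pixels", t, int(fg.sum()))
    return SegmentationResult(masks=masks, ghost_reclassified=[0] * len(fs), params=params)


def run_vibe1d(
    proximity_frames: Sequence,
    params: AlgoParams | None = None,
    rng: np.random.Generator | None = None,
) -> SegmentationResult:
    """Depth-only baseline: ViBe on 1-component proximity values.

    Input frames are proximity grids in [0, 1]; they are mapped to the
    8-bit scale (x255) so the default radius keeps its magnitude, then
    fed through the identical machinery with k = 1.
    """
    scaled = [np.asarray(p, dtype=np.float64) * PROXIMITY_SCALE for p in proximity_frames]
    return run_vibe(scaled, params, rng)


def run_devb(
    frames: Sequence[FrameTriplet],
    params: AlgoParams | None = None,
    rng: np.random.Generator | None = None,
    depth_rng: np.random.Generator | None = None,
    max_range_mm: int = 8000,
) -> SegmentationResult:
    """Depth-extended segmentation with ghost reclassification.

    Per frame: build the fused working frame, classify it against the
    fused-value sample model; background pixels update the sample model
    and (with the same 1/phi coin, on an independent stream) the depth
    model; foreground pixels face the ghost test against the depth
    model on the 8-bit proximity scale — pixels whose reference
    proximity exceeds the current one by more than ``ghost_threshold``
    are stored as background and update the *sample* model, but not the
    depth model.  Withholding the depth refresh from ghost pixels is
    essential: the reference proximity must keep remembering the
    departed object until the sample model has genuinely absorbed the
    revealed background (after which the pixel no longer reaches the
    ghost branch at all); refreshing it earlier silences the ghost test
    while the stale color samples still misfire.
    """
    params = params or AlgoParams()
    rng = rng or np.random.default_rng(params.seed)
    if depth_rng is None:
        depth_rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    if len(frames) == 0:
        raise ValueError("at least one frame is required")
    shape = frames[0].shape
    if any(tri.shape != shape for tri in frames):
        raise ValueError("all frames must share one shape")

    fused0 = fused_working_frame(frames[0].color, frames[0].depth, max_range_mm)
    model = init_model(fused0, params, rng)
    depth_model = init_depth_model(frames[0].depth, max_range_mm)

    masks = np.empty((len(frames),) + shape, dtype=bool)
    ghost_counts: list[int] = []
    tau = params.ghost_threshold
    for t, tri in enumerate(frames):
        prox = to_proximity(tri.depth, max_range_mm)
        fused = fused_working_frame(tri.color, tri.depth, max_range_mm)
        matched = ~classify_frame(model, fused, params)
        ghost = ~matched & is_ghost(
            depth_model * PROXIMITY_SCALE, prox * PROXIMITY_SCALE, tau
        )
        fg = ~matched & ~ghost
        update_frame(model, fused, ~fg, params, rng)
        update_depth_frame(depth_model, prox, matched, params.subsample_factor, depth_rng)
        masks[t] = fg
        ghost_counts.append(int(ghost.sum()))
        log.info("devb frame %d: %d foreground pixels", t, int(fg.sum()))
        log.debug("devb frame %d: %d ghost pixels reclassified", t, ghost_counts[-1])
    return SegmentationResult(masks=masks, ghost_reclassified=ghost_counts, params=params)
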