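"""Depth preprocessing, color-depth fusion, and the ghost criterion.

Depth frames are 16-bit integers in millimeters; a raw value of 0 is a
hole (the active-IR sensor returned no measurement).  They are mapped to
a *proximity* image on [0, 1] in which larger means closer to the
camera (the usual "brighter is closer" depth rendering); holes map to
0.  The normalized uncertainty sigma = 1 - proximity plays the role of
a variance image: near surfaces give reliable depth (sigma small), far
surfaces and holes are unreliable (sigma -> 1), and the fusion

    wd = (1 - sigma) * d_hat
    wc = (1 + sigma) * c_hat          (per color channel)
    I_hat = (wd + wc) / 2

blends the normalized color c_hat with the proximity d_hat accordingly:
at sigma = 1 the fused image is pure color, at sigma = 0 it is the
color/proximity average.  Fusion is applied per color channel with a
shared depth term, producing a 3-channel fused frame in [0, 1.5] that
is rescaled by 255/1.5 = 170 to the usual 8-bit working scale, so the
conventional match radius R = 20 keeps its magnitude.

The ghost test: a foreground-labelled pixel whose reference proximity
(the depth model, remembered from when the scene was learned) exceeds
its current proximity by more than tau was vacated — the surface there
moved *away* — so the detection is the stale footprint of a departed
object, not a real one, and is reclassified as background.  A pixel
whose current proximity exceeds the reference (an approaching object)
is never a ghost.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "FUSED_SCALE",
    "PROXIMITY_SCALE",
    "to_proximity",
    "compute_sigma",
    "fuse",
    "fused_working_frame",
    "is_ghost",
    "init_depth_model",
    "update_depth_model",
    "update_depth_frame",
]

#: Multiplier taking pre-rescale fused values [0, 1.5] to the [0, 255] scale.
FUSED_SCALE = 255.0 / 1.5

#: Multiplier taking proximity values [0, 1] to the 8-bit scale on which
#: the ghost threshold tau and depth-only segmentation operate.
PROXIMITY_SCALE = 255.0


def to_proximity(depth_mm, max_range_mm: int = 8000) -> np.ndarray:
    """Map millimeter depth to the [0, 1] proximity (closer = larger) scale.

    Valid pixels map linearly, ``(max_range_mm - depth) / max_range_mm``,
    clipped to [0, 1]; holes (raw value 0) map to 0, i.e. they read as
    "maximally far / unknown".  The default 8 m range is the practical
    limit of consumer structured-light depth cameras.
    """
    if max_range_mm <= 0:
        raise ValueError("max_range_mm must be positive")
    d = np.asarray(depth_mm)
    prox = np.clip((max_range_mm - d.astype(np.float64)) / max_range_mm, 0.0, 1.0)
    prox[d == 0] = 0.0
    return prox


def compute_sigma(proximity) -> np.ndarray:
    """Normalized uncertainty: the exact complement of proximity.

    sigma = 1 at holes and at maximum range, 0 at the camera.
    """
    return 1.0 - np.asarray(proximity, dtype=np.float64)


def fuse(color01, proximity, sigma) -> np.ndarray:
    """Uncertainty-weighted color-depth fusion (pre-rescale).

    Parameters are the [0, 1]-normalized color (H, W, 3), the proximity
    frame (H, W) and the uncertainty map (H, W).  Returns the fused
    frame (H, W, 3) with components in [0, 1.5].
    """
    c = np.asarray(color01, dtype=np.float64)
    d = np.asarray(proximity, dtype=np.float64)
    s = np.asarray(sigma, dtype=np.float64)
    if c.shape[:2] != d.shape or d.shape != s.shape:
        raise ValueError(
            f"shape mismatch: color {c.shape}, proximity {d.shape}, sigma {s.shape}"
        )
    wd = (1.0 - s) * d
    return 0.5 * (wd[..., None] + (1.0 + s[..., None]) * c)


def fused_working_frame(color_u8, depth_mm, max_range_mm: int = 8000) -> np.ndarray:
    """Full color+depth -> fused pipeline onto the [0, 255] working scale.

    Convenience wrapper: normalizes 8-bit color by 255, builds proximity
    and sigma, fuses, and rescales by :data:`FUSED_SCALE`.  Returns
    float32, which is the dtype the sample model stores.
    """
    color = np.asarray(color_u8, dtype=np.float64) / 255.0
    prox = to_proximity(depth_mm, max_range_mm)
    fused = fuse(color, prox, compute_sigma(prox))
    return (fused * FUSED_SCALE).astype(np.float32)


def is_ghost(model_value, current_value, tau: float):
    """Ghost test: did the surface at this pixel move away by more than tau?

    ``model_value`` and ``current_value`` must share a scale and tau is
    expressed on that same scale (the segmenters use the 8-bit proximity
    scale).  Returns a boolean (elementwise for array inputs): true iff
    ``model_value - current_value > tau``.  The comparison is signed; an
    approaching object (current > model) never fires.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    diff = np.asarray(model_value, dtype=np.float64) - np.asarray(
        current_value, dtype=np.float64
    )
    out = diff > tau
    return bool(out) if np.isscalar(model_value) and np.isscalar(current_value) else out


def init_depth_model(first_depth_mm, max_range_mm: int = 8000) -> np.ndarray:
    """Depth model MD(x): per-pixel reference proximity, from frame 1."""
    return to_proximity(first_depth_mm, max_range_mm).copy()


def update_depth_model(
    model: np.ndarray,
    position: tuple[int, int],
    current_value: float,
    subsample_factor: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-pixel depth-model refresh (background-classified pixels only).

    With probability ``1/subsample_factor`` the stored reference
    proximity is replaced by the current one — the same memoryless coin
    as the background model.  Modified in place and returned.
    """
    r, c = position
    h, w = model.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"position {position} out of bounds for {h}x{w} grid")
    if rng.random() < 1.0 / subsample_factor:
        model[r, c] = current_value
    return model


def update_depth_frame(
    model: np.ndarray,
    proximity: np.ndarray,
    update_mask: np.ndarray,
    subsample_factor: int,
    rng: np.random.Generator,
) -> None:
    """Vectorized depth-model refresh over a whole frame.

    One coin per pixel is drawn for the entire frame (mask-independent
    stream consumption, as in :func:`devibe.model_core.update_frame`).
    """
    coin = rng.random(model.shape)
    hit = np.asarray(update_mask, dtype=bool) & (coin < 1.0 / subsample_factor)
    model[hit] = np.asarray(proximity)[hit]
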