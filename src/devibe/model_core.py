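"""Sample-based per-pixel background model (the ViBe machinery).

Each pixel x keeps a bag of ``n_samples`` raw values observed at x or in
its 8-neighborhood, M(x) = {v_1, ..., v_N}.  A new observation v(x) is
background when at least ``min_matches`` stored samples lie within
Euclidean distance ``radius`` of it.  Background pixels trigger a
memoryless update: with probability ``1/subsample_factor`` one randomly
chosen sample of the pixel's own bag is overwritten by v(x), and
independently, with the same probability, one randomly chosen sample of
a randomly chosen in-bounds 8-neighbor's bag.  Random replacement (as
opposed to FIFO) gives every sample an exponentially decaying expected
lifespan, so the model adapts smoothly without a fixed memory horizon.

All grids are row-major with 0-based (row, col) coordinates, origin at
the top-left.  Values live in a k-dimensional Euclidean space (k = 3 for
color or fused frames, k = 1 for depth-only runs) on an 8-bit-like
[0, 255] working scale so that the conventional radius R = 20 keeps its
usual magnitude.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AlgoParams",
    "SampleModelGrid",
    "BACKGROUND",
    "FOREGROUND",
    "init_model",
    "count_matches",
    "classify",
    "classify_frame",
    "stochastic_update",
    "update_frame",
    "survival_probability",
    "simulate_sample_survival",
]

log = logging.getLogger(__name__)

BACKGROUND = "background"
FOREGROUND = "foreground"


@dataclass(frozen=True)
class AlgoParams:
    """Parameters shared by all segmenters.

    Attributes
    ----------
    n_samples : int
        Number of stored samples per pixel (N).  Default 20.
    radius : float
        Euclidean match radius in pixel-value units (R).  Default 20.
    min_matches : int
        Minimum number of matching samples for a background decision
        (lambda).  Default 2.
    subsample_factor : int
        Time subsampling factor (phi): a background pixel has one chance
        in ``subsample_factor`` of updating its model.  Default 16.
    ghost_threshold : float
        Threshold tau of the depth-based ghost test, expressed on the
        8-bit proximity scale (see :mod:`devibe.depth_fusion`).
        Default 2.  May be ``inf`` to disable ghost reclassification.
    seed : int
        Seed of the pseudo-random stream when the caller does not supply
        a generator.
    """

    n_samples: int = 20
    radius: float = 20.0
    min_matches: int = 2
    subsample_factor: int = 16
    ghost_threshold: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be a positive integer")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if not 1 <= self.min_matches <= self.n_samples:
            raise ValueError("min_matches must satisfy 1 <= min_matches <= n_samples")
        if self.subsample_factor < 1:
            raise ValueError("subsample_factor must be a positive integer")
        if self.ghost_threshold < 0:
            raise ValueError("ghost_threshold must be non-negative")


@dataclass
class SampleModelGrid:
    """Per-pixel background sample collection.

    ``samples`` has shape ``(height, width, n_samples, k)`` (float32).
    """

    samples: np.ndarray

    @property
    def height(self) -> int:
        return self.samples.shape[0]

    @property
    def width(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[2]

    @property
    def k(self) -> int:
        return self.samples.shape[3]


_OFFSETS8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@functools.lru_cache(maxsize=64)
def _neighbor_table(height: int, width: int, include_self: bool):
    """Packed in-bounds neighbor lookup.

    Returns ``(packed, counts)`` where ``packed`` has shape
    ``(height*width, m)`` (m = 9 with self, 8 without) holding flat pixel
    indices with the valid neighbors packed first, and ``counts`` gives
    the number of valid entries per pixel.  Border pixels simply have
    fewer valid neighbors; there is no wrap-around or clamping.
    """
    offsets = ((0, 0),) + _OFFSETS8 if include_self else _OFFSETS8
    dr = np.array([o[0] for o in offsets])
    dc = np.array([o[1] for o in offsets])
    r = np.arange(height)[:, None, None] + dr
    c = np.arange(width)[None, :, None] + dc
    valid = (r >= 0) & (r < height) & (c >= 0) & (c < width)
    flat = np.clip(r, 0, height - 1) * width + np.clip(c, 0, width - 1)
    order = np.argsort(~valid, axis=-1, kind="stable")
    packed = np.take_along_axis(flat, order, axis=-1).reshape(height * width, -1)
    counts = valid.sum(axis=-1).reshape(-1)
    return packed, counts


def _as_value_frame(frame) -> np.ndarray:
    f = np.asarray(frame, dtype=np.float32)
    if f.size == 0:
        raise ValueError("frame is empty")
    if f.ndim == 2:
        f = f[..., None]
    if f.ndim != 3:
        raise ValueError(f"expected a (H, W) or (H, W, k) frame, got shape {f.shape}")
    return f


def init_model(first_frame, params: AlgoParams, rng: np.random.Generator) -> SampleModelGrid:
    """Build the background model from the first frame.

    For every pixel, ``n_samples`` values are drawn uniformly at random
    (with replacement) from the pixel's 8-neighborhood including itself;
    border pixels draw from their clipped (in-bounds) neighborhood.
    This makes frame 1 classifiable immediately, at the price of
    adopting any frame-1 foreground into the model — the origin of
    ghosts.
    """
    frame = _as_value_frame(first_frame)
    h, w, k = frame.shape
    packed, counts = _neighbor_table(h, w, True)
    u = rng.random((h * w, params.n_samples))
    choice = np.minimum((u * counts[:, None]).astype(np.int64), counts[:, None] - 1)
    picked = np.take_along_axis(packed, choice, axis=1)
    samples = frame.reshape(-1, k)[picked]
    return SampleModelGrid(samples=samples.reshape(h, w, params.n_samples, k))


def _value_and_samples(value, samples):
    v = np.asarray(value, dtype=np.float64).reshape(-1)
    s = np.asarray(samples, dtype=np.float64)
    if s.ndim == 1:
        s = s[:, None]
    if s.ndim != 2 or s.shape[1] != v.size:
        raise ValueError(
            f"dimensionality mismatch: value has {v.size} components, "
            f"samples have shape {s.shape}"
        )
    return v, s


def count_matches(value, samples, radius: float) -> int:
    """Number of stored samples at strict Euclidean distance < radius."""
    v, s = _value_and_samples(value, samples)
    d2 = ((s - v) ** 2).sum(axis=1)
    return int(np.count_nonzero(d2 < radius * radius))


def classify(value, samples, params: AlgoParams) -> str:
    """Label a single observation against a sample bag.

    Returns :data:`BACKGROUND` when at least ``min_matches`` samples
    match, else :data:`FOREGROUND`.
    """
    n = count_matches(value, samples, params.radius)
    return BACKGROUND if n >= params.min_matches else FOREGROUND


def classify_frame(model: SampleModelGrid, frame, params: AlgoParams) -> np.ndarray:
    """Vectorized classification of a whole frame.

    Returns a boolean foreground mask (True = foreground).
    """
    f = _as_value_frame(frame)
    if f.shape[:2] != (model.height, model.width) or f.shape[2] != model.k:
        raise ValueError("frame shape does not match the model")
    d2 = ((model.samples - f[:, :, None, :]) ** 2).sum(axis=-1)
    matches = np.count_nonzero(d2 < params.radius * params.radius, axis=-1)
    return matches < params.min_matches


def stochastic_update(
    model: SampleModelGrid,
    position: tuple[int, int],
    value,
    params: AlgoParams,
    rng: np.random.Generator,
) -> SampleModelGrid:
    """Single-pixel memoryless update (call only for background pixels).

    Five pseudo-random draws are consumed in a fixed order regardless of
    the coin outcomes — self coin, self slot, neighbor coin, neighbor
    choice, neighbor slot — so that identical seeds give bit-identical
    trajectories.  The model is modified in place and returned.
    """
    h, w, n, k = model.samples.shape
    r, c = position
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"position {position} out of bounds for {h}x{w} grid")
    v = np.asarray(value, dtype=np.float32).reshape(-1)
    if v.size != k:
        raise ValueError("value dimensionality does not match the model")
    inv = 1.0 / params.subsample_factor

    self_coin = rng.random()
    self_slot = int(rng.integers(n))
    nb_coin = rng.random()
    packed, counts = _neighbor_table(h, w, False)
    p = r * w + c
    nb_idx = int(rng.integers(counts[p]))
    nb_slot = int(rng.integers(n))

    if self_coin < inv:
        model.samples[r, c, self_slot] = v
    if nb_coin < inv:
        q = packed[p, nb_idx]
        model.samples.reshape(-1, n, k)[q, nb_slot] = v
    return model


def update_frame(
    model: SampleModelGrid,
    frame,
    background_mask: np.ndarray,
    params: AlgoParams,
    rng: np.random.Generator,
    *,
    neighbor_update: bool = True,
    tags: np.ndarray | None = None,
) -> None:
    """Vectorized memoryless update of all background pixels of a frame.

    The random draws are whole-frame arrays consumed in the fixed order
    self coin, self slot, neighbor coin, neighbor choice, neighbor slot,
    for *every* pixel (the background mask only gates where they take
    effect).  Consuming the stream independently of the classification
    outcome means two runs that share a seed and frame shapes stay in
    lockstep even when their masks differ — the property behind the
    exact DEVB-to-ViBe reduction when the ghost test is disabled.

    When several pixels elect the same neighbor slot in the same frame,
    the write of the highest flat pixel index wins (deterministic).

    Parameters
    ----------
    neighbor_update : bool
        Disable to isolate the pixel's own temporal subsampling from
        spatial diffusion (used when measuring the sample-lifespan law).
    tags : ndarray of bool, optional
        Shape ``(H, W, n_samples)``; entries are cleared wherever a
        sample is overwritten, which lets callers track the survival of
        a tagged cohort of samples.
    """
    f = _as_value_frame(frame)
    h, w, n, k = model.samples.shape
    bg = np.asarray(background_mask, dtype=bool)
    if bg.shape != (h, w):
        raise ValueError("background mask shape does not match the model")
    inv = 1.0 / params.subsample_factor

    self_coin = rng.random((h, w))
    self_slot = rng.integers(0, n, size=(h, w))
    nb_coin = rng.random((h, w))
    nb_u = rng.random((h, w))
    nb_slot = rng.integers(0, n, size=(h, w))

    flat_samples = model.samples.reshape(h * w, n, k)
    flat_frame = f.reshape(-1, k)
    flat_tags = tags.reshape(h * w, n) if tags is not None else None

    do_self = (bg & (self_coin < inv)).reshape(-1)
    idx = np.flatnonzero(do_self)
    slots = self_slot.reshape(-1)[idx]
    flat_samples[idx, slots] = flat_frame[idx]
    if flat_tags is not None:
        flat_tags[idx, slots] = False

    if neighbor_update:
        packed, counts = _neighbor_table(h, w, False)
        do_nb = (bg & (nb_coin < inv)).reshape(-1)
        j = np.flatnonzero(do_nb)
        choice = np.minimum((nb_u.reshape(-1)[j] * counts[j]).astype(np.int64), counts[j] - 1)
        target = packed[j, choice]
        nslots = nb_slot.reshape(-1)[j]
        flat_samples[target, nslots] = flat_frame[j]
        if flat_tags is not None:
            flat_tags[target, nslots] = False


def survival_probability(n_samples: int, dt: float, *, form: str = "power") -> float:
    """Probability that a given sample is still in a pixel's bag after
    ``dt`` update opportunities.

    Each update replaces one of ``n_samples`` slots uniformly at random,
    so a sample survives one update with probability (N-1)/N and, under
    time continuity, dt updates with probability ((N-1)/N)**dt — equal
    to exp(-ln(N/(N-1)) * dt), the exponential-decay form.  Both closed
    forms are exposed and must agree to floating tolerance.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if form == "power":
        return float(((n_samples - 1) / n_samples) ** dt)
    if form == "exponential":
        return float(np.exp(-np.log(n_samples / (n_samples - 1)) * dt))
    raise ValueError("form must be 'power' or 'exponential'")


def simulate_sample_survival(
    shape: tuple[int, int],
    params: AlgoParams,
    n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Empirical sample-lifespan curve on a static scene.

    Builds a model on a uniform static frame, tags every initial sample,
    and runs the real per-frame update for ``n_frames`` frames with the
    spatial (neighbor) channel disabled, so that only the pixel's own
    1/phi coin and uniform slot replacement act — the process whose
    per-frame survival probability is exactly 1 - 1/(N*phi).  Returns
    the surviving-tag fraction after each frame (length ``n_frames``,
    monotone non-increasing).  With the neighbor channel on, diffusion
    from the 8-neighborhood adds a second, comparable replacement hazard
    and the curve decays roughly twice as fast; disabling it isolates
    the law being measured.
    """
    h, w = shape
    frame = np.full((h, w, 1), 128.0, dtype=np.float32)
    model = init_model(frame, params, rng)
    tags = np.ones((h, w, params.n_samples), dtype=bool)
    bg = np.ones((h, w), dtype=bool)
    curve = np.empty(n_frames)
    for t in range(n_frames):
        update_frame(model, frame, bg, params, rng, neighbor_update=False, tags=tags)
        curve[t] = tags.mean()
    return curve
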