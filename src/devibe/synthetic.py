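"""Seeded synthetic RGB-D scene generator.

Renders toy indoor scenes the way a consumer depth camera sees them: a
textured static background plane at a fixed range, flat-colored moving
objects strictly closer than the background, per-frame independent
depth holes (raw value 0), and optional global illumination flicker.
The named scenarios reproduce the situations that break color-only
background subtraction — a ghost inducer (object present in frame 1
that then departs), a black-shadow inducer (a similar-colored, closer
object crossing the departed object's footprint), flickering depth
holes, and illumination flicker — with per-frame ground truth, so the
whole pipeline is testable without recorded video.

Everything is fully determined by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .segmenters import FrameTriplet

__all__ = [
    "ObjectSpec",
    "SceneSpec",
    "Scenario",
    "generate",
    "ghost_scenario",
    "black_shadow_scenario",
    "holes_scenario",
    "flicker_scenario",
    "static_scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class ObjectSpec:
    """A flat-colored moving object.

    ``positions`` is the per-frame top-left corner of the bounding box,
    one entry per frame of the object's lifetime starting at
    ``first_frame``; the object disappears after its last position.
    """

    color: tuple[int, int, int]
    depth_mm: int
    size: tuple[int, int]
    positions: tuple[tuple[int, int], ...]
    shape: str = "rect"
    first_frame: int = 0

    @property
    def last_frame(self) -> int:
        return self.first_frame + len(self.positions) - 1


@dataclass(frozen=True)
class SceneSpec:
    height: int = 64
    width: int = 64
    n_frames: int = 30
    background_color: tuple[int, int, int] = (100, 100, 100)
    texture_amplitude: float = 5.0
    background_depth_mm: int = 3000
    objects: tuple[ObjectSpec, ...] = ()
    hole_rate: float = 0.0
    flicker_amplitude: float = 0.0
    seed: int = 0


@dataclass
class Scenario:
    """A generated sequence plus the named regions a study measures."""

    frames: list[FrameTriplet]
    regions: dict
    spec: SceneSpec


def _footprint(obj: ObjectSpec, pos: tuple[int, int], h: int, w: int) -> np.ndarray:
    r0, c0 = pos
    oh, ow = obj.size
    if r0 < 0 or c0 < 0 or r0 + oh > h or c0 + ow > w:
        raise ValueError(f"object trajectory leaves the {h}x{w} frame at {pos}")
    mask = np.zeros((h, w), dtype=bool)
    if obj.shape == "rect":
        mask[r0 : r0 + oh, c0 : c0 + ow] = True
    elif obj.shape == "ellipse":
        rr = (np.arange(h)[:, None] - (r0 + (oh - 1) / 2)) / (oh / 2)
        cc = (np.arange(w)[None, :] - (c0 + (ow - 1) / 2)) / (ow / 2)
        mask = rr**2 + cc**2 <= 1.0
    else:
        raise ValueError(f"unknown object shape {obj.shape!r}")
    return mask


def generate(spec: SceneSpec) -> list[FrameTriplet]:
    """Render a SceneSpec into color/depth/ground-truth frame triplets.

    Background texture noise is i.i.d. uniform +/- texture_amplitude per
    pixel and channel, frozen at frame 1 for a truly static background;
    when ``flicker_amplitude`` > 0 the texture is re-drawn every frame
    and a global brightness offset uniform in +/- flicker_amplitude is
    added, emulating flickering lights.  Holes are an independent
    per-pixel, per-frame coin at ``hole_rate``.
    """
    h, w = spec.height, spec.width
    if h < 1 or w < 1 or spec.n_frames < 1:
        raise ValueError("height, width and n_frames must be positive")
    if not 0.0 <= spec.hole_rate <= 1.0:
        raise ValueError("hole_rate must lie in [0, 1]")
    for obj in spec.objects:
        if obj.depth_mm >= spec.background_depth_mm:
            raise ValueError("objects must be closer than the background")
        if obj.depth_mm <= 0:
            raise ValueError("object depth must be positive")

    rng = np.random.default_rng(spec.seed)
    base = np.asarray(spec.background_color, dtype=np.float64)
    amp = spec.texture_amplitude
    texture = rng.uniform(-amp, amp, (h, w, 3)) if amp > 0 else np.zeros((h, w, 3))

    frames: list[FrameTriplet] = []
    for t in range(spec.n_frames):
        flick = 0.0
        if spec.flicker_amplitude > 0:
            if amp > 0:
                texture = rng.uniform(-amp, amp, (h, w, 3))
            flick = rng.uniform(-spec.flicker_amplitude, spec.flicker_amplitude)
        color = base + texture + flick
        depth = np.full((h, w), spec.background_depth_mm, dtype=np.float64)
        gt = np.zeros((h, w), dtype=bool)
        for obj in spec.objects:
            if obj.first_frame <= t <= obj.last_frame:
                m = _footprint(obj, obj.positions[t - obj.first_frame], h, w)
                color[m] = np.asarray(obj.color, dtype=np.float64) + flick
                depth[m] = obj.depth_mm
                gt |= m
        if spec.hole_rate > 0:
            holes = rng.random((h, w)) < spec.hole_rate
            depth[holes] = 0
        frames.append(
            FrameTriplet(
                color=np.clip(color, 0, 255).astype(np.uint8),
                depth=depth.astype(np.uint16),
                ground_truth=gt,
            )
        )
    return frames


def _centered(h: int, w: int, size: tuple[int, int]) -> tuple[int, int]:
    return (h - size[0]) // 2, (w - size[1]) // 2


def ghost_scenario(height: int = 64, width: int = 64, n_frames: int = 60, seed: int = 0) -> Scenario:
    """Canonical ghost inducer: an object present only in frame 1.

    From frame 2 on the ground truth inside the object's initial
    footprint is all background, yet a model built from frame 1 has
    memorized the object there — a color-only segmenter keeps detecting
    a foreground blob that corresponds to no real object.  The region
    is returned under ``regions['ghost']`` for targeted false-positive
    measurement.
    """
    if n_frames < 3:
        raise ValueError("the ghost scenario needs at least 3 frames")
    size = (max(2, height // 4), max(2, width // 4))
    pos = _centered(height, width, size)
    obj = ObjectSpec(
        color=(180, 60, 60), depth_mm=1500, size=size, positions=(pos,), first_frame=0
    )
    spec = SceneSpec(
        height=height,
        width=width,
        n_frames=n_frames,
        objects=(obj,),
        hole_rate=0.01,
        seed=seed,
    )
    frames = generate(spec)
    region = _footprint(obj, pos, height, width)
    return Scenario(frames=frames, regions={"ghost": region}, spec=spec)


def black_shadow_scenario(
    height: int = 64, width: int = 64, n_frames: int = 30, seed: int = 0
) -> Scenario:
    """Black-shadow inducer: a look-alike crosses a departed object's spot.

    Object A sits on region Q in frame 1 and leaves; object B, with
    nearly the same color but much closer to the camera, later walks
    across Q.  A color-only model still holding A's values matches B
    and swallows it (the "black shadow"); the depth contrast is what a
    depth-aware segmenter must exploit to keep B foreground.  Regions:
    ``old_target`` (Q) and ``crossing_by_frame`` (B's footprint per
    frame index).
    """
    if n_frames < 10:
        raise ValueError("the black-shadow scenario needs at least 10 frames")
    size = (max(2, height // 4), max(2, width // 4))
    q_pos = _centered(height, width, size)
    a = ObjectSpec(
        color=(150, 150, 150), depth_mm=2200, size=size, positions=(q_pos,), first_frame=0
    )
    # B enters at the left edge on Q's row and walks right across Q.
    enter = 8
    step = 4
    cols = range(0, width - size[1] + 1, step)
    positions = tuple((q_pos[0], c) for c in cols)[: max(0, n_frames - enter)]
    if not positions:
        raise ValueError("n_frames too small for the crossing trajectory")
    b = ObjectSpec(
        color=(155, 155, 155), depth_mm=600, size=size, positions=positions, first_frame=enter
    )
    spec = SceneSpec(
        height=height,
        width=width,
        n_frames=n_frames,
        objects=(a, b),
        hole_rate=0.01,
        seed=seed,
    )
    frames = generate(spec)
    q_region = _footprint(a, q_pos, height, width)
    crossing = {
        b.first_frame + i: _footprint(b, p, height, width) for i, p in enumerate(positions)
    }
    return Scenario(
        frames=frames,
        regions={"old_target": q_region, "crossing_by_frame": crossing},
        spec=spec,
    )


def holes_scenario(height: int = 64, width: int = 64, n_frames: int = 30, seed: int = 0) -> Scenario:
    """Static scene with heavy flickering depth holes (5% per pixel/frame)."""
    spec = SceneSpec(height=height, width=width, n_frames=n_frames, hole_rate=0.05, seed=seed)
    return Scenario(frames=generate(spec), regions={}, spec=spec)


def flicker_scenario(
    height: int = 64, width: int = 64, n_frames: int = 30, seed: int = 0
) -> Scenario:
    """Static scene under flickering illumination (+/- 20 gray levels)."""
    spec = SceneSpec(
        height=height, width=width, n_frames=n_frames, flicker_amplitude=20.0, seed=seed
    )
    return Scenario(frames=generate(spec), regions={}, spec=spec)


def static_scenario(
    height: int = 64, width: int = 64, n_frames: int = 30, seed: int = 0
) -> Scenario:
    """Completely static textured scene — the all-background control."""
    spec = SceneSpec(height=height, width=width, n_frames=n_frames, seed=seed)
    return Scenario(frames=generate(spec), regions={}, spec=spec)


SCENARIOS = {
    "ghost": ghost_scenario,
    "black_shadow": black_shadow_scenario,
    "holes": holes_scenario,
    "flicker": flicker_scenario,
    "static": static_scenario,
}
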