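"""Readers and writers for frame-directory RGB-D sequences.

A sequence is three parallel directories of PNGs: 8-bit RGB color,
16-bit single-channel depth in millimeters (0 = hole), and optionally
8-bit ground-truth masks (>= 128 means foreground).  Frames are paired
by natural sort of their file names.

Some public RGB-D change-detection recordings ship their 16-bit depth
PNGs with the three most significant bits moved to the least
significant end; ``depth_transform`` undoes such dialects.  Because the
written description of the bit shuffle is ambiguous, both 3-bit
rotations are provided (each inverts the other), selected by name;
the default is no transform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

from .segmenters import FrameTriplet, SegmentationResult

__all__ = [
    "SequenceSpec",
    "DEPTH_TRANSFORMS",
    "rotl3",
    "rotr3",
    "natural_key",
    "read_sequence",
    "write_sequence",
    "read_masks",
    "write_masks",
]


def rotl3(values) -> np.ndarray:
    """Rotate each 16-bit value left by 3 bits."""
    v = np.asarray(values).astype(np.uint32)
    return (((v << 3) | (v >> 13)) & 0xFFFF).astype(np.uint16)


def rotr3(values) -> np.ndarray:
    """Rotate each 16-bit value right by 3 bits (inverse of rotl3)."""
    v = np.asarray(values).astype(np.uint32)
    return (((v >> 3) | (v << 13)) & 0xFFFF).astype(np.uint16)


DEPTH_TRANSFORMS = {
    "none": lambda v: np.asarray(v, dtype=np.uint16),
    "rotl3": rotl3,
    "rotr3": rotr3,
}


@dataclass(frozen=True)
class SequenceSpec:
    color_dir: Path
    depth_dir: Optional[Path] = None
    gt_dir: Optional[Path] = None
    pattern: str = "*.png"
    depth_transform: str = "none"
    max_range_mm: int = 8000

    def __post_init__(self) -> None:
        if self.depth_transform not in DEPTH_TRANSFORMS:
            raise ValueError(
                f"unknown depth transform {self.depth_transform!r}; "
                f"choose from {sorted(DEPTH_TRANSFORMS)}"
            )
        if self.max_range_mm <= 0:
            raise ValueError("max_range_mm must be positive")


def natural_key(name: str):
    """Sort key treating digit runs numerically ('frame2' < 'frame10')."""
    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", str(name))]


def _listdir(directory: Path, pattern: str) -> list[Path]:
    d = Path(directory)
    if not d.is_dir():
        raise FileNotFoundError(f"directory not found: {d}")
    return sorted(d.glob(pattern), key=lambda p: natural_key(p.name))


def _read_color(path: Path) -> np.ndarray:
    try:
        img = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise naming the file
        raise IOError(f"cannot read color frame {path}: {exc}") from exc
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    return img.astype(np.uint8)


def _read_depth(path: Path, transform: str) -> np.ndarray:
    try:
        img = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read depth frame {path}: {exc}") from exc
    if img.ndim != 2:
        img = img[..., 0]
    return DEPTH_TRANSFORMS[transform](img)


def _read_gt(path: Path) -> np.ndarray:
    try:
        img = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read ground-truth frame {path}: {exc}") from exc
    if img.ndim != 2:
        img = img[..., 0]
    return img >= 128


def read_sequence(spec: SequenceSpec) -> list[FrameTriplet]:
    """Load an aligned color(/depth/ground-truth) frame sequence."""
    color_files = _listdir(spec.color_dir, spec.pattern)
    if not color_files:
        raise FileNotFoundError(f"no frames matching {spec.pattern} in {spec.color_dir}")
    depth_files = gt_files = None
    if spec.depth_dir is not None:
        depth_files = _listdir(spec.depth_dir, spec.pattern)
        if len(depth_files) != len(color_files):
            raise ValueError(
                f"frame count mismatch: {len(color_files)} color vs "
                f"{len(depth_files)} depth frames"
            )
    if spec.gt_dir is not None:
        gt_files = _listdir(spec.gt_dir, spec.pattern)
        if len(gt_files) != len(color_files):
            raise ValueError(
                f"frame count mismatch: {len(color_files)} color vs "
                f"{len(gt_files)} ground-truth frames"
            )
    triplets = []
    for i, cf in enumerate(color_files):
        color = _read_color(cf)
        depth = (
            _read_depth(depth_files[i], spec.depth_transform)
            if depth_files is not None
            else np.zeros(color.shape[:2], dtype=np.uint16)
        )
        gt = _read_gt(gt_files[i]) if gt_files is not None else None
        triplets.append(FrameTriplet(color=color, depth=depth, ground_truth=gt))
    return triplets


def _frame_name(i: int) -> str:
    return f"{i:06d}.png"


def write_sequence(frames: Sequence[FrameTriplet], out_dir) -> dict[str, Path]:
    """Write a sequence as color/, depth/ and (when present) gt/ PNGs."""
    out = Path(out_dir)
    dirs = {"color": out / "color", "depth": out / "depth"}
    if frames and frames[0].ground_truth is not None:
        dirs["gt"] = out / "gt"
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)
    for i, tri in enumerate(frames):
        name = _frame_name(i)
        iio.imwrite(dirs["color"] / name, tri.color.astype(np.uint8))
        iio.imwrite(dirs["depth"] / name, tri.depth.astype(np.uint16))
        if "gt" in dirs:
            iio.imwrite(
                dirs["gt"] / name,
                np.where(tri.ground_truth, 255, 0).astype(np.uint8),
            )
    return dirs


def write_masks(result, out_dir, names: Sequence[str] | None = None) -> list[Path]:
    """Write binary masks as 8-bit PNGs (0 = background, 255 = foreground).

    ``result`` is a :class:`SegmentationResult` or an iterable of
    boolean masks; ``names`` (defaulting to 000000.png, ...) lets the
    outputs mirror the input frame names.
    """
    masks = result.masks if isinstance(result, SegmentationResult) else result
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc
    paths = []
    for i, mask in enumerate(masks):
        name = names[i] if names is not None else _frame_name(i)
        path = out / name
        iio.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))
        paths.append(path)
    return paths


def read_masks(directory, pattern: str = "*.png") -> list[np.ndarray]:
    """Read a directory of binary mask PNGs (natural-sorted)."""
    files = _listdir(directory, pattern)
    if not files:
        raise FileNotFoundError(f"no masks matching {pattern} in {directory}")
    return [_read_gt(f) for f in files]
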