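"""Confusion counting and the percentage-of-wrong-classifications metric.

PWC = 100 * (FN + FP) / (TP + TN + FP + FN) summarizes a binary
segmentation against ground truth in one number; lower is better.  An
optional ignore mask excludes pixels (e.g. unknown regions of a
hand-made ground truth) from every bucket; without it the metric is the
plain whole-image definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion",
    "pwc",
    "mean_pwc",
    "false_positive_fraction",
    "recall",
    "sequence_metrics",
    "write_metrics_csv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _as_binary(grid, name: str) -> np.ndarray:
    a = np.asarray(grid)
    if a.dtype != bool:
        a = a >= 128 if a.dtype.kind in "ui" else a.astype(bool)
    return a


def confusion(mask, truth, ignore=None) -> ConfusionCounts:
    """Pixel-wise confusion tally (foreground = True or >= 128)."""
    m = _as_binary(mask, "mask")
    t = _as_binary(truth, "truth")
    if m.shape != t.shape:
        raise ValueError(f"shape mismatch: mask {m.shape} vs truth {t.shape}")
    if ignore is not None:
        keep = ~_as_binary(ignore, "ignore")
        if keep.shape != m.shape:
            raise ValueError("ignore mask shape mismatch")
        m, t = m[keep], t[keep]
    return ConfusionCounts(
        tp=int(np.count_nonzero(m & t)),
        fp=int(np.count_nonzero(m & ~t)),
        tn=int(np.count_nonzero(~m & ~t)),
        fn=int(np.count_nonzero(~m & t)),
    )


def pwc(counts: ConfusionCounts) -> float:
    """Percentage of wrong classifications, in [0, 100]."""
    if counts.total == 0:
        raise ValueError("PWC is undefined for zero evaluated pixels")
    return 100.0 * (counts.fn + counts.fp) / counts.total


def mean_pwc(per_frame: Sequence[float]) -> float:
    if len(per_frame) == 0:
        raise ValueError("mean of an empty PWC list is undefined")
    return float(np.mean(per_frame))


def false_positive_fraction(mask, truth, region=None) -> float:
    """FP / (FP + TN): the fraction of true-background pixels marked
    foreground, optionally restricted to a boolean region."""
    m = _as_binary(mask, "mask")
    t = _as_binary(truth, "truth")
    sel = ~t if region is None else (np.asarray(region, bool) & ~t)
    denom = int(sel.sum())
    if denom == 0:
        raise ValueError("no true-background pixels in the selected region")
    return float(np.count_nonzero(m & sel)) / denom


def recall(mask, truth, region=None) -> float:
    """TP / (TP + FN) over the (optionally region-restricted) truth."""
    m = _as_binary(mask, "mask")
    t = _as_binary(truth, "truth")
    sel = t if region is None else (np.asarray(region, bool) & t)
    denom = int(sel.sum())
    if denom == 0:
        raise ValueError("no true-foreground pixels in the selected region")
    return float(np.count_nonzero(m & sel)) / denom


def sequence_metrics(masks, truths, ignore=None) -> pd.DataFrame:
    """Per-frame confusion counts and PWC as a DataFrame.

    Columns: frame_index, tp, fp, tn, fn, pwc.
    """
    if len(masks) != len(truths):
        raise ValueError("one ground-truth mask per segmentation mask is required")
    rows = []
    for i, (m, t) in enumerate(zip(masks, truths)):
        c = confusion(m, t, ignore)
        rows.append(
            {"frame_index": i, "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn, "pwc": pwc(c)}
        )
    return pd.DataFrame(rows, columns=["frame_index", "tp", "fp", "tn", "fn", "pwc"])


def write_metrics_csv(df: pd.DataFrame, path) -> float:
    """Write the metrics table with a trailing 'mean' PWC row.

    Returns the sequence mean PWC.
    """
    mean = mean_pwc(df["pwc"].tolist())
    out = df.astype(object)
    out.loc[len(out)] = ["mean", "", "", "", "", mean]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return mean
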