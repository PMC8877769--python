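"""Segmentation and HC-estimation accuracy metrics.

Dice is computed on filled regions; Hausdorff and ASSD on contour point
sets (in mm, after scaling each coordinate axis by its pixel spacing):

    Dice = 2 |Seg ∩ GT| / (|Seg| + |GT|)
    HD   = max( max_i min_j d(s_i, g_j),  max_j min_i d(g_j, s_i) )
    ASSD = mean( mean_i min_j d(s_i, g_j),  mean_j min_i d(g_j, s_i) )
    PMAE = mean_i 100 * |pred_i - gt_i| / gt_i
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidInputError
from .geometry import PixelSpacing

__all__ = [
    "MetricsReport",
    "dice",
    "hausdorff",
    "assd",
    "hc_errors",
]


@dataclass
class MetricsReport:
    """Per-image (or aggregate) evaluation record; distances in mm."""

    dice: float | None = None
    hd_mm: float | None = None
    assd_mm: float | None = None
    mae_mm: float | None = None
    mae_px: float | None = None
    pmae_pct: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "MetricsReport":
        return cls(**json.loads(s))


def _as_mask(m: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(m)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError(f"{name} must be a nonempty 2-D mask")
    return arr.astype(bool)


def dice(seg: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap of two filled-region masks; 1.0 when both are empty."""
    s = _as_mask(seg, "seg")
    g = _as_mask(gt, "gt")
    if s.shape != g.shape:
        raise InvalidInputError(f"shape mismatch: {s.shape} vs {g.shape}")
    denom = int(s.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((s & g).sum()) / denom


def _as_points(c: np.ndarray, name: str) -> np.ndarray:
    pts = np.asarray(c, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise InvalidInputError(f"{name} must be a nonempty (n, 2) point set")
    return pts


def _scaled(pts: np.ndarray, spacing: PixelSpacing) -> np.ndarray:
    return pts * np.array([spacing.sx, spacing.sy])


def _directed(d1: np.ndarray, d2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour distances from d1 to d2 and from d2 to d1."""
    t1 = cKDTree(d2)
    t2 = cKDTree(d1)
    return t1.query(d1)[0], t2.query(d2)[0]


def hausdorff(
    c1: np.ndarray, c2: np.ndarray, spacing: PixelSpacing = PixelSpacing(1.0)
) -> float:
    """Symmetric Hausdorff distance between two contours, in mm."""
    p1 = _scaled(_as_points(c1, "c1"), spacing)
    p2 = _scaled(_as_points(c2, "c2"), spacing)
    fwd, bwd = _directed(p1, p2)
    return float(max(fwd.max(), bwd.max()))


def assd(
    c1: np.ndarray, c2: np.ndarray, spacing: PixelSpacing = PixelSpacing(1.0)
) -> float:
    """Average symmetric surface distance: mean of the two directed means, mm."""
    p1 = _scaled(_as_points(c1, "c1"), spacing)
    p2 = _scaled(_as_points(c2, "c2"), spacing)
    fwd, bwd = _directed(p1, p2)
    return float((fwd.mean() + bwd.mean()) / 2.0)


def hc_errors(
    pred: Sequence[float], gt: Sequence[float]
) -> tuple[float, float]:
    """Mean absolute error (same units as input) and percentage MAE.

    PMAE averages the per-case ratio 100*|pred-gt|/gt, so each image is
    weighted equally regardless of head size.
    """
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gt, dtype=float)
    if p.shape != g.shape or p.ndim != 1 or p.size == 0:
        raise InvalidInputError(
            f"pred and gt must be equal-length nonempty 1-D sequences, got {p.shape} vs {g.shape}"
        )
    if (g <= 0).any():
        raise InvalidInputError("reference HC values must be positive")
    err = np.abs(p - g)
    return float(err.mean()), float((100.0 * err / g).mean())
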