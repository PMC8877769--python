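"""Synthetic elliptical skull phantoms with analytically known HC.

Each phantom emulates one fetal-ultrasound head image: a bright elliptical
skull band (optionally with angular gaps, mimicking the fuzzy/missing
contour segments of real scans) over a darker brain-tissue interior and a
background with clutter blobs, smoothed by a point-spread blur and
corrupted by multiplicative gamma speckle.  Ground truth is exact by
construction: the filled head mask and the contour band are rasterized
from the ellipse parameters, and the reference HC is the *exact*
elliptic-integral perimeter of the physical ellipse — not the Ramanujan
closed form — so the approximation error of the closed form remains
measurable downstream.

Pixel spacing is coupled to the rendered head size (larger heads are
imaged deeper, hence with coarser pixels), with lognormal jitter, clipped
to a configurable range.  This mirrors the depth/zoom behaviour of real
acquisitions and keeps physical HC learnable from the image alone; fully
independent uniform spacing is available via ``spacing_mode="uniform"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidParameterError
from .geometry import EllipseParams, PixelSpacing, exact_perimeter

__all__ = [
    "PhantomConfig",
    "PhantomRecord",
    "SplitSpec",
    "generate_phantom",
    "generate_dataset",
    "split_dataset",
    "augment_training_set",
    "kfold_indices",
    "render_filled_mask",
    "render_contour_band",
]

ANNOT_COLUMNS = ("filename", "pixel size(mm)", "HC(mm)")


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; defaults define the study conditions.

    Geometry is sampled uniformly: semi-major axis ``a`` in ``a_range``
    (pixels), axis ratio ``b/a`` in ``ratio_range`` (fetal skulls are
    mildly eccentric), orientation in [0, 180), center jittered around the
    frame center.  Spacing (mm/px) follows the depth/zoom coupling
    described in the module docstring.
    """

    size: int = 256
    a_range: tuple[float, float] = (20.0, 90.0)
    ratio_range: tuple[float, float] = (0.6, 1.0)
    center_jitter: float = 0.08          # fraction of frame size
    band_fraction: float = 0.08          # skull thickness relative to a
    min_band_px: float = 2.0
    gap_fraction: float = 0.15           # fraction of the band removed
    max_gaps: int = 2
    spacing_mode: str = "coupled"        # "coupled" | "uniform"
    spacing_ref: float = 0.12            # mm/px at reference perimeter
    perimeter_ref: float = 250.0         # px
    spacing_exponent: float = 0.5
    spacing_jitter_sigma: float = 0.08
    spacing_range: tuple[float, float] = (0.05, 0.3)
    bg_level: float = 0.15
    interior_level: float = 0.35
    band_level: float = 0.85
    n_clutter: int = 3
    clutter_amp: float = 0.25
    blur_sigma: float = 1.0
    speckle_looks: float = 4.0
    noise: bool = True


@dataclass
class PhantomRecord:
    """One synthetic image with its exact ground truth."""

    id: str
    image: np.ndarray            # (H, W) uint8
    gt_mask: np.ndarray          # (H, W) bool, filled head region
    gt_contour: np.ndarray       # (H, W) bool, skull band
    ellipse: EllipseParams
    spacing: PixelSpacing
    hc_mm: float


@dataclass(frozen=True)
class SplitSpec:
    """Counts for the train/validation/test partition."""

    n_train: int
    n_val: int
    n_test: int
    seed: int = 0

    def __post_init__(self):
        if min(self.n_train, self.n_val, self.n_test) < 0:
            raise InvalidParameterError("split counts must be nonnegative")


def _ellipse_frames(size: int, e: EllipseParams):
    y, x = np.mgrid[0:size, 0:size].astype(float)
    t = math.radians(e.theta)
    c, s = math.cos(t), math.sin(t)
    u = (x - e.cx) * c + (y - e.cy) * s
    v = -(x - e.cx) * s + (y - e.cy) * c
    return u, v


def render_filled_mask(e: EllipseParams, size: int) -> np.ndarray:
    """Pixels whose centers lie inside the ellipse."""
    u, v = _ellipse_frames(size, e)
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0


def render_contour_band(
    e: EllipseParams, size: int, thickness: float,
    gap_arcs: list[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Elliptical band of the given radial thickness, with optional angular gaps.

    ``gap_arcs`` are (start, end) parametric angles in radians; band pixels
    whose parametric angle falls inside an arc are removed.
    """
    u, v = _ellipse_frames(size, e)
    half = thickness / 2.0
    outer = (u / (e.a + half)) ** 2 + (v / (e.b + half)) ** 2 <= 1.0
    inner = (u / max(e.a - half, 0.5)) ** 2 + (v / max(e.b - half, 0.5)) ** 2 < 1.0
    band = outer & ~inner
    if gap_arcs:
        ang = np.arctan2(v / e.b, u / e.a) % (2 * math.pi)
        cut = np.zeros_like(band)
        for lo, hi in gap_arcs:
            lo %= 2 * math.pi
            hi %= 2 * math.pi
            if lo <= hi:
                cut |= (ang >= lo) & (ang <= hi)
            else:
                cut |= (ang >= lo) | (ang <= hi)
        band &= ~cut
    return band


def generate_phantom(seed: int, config: PhantomConfig = PhantomConfig(),
                     record_id: str | None = None) -> PhantomRecord:
    """Render one phantom, fully determined by ``seed`` and ``config``."""
    rng = np.random.default_rng(seed)
    size = config.size
    a = rng.uniform(*config.a_range)
    b = a * rng.uniform(*config.ratio_range)
    theta = rng.uniform(0.0, 180.0)
    if a >= size / 2.0 - 2:
        raise InvalidParameterError(
            f"semi-major axis {a:.1f} does not fit a {size}x{size} frame"
        )
    jit = config.center_jitter * size
    lim = size / 2.0 - a - 2.0
    jx = rng.uniform(-min(jit, lim), min(jit, lim))
    jy = rng.uniform(-min(jit, lim), min(jit, lim))
    e = EllipseParams((size - 1) / 2.0 + jx, (size - 1) / 2.0 + jy, a, b, theta)

    perim_px = exact_perimeter(a, b)
    if config.spacing_mode == "coupled":
        eps = math.exp(rng.normal(0.0, config.spacing_jitter_sigma))
        s = config.spacing_ref * (perim_px / config.perimeter_ref) ** config.spacing_exponent * eps
        s = float(np.clip(s, *config.spacing_range))
    elif config.spacing_mode == "uniform":
        s = float(rng.uniform(*config.spacing_range))
    else:
        raise InvalidParameterError(f"unknown spacing_mode {config.spacing_mode!r}")
    spacing = PixelSpacing(s)
    hc = exact_perimeter(a * s, b * s)

    gt_mask = render_filled_mask(e, size)
    thickness = max(config.min_band_px, config.band_fraction * a)
    gt_contour = render_contour_band(e, size, thickness)

    # corrupted band for the rendered image: angular gaps
    gap_arcs = []
    if config.gap_fraction > 0:
        n_gaps = int(rng.integers(1, config.max_gaps + 1))
        widths = rng.dirichlet(np.ones(n_gaps)) * config.gap_fraction * 2 * math.pi
        for w in widths:
            start = rng.uniform(0.0, 2 * math.pi)
            gap_arcs.append((start, start + w))
    band_img = render_contour_band(e, size, thickness, gap_arcs)

    img = np.full((size, size), config.bg_level)
    img[gt_mask] = config.interior_level
    img[band_img] = config.band_level

    if config.noise:
        for _ in range(config.n_clutter):
            bx, by = rng.uniform(0, size, 2)
            br = rng.uniform(size / 30, size / 8)
            y, x = np.mgrid[0:size, 0:size]
            blob = np.exp(-(((x - bx) ** 2 + (y - by) ** 2) / (2 * br**2)))
            img += config.clutter_amp * rng.uniform(0.3, 1.0) * blob * ~gt_mask
        img = ndimage.gaussian_filter(img, config.blur_sigma)
        L = config.speckle_looks
        img *= rng.gamma(L, 1.0 / L, size=img.shape)
    else:
        img = ndimage.gaussian_filter(img, config.blur_sigma)

    image8 = np.clip(img * 255.0, 0, 255).astype(np.uint8)
    return PhantomRecord(
        id=record_id if record_id is not None else f"{seed:09d}",
        image=image8,
        gt_mask=gt_mask,
        gt_contour=gt_contour,
        ellipse=e,
        spacing=spacing,
        hc_mm=float(hc),
    )


def generate_dataset(
    n: int,
    seed: int,
    config: PhantomConfig = PhantomConfig(),
    out_dir: str | Path | None = None,
) -> tuple[list[PhantomRecord], pd.DataFrame]:
    """Generate ``n`` phantoms with per-record derived seeds and an annotation table.

    When ``out_dir`` is given, writes an HC18-style layout:
    ``images/NNN.png``, ``masks/NNN_Annotation.png`` and ``annotations.csv``
    with columns (filename, pixel size(mm), HC(mm)).
    """
    if n < 1:
        raise InvalidParameterError(f"need n >= 1, got {n}")
    child_seeds = np.random.SeedSequence(seed).generate_state(n)
    records = [
        generate_phantom(int(cs) % (2**31), config, record_id=f"{i:03d}")
        for i, cs in enumerate(child_seeds)
    ]
    table = pd.DataFrame(
        {
            ANNOT_COLUMNS[0]: [f"{r.id}.png" for r in records],
            ANNOT_COLUMNS[1]: [r.spacing.sx for r in records],
            ANNOT_COLUMNS[2]: [r.hc_mm for r in records],
        }
    )
    if out_dir is not None:
        from .io import write_dataset

        write_dataset(records, out_dir)
    return records, table


def split_dataset(records: list, spec: SplitSpec) -> tuple[list[int], list[int], list[int]]:
    """Seeded random partition into train/validation/test index lists."""
    n = len(records)
    if spec.n_train + spec.n_val + spec.n_test != n:
        raise InvalidParameterError(
            f"split counts {spec.n_train}+{spec.n_val}+{spec.n_test} != {n} records"
        )
    perm = np.random.default_rng(spec.seed).permutation(n)
    i1 = spec.n_train
    i2 = i1 + spec.n_val
    return list(perm[:i1]), list(perm[i1:i2]), list(perm[i2:])


def _flip_record(r: PhantomRecord) -> PhantomRecord:
    W = r.image.shape[1]
    e = r.ellipse
    fe = EllipseParams(W - 1 - e.cx, e.cy, e.a, e.b, (180.0 - e.theta) % 180.0)
    return PhantomRecord(
        id=r.id + "_flip",
        image=r.image[:, ::-1].copy(),
        gt_mask=r.gt_mask[:, ::-1].copy(),
        gt_contour=r.gt_contour[:, ::-1].copy(),
        ellipse=fe,
        spacing=r.spacing,
        hc_mm=r.hc_mm,
    )


def _rotate_record(r: PhantomRecord, angle_deg: float = 10.0) -> PhantomRecord:
    """Rotate image content by ``angle_deg`` about the frame center.

    With y pointing down, ``scipy.ndimage.rotate(+phi)`` maps a point p to
    R(-phi) (p - c) + c, i.e. the ellipse orientation decreases by phi.
    Masks are re-rendered from the transformed ellipse (exact), only the
    intensity image is interpolated.  HC is invariant under rotation.
    """
    H, W = r.image.shape
    c0 = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    phi = math.radians(angle_deg)
    cph, sph = math.cos(phi), math.sin(phi)
    e = r.ellipse
    rel = np.array([e.cx, e.cy]) - c0
    new_c = c0 + np.array([cph * rel[0] + sph * rel[1], -sph * rel[0] + cph * rel[1]])
    ne = EllipseParams(new_c[0], new_c[1], e.a, e.b, (e.theta - angle_deg) % 180.0)
    if not (
        e.a <= new_c[0] <= W - 1 - e.a and e.a <= new_c[1] <= H - 1 - e.a
    ):
        import logging

        logging.getLogger(__name__).warning(
            "rotated ellipse %s extends past the frame edge; mask clipped at the border", r.id
        )
    img = ndimage.rotate(r.image.astype(float), angle_deg, reshape=False, order=1,
                         mode="constant", cval=float(np.median(r.image)))
    size = r.image.shape[0]
    return PhantomRecord(
        id=r.id + "_rot",
        image=np.clip(img, 0, 255).astype(np.uint8),
        gt_mask=render_filled_mask(ne, size),
        gt_contour=render_contour_band(ne, size, max(2.0, 0.08 * ne.a)),
        ellipse=ne,
        spacing=r.spacing,
        hc_mm=r.hc_mm,
    )


def augment_training_set(records: list[PhantomRecord], angle_deg: float = 10.0) -> list[PhantomRecord]:
    """Original + horizontal flip + one rotated copy per record (3x count).

    Reference HC is unchanged by both operations (flip and rotation are
    rigid in pixel space and spacing is untouched).
    """
    if not records:
        raise InvalidParameterError("cannot augment an empty training set")
    out: list[PhantomRecord] = []
    for r in records:
        out.append(r)
        out.append(_flip_record(r))
        out.append(_rotate_record(r, angle_deg))
    return out


def kfold_indices(n: int, k: int = 5, seed: int = 0):
    """Deterministic shuffled k-fold splits; larger test folds come first.

    Returns a list of (train_indices, test_indices) pairs covering every
    index exactly once across test folds; with n = 999, k = 5 the test
    folds have sizes 200, 200, 200, 200, 199.
    """
    from sklearn.model_selection import KFold

    if n < k:
        raise InvalidParameterError(f"need n >= k, got n={n}, k={k}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.tolist(), te.tolist()) for tr, te in kf.split(np.arange(n))]
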