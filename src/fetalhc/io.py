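"""Dataset readers/writers and the cross-validated experiment runner.

On-disk layout (HC18-style)::

    root/
      images/000.png            8-bit grayscale
      masks/000_Annotation.png  0/255 filled head mask (optional)
      annotations.csv           filename, pixel size(mm), HC(mm)

All randomized behavior in :func:`run_experiment` flows from a single
top-level seed that is recorded in every output file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .agreement import agreement_report
from .errors import EmptyMaskError, InvalidInputError, InvalidParameterError
from .geometry import PixelSpacing
from .metrics import MetricsReport, assd, dice, hausdorff, hc_errors
from .models import RegressionHC, SegmentationHC
from .phantoms import ANNOT_COLUMNS, PhantomConfig, PhantomRecord, generate_dataset, kfold_indices
from .postproc import mask_to_contour_points

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "LoadedRecord",
    "write_dataset",
    "read_dataset",
    "run_experiment",
]


@dataclass
class AnnotationTable:
    """Validated per-image annotation rows (filename, pixel size, HC)."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ANNOT_COLUMNS if c not in self.df.columns]
        if missing:
            raise InvalidInputError(f"annotation table missing columns {missing}")
        if self.df[ANNOT_COLUMNS[0]].duplicated().any():
            dup = self.df[ANNOT_COLUMNS[0]][self.df[ANNOT_COLUMNS[0]].duplicated()].iloc[0]
            raise InvalidInputError(f"duplicate filename in annotations: {dup!r}")
        for col in ANNOT_COLUMNS[1:]:
            bad = self.df.index[~(self.df[col] > 0)].tolist()
            if bad:
                raise InvalidInputError(
                    f"column {col!r} must be positive; offending rows {bad[:5]}"
                )

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class LoadedRecord:
    """One image as loaded from disk; mask may be absent (prediction-only)."""

    id: str
    image: np.ndarray
    mask: np.ndarray | None
    spacing: PixelSpacing
    hc_mm: float


def write_dataset(records: list[PhantomRecord], root: str | Path) -> None:
    """Write records in the HC18-style layout described in the module docs."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        iio.imwrite(root / "images" / f"{r.id}.png", r.image)
        iio.imwrite(root / "masks" / f"{r.id}_Annotation.png",
                    (r.gt_mask.astype(np.uint8) * 255))
        rows.append((f"{r.id}.png", r.spacing.sx, r.hc_mm))
    pd.DataFrame(rows, columns=list(ANNOT_COLUMNS)).to_csv(root / "annotations.csv", index=False)


def read_dataset(root: str | Path) -> tuple[list[LoadedRecord], AnnotationTable]:
    """Load a dataset written by :func:`write_dataset` (or HC18-formatted data).

    Missing masks are tolerated with a warning; a missing CSV, malformed
    row, or unreadable image raises a descriptive error naming the file.
    """
    root = Path(root)
    csv = root / "annotations.csv"
    if not csv.exists():
        raise InvalidInputError(f"annotation file not found: {csv}")
    df = pd.read_csv(csv)
    table = AnnotationTable(df)
    records = []
    n_missing_masks = 0
    for _, row in df.iterrows():
        fname = row[ANNOT_COLUMNS[0]]
        img_path = root / "images" / fname
        try:
            image = np.asarray(iio.imread(img_path))
        except FileNotFoundError as exc:
            raise InvalidInputError(f"image not readable: {img_path}") from exc
        mask_path = root / "masks" / (Path(fname).stem + "_Annotation.png")
        mask = None
        if mask_path.exists():
            mask = np.asarray(iio.imread(mask_path)) > 127
        else:
            n_missing_masks += 1
        records.append(
            LoadedRecord(
                id=Path(fname).stem,
                image=image,
                mask=mask,
                spacing=PixelSpacing(float(row[ANNOT_COLUMNS[1]])),
                hc_mm=float(row[ANNOT_COLUMNS[2]]),
            )
        )
    if n_missing_masks:
        logger.warning("%d/%d records have no mask (prediction-only mode)",
                       n_missing_masks, len(records))
    return records, table


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

DEFAULT_EXPERIMENT = {
    "seed": 0,
    "n_phantoms": 120,
    "k_folds": 2,
    "routes": ["segmentation", "regression"],
    "input_size": [64, 64],
    "epochs_seg": 12,
    "epochs_reg": 25,
    "learning_rate": 3e-3,
    "dropout_keep": 0.8,
    "batch_size": 16,
    "loss_reg": "MAE",
    "phantom_size": 256,
}

_VALID_KEYS = set(DEFAULT_EXPERIMENT)


def _seg_quality(pred_mask: np.ndarray, gt_mask: np.ndarray, spacing: PixelSpacing) -> MetricsReport:
    rep = MetricsReport()
    rep.dice = dice(pred_mask, gt_mask)
    try:
        c1 = mask_to_contour_points(pred_mask)
        c2 = mask_to_contour_points(gt_mask)
        rep.hd_mm = hausdorff(c1, c2, spacing)
        rep.assd_mm = assd(c1, c2, spacing)
    except EmptyMaskError:  # empty prediction: distances undefined
        rep.hd_mm = rep.assd_mm = None
    return rep


def _fold_seg_quality(est, images, gt_masks, spacings, in_size) -> list[MetricsReport]:
    """Per-image segmentation quality at network resolution.

    Predicted and reference masks are compared on the network grid; pixel
    spacing is scaled by the resize factor so distances stay in mm.
    """
    from .models import preprocess_images, resize_mask

    xin = preprocess_images(images, in_size)
    reports = []
    for i in range(xin.shape[0]):
        prob = est.model_.predict_proba(xin[i : i + 1])[0]
        gt_small = resize_mask(gt_masks[i], in_size) > 0.5
        H, W = images[i].shape
        sp = PixelSpacing(spacings[i].sx * W / in_size[1],
                          spacings[i].sy * H / in_size[0])
        reports.append(_seg_quality(prob >= 0.5, gt_small, sp))
    return reports


def run_experiment(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Train and evaluate both routes under seeded k-fold cross-validation.

    ``config`` may be a dict or a path to a YAML/JSON file with keys from
    :data:`DEFAULT_EXPERIMENT`; unknown keys raise before any compute.
    Returns a summary dict (and writes summary CSV / per-image CSV / JSON
    reports when ``out_dir`` is given); identical configs give identical
    summaries.
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text()) or {}
    unknown = set(config) - _VALID_KEYS
    if unknown:
        raise InvalidParameterError(f"unknown experiment config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_EXPERIMENT, **config}
    seed = int(cfg["seed"])
    routes = list(cfg["routes"])

    size = int(cfg["phantom_size"])
    scale = size / PhantomConfig.size  # geometry ranges proportional to frame
    pconf = PhantomConfig(
        size=size,
        a_range=(PhantomConfig.a_range[0] * scale, PhantomConfig.a_range[1] * scale),
    )
    records, _ = generate_dataset(int(cfg["n_phantoms"]), seed, pconf)
    images = np.stack([r.image for r in records]).astype(float)
    masks = np.stack([r.gt_mask for r in records]).astype(float)
    hc = np.array([r.hc_mm for r in records])
    spacings = [r.spacing for r in records]

    folds = kfold_indices(len(records), int(cfg["k_folds"]), seed)
    in_size = tuple(int(v) for v in cfg["input_size"])

    per_image_rows = []
    fold_stats: dict[str, list[dict]] = {r: [] for r in routes}
    route_abs_errors: dict[str, np.ndarray] = {}
    all_preds: dict[str, list] = {r: [] for r in routes}
    all_refs: dict[str, list] = {r: [] for r in routes}

    for ifold, (tr, te) in enumerate(folds):
        tr = np.asarray(tr)
        te = np.asarray(te)
        for route in routes:
            seg_reports = None
            if route == "segmentation":
                est = SegmentationHC(input_size=in_size, epochs=int(cfg["epochs_seg"]),
                                     learning_rate=float(cfg["learning_rate"]),
                                     batch_size=int(cfg["batch_size"]),
                                     random_state=seed + ifold)
                est.fit(images[tr], masks[tr])
                pred = est.predict(images[te], spacing=[spacings[i] for i in te])
                seg_reports = _fold_seg_quality(est, images[te], masks[te],
                                                [spacings[i] for i in te], in_size)
            elif route == "regression":
                est = RegressionHC(input_size=in_size, epochs=int(cfg["epochs_reg"]),
                                   learning_rate=float(cfg["learning_rate"]),
                                   batch_size=int(cfg["batch_size"]),
                                   loss=str(cfg["loss_reg"]),
                                   dropout_keep=float(cfg["dropout_keep"]),
                                   random_state=seed + ifold)
                est.fit(images[tr], hc[tr])
                pred = est.predict(images[te])
            else:
                raise InvalidParameterError(f"unknown route {route!r}")
            ok = np.isfinite(pred)
            n_failed = int((~ok).sum())
            if n_failed:
                logger.warning("fold %d %s route: %d failed predictions excluded",
                               ifold, route, n_failed)
            mae, pmae = hc_errors(pred[ok], hc[te][ok])
            stats = {"fold": ifold, "mae_mm": mae, "pmae_pct": pmae,
                     "n": int(ok.sum()), "n_failed": n_failed}
            if seg_reports is not None:
                stats["dice"] = float(np.mean([r.dice for r in seg_reports]))
                hds = [r.hd_mm for r in seg_reports if r.hd_mm is not None]
                if hds:
                    stats["hd_mm"] = float(np.mean(hds))
                    stats["assd_mm"] = float(np.mean(
                        [r.assd_mm for r in seg_reports if r.assd_mm is not None]))
            fold_stats[route].append(stats)
            all_preds[route].extend(pred[ok])
            all_refs[route].extend(hc[te][ok])
            for j, i_img in enumerate(te):
                per_image_rows.append(
                    {"fold": ifold, "route": route, "id": records[i_img].id,
                     "hc_pred_mm": pred[j], "hc_ref_mm": hc[i_img]}
                )

    summary_rows = []
    reports = {}
    for route in routes:
        maes = [f["mae_mm"] for f in fold_stats[route]]
        pmaes = [f["pmae_pct"] for f in fold_stats[route]]
        row = {
            "route": route,
            "mae_mm_mean": float(np.mean(maes)), "mae_mm_std": float(np.std(maes)),
            "pmae_pct_mean": float(np.mean(pmaes)), "pmae_pct_std": float(np.std(pmaes)),
            "n_failed": int(sum(f["n_failed"] for f in fold_stats[route])),
        }
        dices = [f["dice"] for f in fold_stats[route] if "dice" in f]
        if dices:
            row["dice_mean"] = float(np.mean(dices))
            row["hd_mm_mean"] = float(np.mean(
                [f["hd_mm"] for f in fold_stats[route] if "hd_mm" in f]))
            row["assd_mm_mean"] = float(np.mean(
                [f["assd_mm"] for f in fold_stats[route] if "assd_mm" in f]))
        summary_rows.append(row)
        reports[route] = agreement_report(all_preds[route], all_refs[route])

    t_p = None
    if set(routes) >= {"segmentation", "regression"}:
        # pair per-image absolute errors on images where both routes succeeded
        by_route = {}
        for route in ("segmentation", "regression"):
            by_route[route] = {
                row["id"]: abs(row["hc_pred_mm"] - row["hc_ref_mm"])
                for row in per_image_rows
                if row["route"] == route and np.isfinite(row["hc_pred_mm"])
            }
        common = sorted(set(by_route["segmentation"]) & set(by_route["regression"]))
        if len(common) >= 3:
            from .agreement import paired_t

            t_p = paired_t(
                [by_route["segmentation"][i] for i in common],
                [by_route["regression"][i] for i in common],
            )

    result = {
        "seed": seed,
        "config": cfg,
        "summary": summary_rows,
        "folds": fold_stats,
        "agreement": {r: reports[r].to_json() for r in routes},
        "paired_t_p_value": t_p,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# seed={seed}\n"
        with open(out / "summary.csv", "w") as fh:
            fh.write(header)
            pd.DataFrame(summary_rows).to_csv(fh, index=False)
        with open(out / "predictions.csv", "w") as fh:
            fh.write(header)
            pd.DataFrame(per_image_rows).to_csv(fh, index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(result, fh, indent=2, default=str)
    return result
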