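"""End-to-end slide inference and cohort evaluation.

A slide flows through: Otsu tissue mask -> fragment boxes -> per-fragment
U-Net epithelium masks merged at level 0 -> centerline tile sampling ->
tile classification -> worst-tile slide diagnosis. A slide whose merged
epithelium mask is empty (or below ``min_epithelium_area``) is classified
"others" without ever reaching the classifier: non-representative samples
have no epithelium to grade. Over-segmented slides (epithelium found where
there is none) go through the classifier like any other slide.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .centerline import extract_centerline, extract_tiles, sample_tile_centers
from .labels import CLASS_NAMES, OTHERS, OrdinalLabel, label_name
from .metrics import (ConfusionMatrix, classification_report, detection_balanced_accuracy,
                      exclude_class)
from .slide_io import Box, SlideImage, crop_and_resize, detect_fragments, otsu_tissue_mask

__all__ = ["PipelineConfig", "SlideDiagnosis", "diagnose_slide", "run_cohort"]


@dataclasses.dataclass
class PipelineConfig:
    crop_size: int = 1024            # segmentation input side
    tile_size: int = 512             # tile side at 20x
    tile_interval: float = 256.0     # sampling interval in 20x pixels
    tile_magnification: float = 20.0
    min_fragment_area_frac: float = 0.0005  # of the overview area
    closing_radius: int = 5
    overview_max_side: int = 2048
    min_epithelium_area: int = 0     # level-0 px; 0 = strictly-empty rule
    min_skeleton_length: int = 10


@dataclasses.dataclass
class SlideDiagnosis:
    slide_id: str
    label: object                    # OrdinalLabel or OTHERS
    worst_tile: object = None
    worst_score: float | None = None
    worst_probs: np.ndarray | None = None
    n_fragments: int = 0
    n_epithelium_pixels: int = 0
    n_tiles: int = 0


def _segment(seg_model, crop):
    """Accept either a trained SegModel or any oracle exposing segment()."""
    if hasattr(seg_model, "segment"):
        return seg_model.segment(crop)
    from .segmentation import predict_mask

    return predict_mask(seg_model, crop)


def diagnose_slide(slide: SlideImage, seg_model, cls_model, config: PipelineConfig | None = None,
                   slide_id: str = "") -> SlideDiagnosis:
    config = config or PipelineConfig()
    overview, down = slide.overview(config.overview_max_side)
    tissue = otsu_tissue_mask(overview)
    min_area = config.min_fragment_area_frac * tissue.size
    boxes_ov = detect_fragments(tissue, min_area=min_area, closing_radius=config.closing_radius)

    w, h = slide.dimensions
    merged = np.zeros((h, w), dtype=bool)
    n_fragments = 0
    from .slide_io import unwarp_mask_to_level0

    for box_ov in boxes_ov:
        box = Box(int(box_ov.x0 * down), int(box_ov.y0 * down),
                  min(int(np.ceil(box_ov.x1 * down)), w), min(int(np.ceil(box_ov.y1 * down)), h))
        if box.area <= 0:
            continue
        n_fragments += 1
        crop = crop_and_resize(slide, box, size=config.crop_size)
        crop_mask = _segment(seg_model, crop)
        merged |= unwarp_mask_to_level0(crop, crop_mask, (h, w))

    n_epi = int(merged.sum())
    if n_epi <= config.min_epithelium_area:
        return SlideDiagnosis(slide_id=slide_id, label=OTHERS, n_fragments=n_fragments,
                              n_epithelium_pixels=n_epi, n_tiles=0)

    interval_level0 = config.tile_interval * slide.base_magnification / config.tile_magnification
    lines = extract_centerline(merged, min_length=config.min_skeleton_length)
    tiles = []
    for eid, line in enumerate(lines):
        centers = sample_tile_centers(line, interval=interval_level0)
        tiles.extend(extract_tiles(slide, centers, size=config.tile_size,
                                   magnification=config.tile_magnification,
                                   slide_id=slide_id, epithelium_id=eid))
    if not tiles:
        return SlideDiagnosis(slide_id=slide_id, label=OTHERS, n_fragments=n_fragments,
                              n_epithelium_pixels=n_epi, n_tiles=0)

    probs = cls_model.predict_proba_tiles(tiles)
    scores = probs @ np.arange(1, probs.shape[1] + 1, dtype=float)
    order = sorted(range(len(tiles)), key=lambda i: (-scores[i], -probs[i, -1], i))
    worst = order[0]
    label = OrdinalLabel(int(np.argmax(probs[worst])) + 1)
    return SlideDiagnosis(slide_id=slide_id, label=label, worst_tile=tiles[worst],
                          worst_score=float(scores[worst]), worst_probs=probs[worst],
                          n_fragments=n_fragments, n_epithelium_pixels=n_epi,
                          n_tiles=len(tiles))


def run_cohort(manifest: pd.DataFrame, seg_model, cls_model, out_dir=None,
               config: PipelineConfig | None = None, slide_root=None,
               slide_loader=None) -> tuple[pd.DataFrame, dict]:
    """Diagnose every manifest row; return predictions and a metrics report.

    ``slide_loader(row) -> SlideImage`` overrides file loading (used with
    in-memory phantoms). Failures are logged per slide and the run
    continues; failed slides are excluded from the confusion matrix.
    """
    config = config or PipelineConfig()
    rows = []
    for _, row in manifest.iterrows():
        slide_id = str(row["slide_id"])
        try:
            if slide_loader is not None:
                slide = slide_loader(row)
            else:
                root = Path(slide_root) if slide_root is not None else Path(".")
                slide = SlideImage.from_file(root / row["path"])
            diag = diagnose_slide(slide, seg_model, cls_model, config, slide_id=slide_id)
            rows.append({"slide_id": slide_id, "predicted": label_name(diag.label),
                         "actual": str(row["label"]),
                         "worst_score": diag.worst_score if diag.worst_score is not None else "",
                         "n_tiles": diag.n_tiles, "failed": False})
        except Exception as exc:  # noqa: BLE001 - partial failures logged, run continues
            rows.append({"slide_id": slide_id, "predicted": "failed",
                         "actual": str(row["label"]), "worst_score": "",
                         "n_tiles": 0, "failed": True, "error": str(exc)})
    predictions = pd.DataFrame(rows)

    ok = predictions[~predictions["failed"]]
    classes = list(CLASS_NAMES) + [OTHERS]
    cm = ConfusionMatrix.from_labels(ok["predicted"], ok["actual"], classes=classes)
    report = {"n_slides": int(len(predictions)), "n_failed": int(predictions["failed"].sum()),
              "all_classes": classification_report(cm)}
    cm3 = exclude_class(cm, OTHERS)
    if cm3.total > 0 and (cm3.actual_totals > 0).all():
        report["excluding_others"] = classification_report(cm3)
    actual_pos = (ok["actual"] != OTHERS).to_numpy()
    pred_pos = (ok["predicted"] != OTHERS).to_numpy()
    if actual_pos.any() and (~actual_pos).any():
        report["detection_balanced_accuracy"] = detection_balanced_accuracy(pred_pos, actual_pos)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        predictions.to_csv(out_dir / "predictions.csv", index=False)
        cm.to_frame().to_csv(out_dir / "confusion_matrix.csv")
        (out_dir / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return predictions, report
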