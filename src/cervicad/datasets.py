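"""Assemble training data (fragment crops, tiles, bags) from slides.

Records unify on-disk cohorts (a directory written by
:func:`cervicad.phantom.generate_dataset`) and in-memory PhantomSlides,
so the same builders serve the CLI, the tests and the acceptance run.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .centerline import Tile, extract_centerline, extract_tiles, sample_tile_centers
from .labels import OTHERS, label_name
from .slide_io import (Box, Region, SlideImage, crop_and_resize, detect_fragments,
                       otsu_tissue_mask, read_annotations, read_mask, warp_mask_to_crop)

__all__ = ["SlideRecord", "records_from_dir", "records_from_phantoms",
           "build_segmentation_pairs", "build_tile_dataset"]


@dataclasses.dataclass
class SlideRecord:
    slide_id: str
    slide: SlideImage
    mask: np.ndarray          # level-0 ground-truth/predicted epithelium mask
    regions: list[Region]
    label: str


def records_from_dir(data_dir) -> list[SlideRecord]:
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        slide = SlideImage.from_file(data_dir / row["path"])
        mask = read_mask(data_dir / row["mask_path"])
        regions = read_annotations(data_dir / row["annotations_path"])
        records.append(SlideRecord(str(row["slide_id"]), slide, mask, regions, str(row["label"])))
    return records


def records_from_phantoms(phantoms, ids=None) -> list[SlideRecord]:
    records = []
    for i, ph in enumerate(phantoms):
        slide_id = ids[i] if ids is not None else f"slide_{i:04d}"
        regions = [Region(poly, label_name(grade)) for poly, grade in ph.region_labels]
        records.append(SlideRecord(slide_id, SlideImage(ph.image), ph.epithelium_mask,
                                   regions, label_name(ph.slide_label)))
    return records


def build_segmentation_pairs(records, crop_size: int = 256,
                             min_fragment_area_frac: float = 0.0005,
                             closing_radius: int = 5,
                             overview_max_side: int = 2048):
    """(FragmentCrop, crop-space mask) pairs via Otsu fragment detection.

    Negative fragments (no epithelium) are kept: the segmenter must learn
    to return empty masks on them.
    """
    pairs = []
    for rec in records:
        overview, down = rec.slide.overview(overview_max_side)
        tissue = otsu_tissue_mask(overview)
        boxes = detect_fragments(tissue, min_area=min_fragment_area_frac * tissue.size,
                                 closing_radius=closing_radius)
        w, h = rec.slide.dimensions
        for box_ov in boxes:
            box = Box(int(box_ov.x0 * down), int(box_ov.y0 * down),
                      min(int(np.ceil(box_ov.x1 * down)), w),
                      min(int(np.ceil(box_ov.y1 * down)), h))
            if box.area <= 0:
                continue
            crop = crop_and_resize(rec.slide, box, size=crop_size)
            pairs.append((crop, warp_mask_to_crop(crop, rec.mask)))
    return pairs


def build_tile_dataset(records, tile_size: int = 512, tile_interval: float = 256.0,
                       magnification: float = 20.0, min_skeleton_length: int = 10
                       ) -> tuple[pd.DataFrame, list[Tile], dict]:
    """Centerline tiles from ground-truth masks, plus annotations per slide.

    Returns (manifest, tiles, annotations) ready for
    :func:`cervicad.mil.build_bags`. "Others" slides contribute no tiles.
    """
    rows, tiles, annotations = [], [], {}
    for rec in records:
        rows.append({"slide_id": rec.slide_id, "label": rec.label})
        annotations[rec.slide_id] = rec.regions
        if rec.label == OTHERS or not rec.mask.any():
            continue
        interval_level0 = tile_interval * rec.slide.base_magnification / magnification
        for eid, line in enumerate(extract_centerline(rec.mask, min_length=min_skeleton_length)):
            centers = sample_tile_centers(line, interval=interval_level0)
            tiles.extend(extract_tiles(rec.slide, centers, size=tile_size,
                                       magnification=magnification,
                                       slide_id=rec.slide_id, epithelium_id=eid))
    return pd.DataFrame(rows), tiles, annotations
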