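"""Ground-truth-backed stand-in models for pipeline testing.

These plug into :func:`cervicad.pipeline.diagnose_slide` in place of
trained models, so the deterministic plumbing (fragmentation, centerline
tiling, worst-tile aggregation, the "others" rule) can be verified in
isolation from learning.
"""

from __future__ import annotations

import numpy as np

from .labels import OrdinalLabel
from .slide_io import FragmentCrop, points_in_polygon, warp_mask_to_crop

__all__ = ["OracleSegmenter", "OracleClassifier"]


class OracleSegmenter:
    """Returns the phantom's ground-truth epithelium mask, warped into
    whatever crop the pipeline asks about."""

    def __init__(self, level0_mask: np.ndarray):
        self.level0_mask = np.asarray(level0_mask).astype(bool)

    def segment(self, crop: FragmentCrop) -> np.ndarray:
        return warp_mask_to_crop(crop, self.level0_mask)


class OracleClassifier:
    """One-hot tile probabilities from the phantom's region annotations.

    A tile takes the grade of the polygon containing its center; a tile
    inside no polygon (a few px at ribbon ends fall outside the inset
    annotation rings) takes the grade of the nearest polygon.
    """

    def __init__(self, regions_by_slide: dict):
        # slide_id -> list of (polygon (N,2) xy, OrdinalLabel)
        self.regions_by_slide = regions_by_slide

    def _grade(self, slide_id: str, center) -> OrdinalLabel:
        regions = self.regions_by_slide.get(slide_id, [])
        if not regions:
            return OrdinalLabel.NNEO
        pt = np.asarray([[center[0] + 0.5, center[1] + 0.5]], dtype=float)
        for poly, grade in regions:
            if points_in_polygon(pt, poly)[0]:
                return OrdinalLabel(grade)
        dists = [np.min(np.linalg.norm(np.asarray(poly) - pt, axis=1)) for poly, _ in regions]
        return OrdinalLabel(regions[int(np.argmin(dists))][1])

    def predict_proba_tiles(self, tiles) -> np.ndarray:
        probs = np.zeros((len(tiles), 3))
        for i, tile in enumerate(tiles):
            probs[i, int(self._grade(tile.slide_id, tile.center)) - 1] = 1.0
        return probs
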