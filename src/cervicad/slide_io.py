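"""Slide abstraction, tissue-fragment detection and annotation I/O.

Coordinate conventions used everywhere in the package:

* 0-based, (x = column, y = row);
* boxes are half-open ``[x0, x1) x [y0, y1)`` in level-0 pixels;
* pixel ``(r, c)`` covers the unit square ``[c, c+1) x [r, r+1)`` and its
  center sits at ``(c + 0.5, r + 0.5)`` -- polygon rasterisation and
  point-in-polygon tests are even-odd on these centers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import NamedTuple, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, transform

from .labels import UNCERTAIN

__all__ = [
    "Box",
    "SlideImage",
    "FragmentCrop",
    "Region",
    "otsu_tissue_mask",
    "detect_fragments",
    "crop_and_resize",
    "warp_mask_to_crop",
    "unwarp_mask_to_level0",
    "read_mask",
    "write_mask",
    "read_annotations",
    "write_annotations",
    "rasterize_polygons",
    "points_in_polygon",
]


class Box(NamedTuple):
    """Half-open level-0 pixel box [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height


def _halve(img: np.ndarray) -> np.ndarray:
    """Exact 2x block-mean downsample, edge-padding odd dimensions."""
    h, w = img.shape[:2]
    pad_h, pad_w = h % 2, w % 2
    if pad_h or pad_w:
        pads = ((0, pad_h), (0, pad_w)) + ((0, 0),) * (img.ndim - 2)
        img = np.pad(img, pads, mode="edge")
    h, w = img.shape[:2]
    blocks = img.reshape(h // 2, 2, w // 2, 2, *img.shape[2:]).astype(np.float32)
    out = blocks.mean(axis=(1, 3))
    return out.astype(np.uint8) if img.dtype == np.uint8 else out


class SlideImage:
    """An RGB slide with a magnification pyramid (level 0 = 40x).

    Backed by a plain array (PNG or TIFF); further levels are computed by
    repeated 2x block averaging, so ``level_downsamples`` is
    ``[1, 2, 4, ...]``.
    """

    def __init__(self, image: np.ndarray, base_magnification: float = 40.0, n_levels: int | None = None):
        image = np.asarray(image)
        if image.ndim == 2:
            image = np.stack([image] * 3, axis=-1)
        if image.ndim != 3 or image.shape[2] < 3:
            raise ValueError("slide image must be RGB")
        image = np.ascontiguousarray(image[..., :3])
        if image.dtype != np.uint8:
            image = np.clip(image, 0, 255).astype(np.uint8)
        self.base_magnification = float(base_magnification)
        if n_levels is None:
            n_levels = 1
            side = min(image.shape[:2])
            while side // (2**n_levels) >= 256:
                n_levels += 1
        self._levels = [image]
        for _ in range(1, n_levels):
            self._levels.append(_halve(self._levels[-1]))
        self.level_downsamples = [float(2**i) for i in range(n_levels)]

    @classmethod
    def from_file(cls, path, base_magnification: float = 40.0) -> "SlideImage":
        return cls(iio.imread(Path(path)), base_magnification=base_magnification)

    @property
    def n_levels(self) -> int:
        return len(self._levels)

    @property
    def dimensions(self) -> tuple[int, int]:
        """(width, height) at level 0."""
        h, w = self._levels[0].shape[:2]
        return w, h

    def level_array(self, level: int) -> np.ndarray:
        return self._levels[level]

    def level_for_magnification(self, magnification: float) -> int:
        """Pyramid level whose downsample matches base/magnification."""
        target = self.base_magnification / magnification
        downs = np.asarray(self.level_downsamples)
        level = int(np.argmin(np.abs(downs - target)))
        return level

    def read_region(self, level: int, x: int, y: int, width: int, height: int,
                    pad_value: int = 255) -> tuple[np.ndarray, bool]:
        """Read a box given in *level* coordinates.

        Regions crossing the image border are padded with white; the
        returned flag reports whether any padding occurred.
        """
        arr = self._levels[level]
        h, w = arr.shape[:2]
        x0, y0 = int(x), int(y)
        x1, y1 = x0 + int(width), y0 + int(height)
        sx0, sy0 = max(x0, 0), max(y0, 0)
        sx1, sy1 = min(x1, w), min(y1, h)
        if sx0 >= sx1 or sy0 >= sy1:
            return np.full((height, width, 3), pad_value, dtype=np.uint8), True
        out = np.full((height, width, 3), pad_value, dtype=np.uint8)
        out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = arr[sy0:sy1, sx0:sx1]
        padded = (sx0 != x0) or (sy0 != y0) or (sx1 != x1) or (sy1 != y1)
        return out, padded

    def overview(self, max_side: int = 2048) -> tuple[np.ndarray, float]:
        """Smallest pyramid level with max side <= max_side, and its downsample."""
        for level, arr in enumerate(self._levels):
            if max(arr.shape[:2]) <= max_side:
                return arr, self.level_downsamples[level]
        arr = self._levels[-1]
        down = self.level_downsamples[-1]
        while max(arr.shape[:2]) > max_side:
            arr = _halve(arr)
            down *= 2
        return arr, down


def otsu_tissue_mask(image: np.ndarray) -> np.ndarray:
    """Tissue mask by Otsu's threshold on the grayscale channel.

    Tissue is darker than the glass background, so foreground = pixels
    below the threshold. A constant image yields an empty mask.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        gray = image[..., :3].astype(np.float32) @ np.array([0.2125, 0.7154, 0.0721], dtype=np.float32)
    else:
        gray = image.astype(np.float32)
    if np.ptp(gray) == 0:
        return np.zeros(gray.shape, dtype=bool)
    g8 = gray.astype(np.uint8)
    thresh = filters.threshold_otsu(g8)
    # threshold_otsu's convention puts foreground above the threshold;
    # tissue is the dark side, so foreground = at or below it
    return g8 <= thresh


def detect_fragments(mask: np.ndarray, min_area: int = 0, closing_radius: int = 5) -> list[Box]:
    """Bounding boxes of tissue fragments (connected components).

    The mask is morphologically closed first to bridge small gaps, then
    components with area >= min_area are boxed and sorted by (y0, x0).
    """
    mask = np.asarray(mask).astype(bool)
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    labeled, n = ndi.label(mask)
    boxes = []
    for sl in ndi.find_objects(labeled):
        if sl is None:
            continue
        area = int((labeled[sl] > 0).sum())
        if area < min_area:
            continue
        ys, xs = sl
        boxes.append(Box(xs.start, ys.start, xs.stop, ys.stop))
    boxes.sort(key=lambda b: (b.y0, b.x0))
    return boxes


@dataclasses.dataclass
class FragmentCrop:
    """One tissue fragment, padded to square and resized for segmentation.

    ``scale_x``/``scale_y`` map crop pixels back to level-0 pixels; the
    white padding applied before resizing is centered, so the transform is
    crop -> padded -> box -> level 0.
    """

    image: np.ndarray
    source_box: Box
    scale_x: float
    scale_y: float
    pad_left: int = 0
    pad_top: int = 0

    def to_level0(self, px: float, py: float) -> tuple[float, float]:
        """Map a crop-pixel coordinate to level-0 pixels."""
        x = self.source_box.x0 - self.pad_left + px * self.scale_x
        y = self.source_box.y0 - self.pad_top + py * self.scale_y
        return x, y

    def from_level0(self, x: float, y: float) -> tuple[float, float]:
        px = (x - self.source_box.x0 + self.pad_left) / self.scale_x
        py = (y - self.source_box.y0 + self.pad_top) / self.scale_y
        return px, py


def crop_and_resize(slide: SlideImage, box: Box, size: int = 1024) -> FragmentCrop:
    """Crop a level-0 box, pad to square with white, resize to size x size."""
    if box.area <= 0:
        raise ValueError(f"degenerate box {box}")
    w, h = slide.dimensions
    if box.x0 < 0 or box.y0 < 0 or box.x1 > w or box.y1 > h:
        raise ValueError(f"box {box} outside level-0 bounds {w}x{h}")
    region, _ = slide.read_region(0, box.x0, box.y0, box.width, box.height)
    side = max(box.width, box.height)
    pad_left = (side - box.width) // 2
    pad_top = (side - box.height) // 2
    padded = np.full((side, side, 3), 255, dtype=np.uint8)
    padded[pad_top:pad_top + box.height, pad_left:pad_left + box.width] = region
    resized = transform.resize(padded, (size, size), order=1, anti_aliasing=side > size,
                               preserve_range=True).astype(np.uint8)
    scale = side / size
    return FragmentCrop(resized, box, scale, scale, pad_left=pad_left, pad_top=pad_top)


def warp_mask_to_crop(crop: FragmentCrop, level0_mask: np.ndarray) -> np.ndarray:
    """Transform a level-0 binary mask into the crop's pixel grid (nearest)."""
    box = crop.source_box
    region = np.zeros((box.height, box.width), dtype=bool)
    sub = np.asarray(level0_mask)[box.y0:box.y1, box.x0:box.x1].astype(bool)
    region[:sub.shape[0], :sub.shape[1]] = sub
    side = max(box.width, box.height)
    padded = np.zeros((side, side), dtype=bool)
    padded[crop.pad_top:crop.pad_top + box.height, crop.pad_left:crop.pad_left + box.width] = region
    size = crop.image.shape[0]
    return transform.resize(padded.astype(np.uint8), (size, size), order=0,
                            preserve_range=True, anti_aliasing=False).astype(bool)


def unwarp_mask_to_level0(crop: FragmentCrop, crop_mask: np.ndarray, canvas_shape: tuple[int, int]) -> np.ndarray:
    """Map a crop-space mask back onto a level-0 canvas (nearest)."""
    box = crop.source_box
    side = max(box.width, box.height)
    padded = transform.resize(np.asarray(crop_mask).astype(np.uint8), (side, side), order=0,
                              preserve_range=True, anti_aliasing=False).astype(bool)
    region = padded[crop.pad_top:crop.pad_top + box.height, crop.pad_left:crop.pad_left + box.width]
    canvas = np.zeros(canvas_shape, dtype=bool)
    canvas[box.y0:box.y1, box.x0:box.x1] = region
    return canvas


# ---------------------------------------------------------------------------
# Masks and annotations on disk


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a {0, 255} single-channel PNG."""
    arr = (np.asarray(mask).astype(bool) * 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


@dataclasses.dataclass
class Region:
    """A labelled annotation polygon in level-0 (x, y) coordinates."""

    polygon: np.ndarray  # (N, 2) array of (x, y)
    label: str

    def __post_init__(self):
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon must be an (N>=3, 2) array of (x, y)")
        self.polygon = poly


def write_annotations(path, regions: Sequence[Region]) -> None:
    """Write regions as a GeoJSON FeatureCollection (closed rings)."""
    features = []
    for region in regions:
        ring = region.polygon.tolist()
        if ring[0] != ring[-1]:
            ring = ring + [ring[0]]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {"label": region.label},
        })
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))


def read_annotations(path) -> list[Region]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed GeoJSON in {path}: {exc}") from None
    if payload.get("type") != "FeatureCollection" or "features" not in payload:
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    regions = []
    for feat in payload["features"]:
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValueError(f"unsupported geometry {geom.get('type')!r} in {path}")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        label = str((feat.get("properties") or {}).get("label", UNCERTAIN))
        regions.append(Region(ring, label))
    return regions


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, vectorised over points."""
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    px, py = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        crosses = (y0 > py) != (y1 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (px < x_at)
    return inside


def rasterize_polygons(polygons: Sequence[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    """Rasterise polygons onto a grid: even-odd fill, pixel-center inclusion.

    Each polygon ring is filled independently and the results OR-combined.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    if not polygons:
        return mask
    for poly in polygons:
        poly = np.asarray(poly, dtype=float)
        # restrict the test to the polygon's bounding box for speed
        x_min = max(int(np.floor(poly[:, 0].min())), 0)
        x_max = min(int(np.ceil(poly[:, 0].max())), w)
        y_min = max(int(np.floor(poly[:, 1].min())), 0)
        y_max = min(int(np.ceil(poly[:, 1].max())), h)
        if x_min >= x_max or y_min >= y_max:
            continue
        sub_cols, sub_rows = np.meshgrid(np.arange(x_min, x_max), np.arange(y_min, y_max))
        pts = np.stack([sub_cols.ravel() + 0.5, sub_rows.ravel() + 0.5], axis=1)
        inside = points_in_polygon(pts, poly).reshape(y_max - y_min, x_max - x_min)
        mask[y_min:y_max, x_min:x_max] |= inside
    return mask
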