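"""Synthetic phantom slides with ground truth for every pipeline stage.

A phantom slide emulates the geometry of a scanned LEEP/cone tissue
section: one to four tissue fragments (elliptical stromal blobs on a
bright glass background), each optionally carrying a thin epithelium
ribbon that hugs part of the fragment edge. The ribbon follows a smooth
randomised curve with thickness varying +-25% along its length, so
centerline extraction is exercised on curved, variable-width shapes.

Grade is encoded as nuclear texture, mimicking how dysplasia is actually
graded -- by how far basal/parabasal-like cell proliferation extends
through the epithelial thickness:

* NNeo   -- sparse dark nuclei confined to a thin basal band;
* LSIL   -- dense nuclei in the basal third plus perinuclear vacuole
            rings (koilocyte proxy) above it;
* HSIL   -- dense nuclei across the full ribbon thickness.

Non-representative ("others") slides contain fragments but zero ribbon
pixels. The generator keeps its internal band map (basal / middle /
upper third), nucleus mask, fragment boxes and ribbon curves as ground
truth for the oracles used in tests.

Photo-realistic H&E rendering and stain variation are out of scope.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .labels import ALL_CLASS_NAMES, OTHERS, OrdinalLabel, label_name, parse_label
from .slide_io import Box, Region, rasterize_polygons, write_annotations, write_mask

__all__ = [
    "PhantomConfig",
    "PhantomSlide",
    "generate_phantom_slide",
    "generate_dataset",
    "largest_remainder_counts",
]

# Base colours (R, G, B): glass, stroma, epithelium cytoplasm, nuclei.
# Tissue luma sits well below the glass background (as in scanned H&E),
# so Otsu's threshold falls in the glass/tissue valley rather than the
# nuclei/cytoplasm one.
_GLASS = np.array([245, 245, 245], dtype=float)
_STROMA = np.array([225, 160, 180], dtype=float)
_EPITHELIUM = np.array([185, 160, 210], dtype=float)
_NUCLEUS = np.array([72, 52, 128], dtype=float)

#: nuclei per 1000 ribbon pixels, keyed by (grade, band); bands are the
#: basal / middle / upper thirds of the ribbon thickness.
_NUCLEUS_DENSITY = {
    OrdinalLabel.NNEO: {"basal": 5.0, "middle": 0.2, "upper": 0.2},
    OrdinalLabel.LSIL: {"basal": 16.0, "middle": 0.8, "upper": 0.8},
    OrdinalLabel.HSIL: {"basal": 16.0, "middle": 16.0, "upper": 16.0},
}
_VACUOLE_DENSITY = 4.0  # LSIL only, middle+upper bands (koilocyte proxy)


@dataclasses.dataclass
class PhantomConfig:
    """Study conditions for phantom generation.

    Defaults describe a slide-scale phantom: a 2048x1536 canvas with up
    to four fragments and ribbons 40-90 px thick at level 0 (40x).
    """

    image_size: tuple[int, int] = (2048, 1536)  # (width, height)
    fragments_per_slide: tuple[int, int] = (1, 4)
    ribbon_thickness: tuple[float, float] = (40.0, 90.0)
    class_mix: dict = dataclasses.field(default_factory=lambda: {
        "NNeo": 0.3, "LSIL": 0.4, "HSIL": 0.2, OTHERS: 0.1})
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions sum to {total}, not 1")
        unknown = set(self.class_mix) - set(ALL_CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown classes in class_mix: {unknown}")
        lo, hi = self.ribbon_thickness
        if not (0 < lo <= hi):
            raise ValueError("ribbon_thickness must be a positive (lo, hi) range")


@dataclasses.dataclass
class PhantomSlide:
    """A generated slide plus every piece of ground truth about it."""

    image: np.ndarray            # (H, W, 3) uint8
    epithelium_mask: np.ndarray  # (H, W) bool
    region_labels: list          # list of (polygon (N,2) xy, OrdinalLabel)
    slide_label: object          # OrdinalLabel or OTHERS
    manifest_row: dict
    # --- generator-internal ground truth for oracles ---
    band_map: np.ndarray         # (H, W) uint8: 0 bg, 1 basal, 2 middle, 3 upper
    nucleus_mask: np.ndarray     # (H, W) bool, dense-nucleus pixels
    fragment_boxes: list         # list[Box]
    ribbon_paths: list           # list of (points (N,2) xy, half_thickness (N,))


def largest_remainder_counts(n: int, mix: dict) -> dict:
    """Apportion n items to classes by largest-remainder rounding.

    Ties in the fractional parts are broken by the canonical class order,
    so manifests are reproducible.
    """
    order = [c for c in ALL_CLASS_NAMES if c in mix]
    exact = {c: n * mix[c] for c in order}
    counts = {c: int(np.floor(exact[c])) for c in order}
    short = n - sum(counts.values())
    by_remainder = sorted(order, key=lambda c: (-(exact[c] - counts[c]), order.index(c)))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


def _smooth_noise(rng, n: int, sigma: float) -> np.ndarray:
    """Zero-mean smooth 1-D noise with unit max-abs scale."""
    raw = gaussian_filter1d(rng.normal(size=n), sigma, mode="wrap")
    peak = np.abs(raw).max()
    return raw / peak if peak > 0 else raw


def _fragment_cells(width: int, height: int, n: int, rng) -> list[tuple[float, float, float, float]]:
    """Non-overlapping placement cells: (cx, cy, cell_w, cell_h) per fragment."""
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    cw, ch = width / cols, height / rows
    cells = [(c * cw + cw / 2, r * ch + ch / 2, cw, ch)
             for r in range(rows) for c in range(cols)]
    idx = rng.permutation(len(cells))[:n]
    return [cells[i] for i in sorted(idx)]


def _draw_disk(img: np.ndarray, masks: Sequence[np.ndarray], cy: int, cx: int,
               radius: int, color: np.ndarray) -> None:
    h, w = img.shape[:2]
    y0, y1 = max(cy - radius, 0), min(cy + radius + 1, h)
    x0, x1 = max(cx - radius, 0), min(cx + radius + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0 - cy:y1 - cy, x0 - cx:x1 - cx]
    disk = yy * yy + xx * xx <= radius * radius
    img[y0:y1, x0:x1][disk] = color
    for m in masks:
        m[y0:y1, x0:x1][disk] = True


def _segment_polygons(segment_mask: np.ndarray, erosion: int = 2,
                      min_len: int = 12) -> list[np.ndarray]:
    """Polygons strictly inside a ribbon-segment mask (for annotations)."""
    core = morphology.erosion(segment_mask, morphology.disk(erosion))
    polys = []
    for contour in measure.find_contours(core.astype(float), 0.5):
        if len(contour) < min_len:
            continue
        ring = contour[::4]
        # (row, col) index space -> (x, y) with pixel centers at (c+.5, r+.5)
        polys.append(np.stack([ring[:, 1] + 0.5, ring[:, 0] + 0.5], axis=1))
    return polys


def generate_phantom_slide(config: PhantomConfig, slide_label, seed: int,
                           segment_labels: Sequence[OrdinalLabel] | None = None) -> PhantomSlide:
    """Generate one phantom slide. Bit-identical for identical arguments.

    ``segment_labels`` optionally splits the first fragment's ribbon into
    contiguous arc segments with the given grades (e.g. an HSIL segment
    injected into an otherwise LSIL ribbon); the worst segment grade must
    equal ``slide_label``.
    """
    rng = np.random.default_rng(seed)
    width, height = config.image_size
    is_others = slide_label == OTHERS
    if not is_others:
        slide_label = OrdinalLabel(slide_label)
        if segment_labels is not None:
            segment_labels = [OrdinalLabel(s) for s in segment_labels]
            if max(segment_labels) != slide_label:
                raise ValueError("worst segment label must equal the slide label")
    elif segment_labels is not None:
        raise ValueError("'others' slides have no ribbon segments")

    image = np.tile(_GLASS, (height, width, 1))
    epi_mask = np.zeros((height, width), dtype=bool)
    band_map = np.zeros((height, width), dtype=np.uint8)
    nucleus_mask = np.zeros((height, width), dtype=bool)
    regions: list[tuple[np.ndarray, OrdinalLabel]] = []
    boxes: list[Box] = []
    ribbon_paths: list[tuple[np.ndarray, np.ndarray]] = []

    lo, hi = config.fragments_per_slide
    n_frags = int(rng.integers(lo, hi + 1))
    cells = _fragment_cells(width, height, n_frags, rng)

    # Per-fragment ribbon grades: the first fragment carries the slide
    # grade, the rest draw uniformly from grades no worse than it, so the
    # slide label is always the maximum grade present.
    frag_grades: list = []
    for k in range(n_frags):
        if is_others:
            frag_grades.append(None)
        elif k == 0:
            frag_grades.append(slide_label)
        else:
            frag_grades.append(OrdinalLabel(int(rng.integers(1, int(slide_label) + 1))))

    for k, (cx, cy, cw, ch) in enumerate(cells):
        ax = rng.uniform(0.32, 0.42) * cw   # semi-axes
        ay = rng.uniform(0.32, 0.42) * ch
        theta = rng.uniform(0, np.pi)
        minor = 2 * min(ax, ay)
        if not is_others and config.ribbon_thickness[1] >= minor:
            raise ValueError(
                f"ribbon thickness up to {config.ribbon_thickness[1]} px does not fit "
                f"a fragment with minor axis {minor:.0f} px; enlarge image_size or "
                "thin the ribbon")
        cosa, sina = np.cos(theta), np.sin(theta)

        # stroma blob with a slightly wobbly boundary
        n_ang = 720
        ang = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
        wobble = 1.0 + 0.06 * _smooth_noise(rng, n_ang, 40)
        ex = ax * np.cos(ang) * wobble
        ey = ay * np.sin(ang) * wobble
        bx = cx + ex * cosa - ey * sina
        by = cy + ex * sina + ey * cosa
        # fill with a decimated ring: 180 vertices are indistinguishable at
        # pixel scale but rasterise 4x faster
        frag_mask = rasterize_polygons([np.stack([bx, by], axis=1)[::4]], (height, width))
        ys, xs = np.nonzero(frag_mask)
        if len(ys) == 0:
            continue
        boxes.append(Box(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1))

        texture = gaussian_filter(rng.normal(size=(height, width)), 12)
        peak = np.abs(texture).max()
        texture = texture / peak if peak > 0 else texture
        stroma = _STROMA[None, None, :] + 14 * texture[..., None]
        image[frag_mask] = stroma[frag_mask]

        if is_others:
            continue

        grade = frag_grades[k]
        # ----- ribbon curve along part of the fragment edge -----
        span = rng.uniform(2.2, 4.2)           # arc length in radians
        start = rng.uniform(0, 2 * np.pi)
        n_pts = max(int(span * max(ax, ay)), 64)
        t = start + np.linspace(0, span, n_pts)
        radial = 0.90 + 0.05 * _smooth_noise(rng, n_pts, n_pts / 8)
        px = ax * np.cos(t) * radial
        py = ay * np.sin(t) * radial
        curve = np.stack([cx + px * cosa - py * sina, cy + px * sina + py * cosa], axis=1)
        # outward normal = radial direction in the rotated frame
        nx = np.cos(t) * cosa * ay - np.sin(t) * sina * ax
        ny = np.cos(t) * sina * ay + np.sin(t) * cosa * ax
        norms = np.stack([nx, ny], axis=1)
        norms /= np.linalg.norm(norms, axis=1, keepdims=True)

        base_thick = rng.uniform(*config.ribbon_thickness)
        half = 0.5 * base_thick * (1.0 + 0.25 * _smooth_noise(rng, n_pts, n_pts / 6))
        half = np.clip(half, 2.0, None)
        ribbon_paths.append((curve, half.copy()))

        # segment assignment along the arc
        if k == 0 and segment_labels is not None:
            seg_of_pt = np.minimum(
                (np.arange(n_pts) * len(segment_labels)) // n_pts, len(segment_labels) - 1)
            seg_grades = list(segment_labels)
        else:
            seg_of_pt = np.zeros(n_pts, dtype=int)
            seg_grades = [grade]

        # rasterise the ribbon: nearest curve sample decides membership,
        # thickness and depth through the thickness
        pad = int(half.max()) + 3
        x0 = max(int(curve[:, 0].min()) - pad, 0)
        x1 = min(int(curve[:, 0].max()) + pad, width)
        y0 = max(int(curve[:, 1].min()) - pad, 0)
        y1 = min(int(curve[:, 1].max()) + pad, height)
        gy, gx = np.mgrid[y0:y1, x0:x1]
        pts = np.stack([gx.ravel() + 0.0, gy.ravel() + 0.0], axis=1)
        tree = cKDTree(curve)
        dist, idx = tree.query(pts, workers=1)
        inside = dist <= half[idx]
        if not inside.any():
            continue
        sel = np.nonzero(inside)[0]
        rel = pts[sel] - curve[idx[sel]]
        signed = np.einsum("ij,ij->i", rel, norms[idx[sel]])
        depth = np.clip((signed / half[idx[sel]] + 1.0) / 2.0, 0.0, 1.0)

        rows = gy.ravel()[sel]
        cols_ = gx.ravel()[sel]
        epi_mask[rows, cols_] = True
        band = np.where(depth < 1 / 3, 1, np.where(depth < 2 / 3, 2, 3)).astype(np.uint8)
        band_map[rows, cols_] = band

        cyto = _EPITHELIUM[None, :] + rng.normal(0, 4, size=(len(sel), 3))
        image[rows, cols_] = cyto

        # per-segment texture
        seg_ids = seg_of_pt[idx[sel]]
        band_names = {1: "basal", 2: "middle", 3: "upper"}
        for seg_id, seg_grade in enumerate(seg_grades):
            in_seg = seg_ids == seg_id
            seg_mask = np.zeros((height, width), dtype=bool)
            seg_mask[rows[in_seg], cols_[in_seg]] = True
            for b in (1, 2, 3):
                bsel = in_seg & (band == b)
                n_px = int(bsel.sum())
                if n_px == 0:
                    continue
                if seg_grade == OrdinalLabel.NNEO and b == 1:
                    # confine NNeo nuclei to a thin basal band
                    bsel = bsel & (depth < 0.15)
                    n_px = int(bsel.sum())
                dens = _NUCLEUS_DENSITY[seg_grade][band_names[b]]
                n_nuc = rng.poisson(dens * n_px / 1000.0)
                if n_nuc > 0:
                    pick = rng.choice(np.nonzero(bsel)[0], size=min(n_nuc, n_px), replace=False)
                    # dysplastic nuclei are enlarged relative to the normal
                    # basal layer (nuclear enlargement under HPV)
                    r_lo, r_hi = (2, 4) if seg_grade == OrdinalLabel.NNEO else (3, 6)
                    for j in pick:
                        r_nuc = int(rng.integers(r_lo, r_hi))
                        col = _NUCLEUS + rng.normal(0, 8, size=3)
                        _draw_disk(image, [nucleus_mask], int(rows[j]), int(cols_[j]), r_nuc, col)
                if seg_grade == OrdinalLabel.LSIL and b in (2, 3):
                    n_vac = rng.poisson(_VACUOLE_DENSITY * n_px / 1000.0)
                    for _ in range(n_vac):
                        j = int(rng.choice(np.nonzero(in_seg & (band == b))[0]))
                        r_vac = int(rng.integers(4, 7))
                        _draw_disk(image, [], int(rows[j]), int(cols_[j]), r_vac,
                                   _NUCLEUS + rng.normal(0, 8, size=3))
                        _draw_disk(image, [], int(rows[j]), int(cols_[j]), r_vac - 2,
                                   np.array([242, 238, 244]) + rng.normal(0, 3, size=3))
            for poly in _segment_polygons(seg_mask):
                regions.append((poly, seg_grade))

    image += rng.normal(0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    return PhantomSlide(
        image=image,
        epithelium_mask=epi_mask,
        region_labels=regions,
        slide_label=OTHERS if is_others else slide_label,
        manifest_row={"slide_id": f"phantom_{seed:08d}",
                      "label": label_name(OTHERS if is_others else slide_label),
                      "seed": int(seed)},
        band_map=band_map,
        nucleus_mask=nucleus_mask,
        fragment_boxes=boxes,
        ribbon_paths=ribbon_paths,
    )


def generate_dataset(n_slides: int, config: PhantomConfig, out_dir) -> pd.DataFrame:
    """Write a phantom cohort to disk and return its manifest.

    Class counts follow largest-remainder apportionment of
    ``config.class_mix``; each slide draws its own seed from a master
    sequence keyed by ``config.seed``, so re-runs are bit-identical.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = largest_remainder_counts(n_slides, config.class_mix)
    labels = [c for c in ALL_CLASS_NAMES if c in counts for _ in range(counts[c])]
    master = np.random.default_rng(config.seed)
    labels = [labels[i] for i in master.permutation(len(labels))]
    seeds = np.random.SeedSequence(config.seed).generate_state(n_slides) % (2**31)

    rows = []
    for i, (lab, seed) in enumerate(zip(labels, seeds)):
        slide = generate_phantom_slide(config, parse_label(lab), int(seed))
        slide_id = f"slide_{i:04d}"
        img_path = out_dir / f"{slide_id}.png"
        mask_path = out_dir / f"{slide_id}_mask.png"
        ann_path = out_dir / f"{slide_id}.geojson"
        import imageio.v3 as iio

        iio.imwrite(img_path, slide.image)
        write_mask(mask_path, slide.epithelium_mask)
        write_annotations(ann_path, [Region(poly, label_name(grade))
                                     for poly, grade in slide.region_labels])
        rows.append({"slide_id": slide_id, "path": img_path.name, "label": lab,
                     "seed": int(seed), "mask_path": mask_path.name,
                     "annotations_path": ann_path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
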