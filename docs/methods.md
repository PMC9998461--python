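# Methods

This note documents the models, conventions and design choices behind
`cervicad`, in the spirit of a model-description appendix: what is
computed, under which assumptions, and what the synthetic experiments do
and do not demonstrate.

## Problem and pipeline

Cervical dysplasia is graded on the squamous epithelium of H&E-stained
slides with the ordered two-tier scale NNeo (1) < LSIL (2) < HSIL (3);
slides without exocervical squamous epithelium are "others" and sit
outside the ordinal scale. The pipeline mirrors how a pathologist works:
find the tissue, find the epithelium, look along it, grade the worst
region.

Inference on a slide proceeds: Otsu tissue mask on a downsampled
overview → connected-component fragment boxes (after morphological
closing, 5-px disk; minimum area 0.05% of the overview) → per-fragment
U-Net epithelium mask, merged at level 0 → skeleton centerline per
epithelium → 512×512 tiles at 20× sampled along the centerline → tile
class probabilities → slide label = argmax class of the worst tile. A
slide whose merged epithelium mask is empty is labelled "others" before
any classification; this rule and the classifier are mutually exclusive
code paths. Over-segmented "others" slides (spurious epithelium found)
go through the classifier like any positive slide.

## Coordinate and evaluation conventions

* 0-based (x = column, y = row); boxes half-open; pixel (r, c) covers
  the unit square with center (c + 0.5, r + 0.5). Polygon rasterisation
  and point-in-polygon tests are even-odd on pixel centers, which makes
  an axis-aligned d×d polygon cover exactly d² pixels.
* Confusion matrices: rows = predicted, columns = actual.
* "Balanced accuracy" = unweighted mean of per-actual-class recall;
  "sensitivity", "precision", "F1" = support-weighted averages with
  actual-class supports (weighted sensitivity therefore equals micro
  accuracy, an identity the tests exploit). Excluding a class removes
  both its predicted row and its actual column, dropping from the
  evaluation any slide predicted as the excluded class.
* QWK is computed on integer counts over the three ordered grades with
  weights w(y, ŷ) = (y − ŷ)²/(n − 1)²; the expected matrix is the outer
  product of the marginals normalised to the matrix total. These
  conventions jointly reproduce every statistic of the reference tables
  to the printed two decimals (see `cervicad.experiments`).
* One worked detection number is reproducible only to ±0.01 percentage
  points from its printed counts (71.03 vs the recomputed 71.025); the
  acceptance test treats it as approximate.

## Segmentation model

A standard U-Net (double-conv blocks, 2×2 max-pool, transposed-conv
upsampling with skip concatenation, 1×1 sigmoid head), trained with
`L_s = BCE + DiceLoss`. The BCE term is averaged over pixels; the Dice
term uses whole-image sums with smoothing λ = 1 (so an empty prediction
against an empty target scores 0 loss), computed per image and averaged
over the batch. Probabilities are clamped to [1e-7, 1 − 1e-7] before the
logs, which are otherwise unbounded. The decision threshold is strict
(p > t, default t = 0.5): a maximally uncertain output (p ≡ 0.5) yields
an empty mask rather than full foreground. Input variants: RGB (3
channels), grayscale (Rec. 709 luma) or the HSV saturation channel.

Full-scale defaults follow the training conditions of the study this
package reimplements: 1024×1024 fragment crops, depth-4/64-filter U-Net,
Adam at 1e-4, batches of 4, 250 epochs, model selection by minimum
validation loss. The desk-scale tests use 256×256 crops and a
depth-2/8-filter U-Net at learning rate 3e-3 for ~10 epochs, which
reaches held-out Dice ≈ 0.8 on phantoms in a few CPU-minutes.

Non-square fragments are padded to square with white (centered) before
resizing, avoiding anisotropic distortion of the thin ribbon; the
recorded scale/pad transform is exactly invertible, so predicted masks
map back to level-0 within a pixel.

## Centerline tiling

"Centerline" means the longest simple path of the morphological skeleton
(iterative thinning) of one epithelium component. The skeleton graph is
reduced to a BFS spanning tree and the classic double farthest-point
traversal finds the longest path (exact on trees; cycles are broken by
the spanning tree). Thinning stops about half the ribbon thickness short
of the ribbon tips, so both path ends are prolonged along their local
direction while they remain inside the mask; components whose path is
shorter than 10 points (e.g. a filled disk) are dropped.

Tile centers are emitted starting at the path's first point and then
whenever the cumulative |Δx| since the last emission reaches 256 px
(measured in 20× pixels, i.e. 512 level-0 px on a 40× scan — a 50%
overlap between neighbouring 512-px tiles). For a path whose overall
y-extent exceeds its x-extent the same rule is applied to |Δy|; a purely
x-based rule degenerates on vertical ribbons. Tiles are axis-aligned,
center-anchored, read from the pyramid level nearest 20×, padded white
at slide borders and flagged when padded.

## Ordinal MIL classifier

Bags: LS = all tiles of one slide (label = slide diagnosis), AE = tiles
of one annotated epithelial region (label = region grade), AT = single
annotated tiles. Tiles inside "uncertain" polygons never enter any bag;
"others" never enters training at all. The worst tile of a bag is the
one maximising the expected ordinal score E = Σ i·pᵢ, ties broken by
higher HSIL probability, then stable order.

Training alternates, per epoch: (i) an inference pass ranking every
LS/AE bag with the current model and selecting its worst tile, labelled
with the bag label; (ii) mini-batch gradient steps over the selected
tiles plus all AT tiles using the weighted-kappa loss L_c = 1 − κ. The
observed matrix accumulates probability mass (soft counts), which makes
the loss differentiable; on one-hot predictions it equals the
count-matrix κ exactly, a property enforced by test. The loss gradient
is the full Jacobian of the implemented expression (including the
dependence of marginals and total on the probabilities) and matches
finite differences to 1e-4. A batch with a single grade has no
chance-corrected signal: it is flagged degenerate (κ defined as 0) and
skipped. The checkpoint returned is the one maximising bag-level
validation balanced accuracy.

Two numerical aids matter for training from random initialisation:

* a small uniform mixing of the probabilities inside the loss
  (`prob_floor`, default 0.02) keeps gradients alive once the softmax
  saturates a class to ~0 probability;
* `warmup_epochs` of plain cross-entropy before the κ loss. The κ
  denominator (expected disagreement) grows when predicted marginals
  concentrate on the extreme grades, so a randomly initialised model
  descending on 1 − κ reliably reaches a two-class solution in which the
  middle grade is never the argmax — observed both on a separable linear
  probe and on phantom tiles. Started from a reasonable 3-class
  solution, the κ phase preserves and refines it. The reference training
  setup starts from pretrained (ImageNet) weights; the CE warmup is this
  package's analogue for randomly initialised backbones.

The backbone is a micro-CNN (conv-ReLU-pool blocks, global average
pooling, linear head, softmax) sized for CPU training; depth/width are
configurable. Tile tensors are standardised around the bright H&E
background ((x − 0.8)/0.25) so optimisation starts well-conditioned.

## Synthetic phantoms

`generate_phantom_slide` emulates the *geometry and weak-label
structure* of scanned LEEP/cone sections, not their appearance: 1–4
elliptical stromal fragments (low-frequency pink texture) on a bright
glass background; per fragment, optionally, an epithelium ribbon
following a smooth randomised curve along part of the fragment edge,
thickness drawn from 40–90 px (level 0) and varying ±25% along the arc.
Grade is encoded as nuclear texture via the depth of basal-like
proliferation: NNeo = sparse small nuclei confined to a thin basal band;
LSIL = dense enlarged nuclei in the basal third plus bright vacuole
rings above (koilocyte proxy); HSIL = dense enlarged nuclei through the
full thickness. "Others" slides have fragments but zero ribbon pixels.
Nucleus densities and radii were fixed once so that the grades are
clearly separable (a one-feature linear classifier separates NNeo from
HSIL tiles with >90% accuracy — the floor that guarantees the learning
tasks are solvable); they are not tuned to any particular model.

All randomness flows through one `numpy` generator per slide, seeded
from the slide's manifest entry, so cohorts are bit-reproducible.
Dataset class counts use largest-remainder apportionment of the
configured class mix (default NNeo/LSIL/HSIL/others =
0.30/0.40/0.20/0.10). Region annotations are polygons traced strictly
inside each ribbon segment (2-px erosion before contouring), so every
annotation rasterises inside the epithelium mask.

What phantom results do **not** show: robustness to stain variation,
scanner artefacts, real nuclear morphology, epithelium/stroma ambiguity,
or gigapixel-scale memory behaviour. Desk-scale metrics quantify the
correctness of the machinery, not expected clinical performance;
real-data accuracies from the original study (e.g. segmentation Dice
≈ 0.81, slide-level balanced accuracy ≈ 0.71) are reproducible only with
the proprietary slides and GPU-scale training and are out of scope here.

## Desk-scale problem sizes

Chosen once as the package's own study conditions: phantoms of 640×480
with a single fragment and 24–40-px ribbons (the slide-scale geometry
shrunk ~3×); segmentation on 40 training crops at 256×256 for 10 epochs;
classification on ~125 AT tiles (128-px tiles at 20×, 64-px inputs) for
40 epochs with a 25-epoch CE warmup; a 20-slide oracle-model cohort for
the end-to-end identity check. `scripts/acceptance.py` runs exactly
these, seeded from its `--seed`.

## Known limitations

* The NumPy networks are deliberately small; no augmentation, no
  normalisation layers, float32 only.
* The skeleton longest path is exact only for tree-shaped skeletons;
  loopy skeletons lose the loop closure (spanning-tree approximation).
* `sample_tile_centers` measures advance along one dominant axis, so a
  strongly C-shaped ribbon is sampled more densely where it runs against
  its dominant axis.
* Cohen-style κ on a degenerate (single-grade) batch is undefined;
  the package defines it as 0 with a flag rather than raising mid-epoch.
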