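# cervicad

Weakly-supervised computer-aided grading of cervical dysplasia on H&E
whole-slide images (WSI).

Cervical pre-cancer is graded on the squamous epithelium with a two-tier
system: non-neoplastic (NNeo), low-grade (LSIL) and high-grade (HSIL)
squamous intraepithelial lesions, with an extra bucket for
non-representative slides ("others") that contain no exocervical
epithelium at all. Grading hinges on how far basal/parabasal-like cell
proliferation extends through the epithelial thickness — the lower third
for LSIL, reaching the middle and upper thirds for HSIL. `cervicad`
implements a full slide-level pipeline for this problem, aimed at people
building or studying computational-pathology grading systems who want an
end-to-end, CPU-runnable reference implementation:

1. **Tissue detection** — Otsu thresholding of a slide overview locates
   tissue fragments; each fragment is cropped, padded to square and
   resized for segmentation.
2. **Epithelium segmentation** — a U-Net trained with the BCE-Dice loss

       L_s = BCE(y, ŷ) + 1 − (2·Σyŷ + λ) / (Σy + Σŷ + λ),  λ = 1,

   with RGB, grayscale or HSV-saturation input variants.
3. **Centerline tiling** — the epithelium mask is skeletonised; tiles of
   512×512 px at 20× magnification are sampled along the longest skeleton
   path at 256-px intervals of dominant-axis advance.
4. **Ordinal MIL classification** — slides (LS), annotated epithelia (AE)
   and annotated tiles (AT) form bags of tiles at three supervision
   levels. Each bag is represented by its *worst tile*, ranked by the
   expected value of the ordinal class distribution

       E(Ĉ) = Σᵢ i · p(Ĉ = C⁽ⁱ⁾),  i ∈ {1 (NNeo), 2 (LSIL), 3 (HSIL)},

   and the classifier is trained with the quadratic-weighted-kappa loss
   L_c = 1 − κ, where κ is computed from the observed matrix x, the
   expected matrix m (outer product of the marginals, matched in total)
   and weights w(y, ŷ) = (y − ŷ)² / (n − 1)².
5. **Slide diagnosis** — the slide takes the class of its worst tile; a
   slide whose segmentation is empty is classified "others" without ever
   reaching the classifier.

Real gigapixel WSIs and GPU-scale backbones are out of scope: the neural
networks are small NumPy implementations (see `cervicad.nn`), and a
**synthetic phantom generator** (`cervicad.phantom`) produces fully
ground-truthed slides — elliptical stromal fragments carrying a curved,
variable-thickness epithelium ribbon whose nuclear texture encodes the
grade — so every stage trains and evaluates on one CPU.

## Worked example

The evaluation conventions are locked by reference confusion tables. For
the 600-slide test cohort (rows = predicted, columns = actual, classes
NNeo/LSIL/HSIL/others):

```python
>>> import numpy as np
>>> from cervicad.metrics import (ConfusionMatrix, balanced_accuracy,
...                               exclude_class, qwk_statistic, weighted_prf)
>>> cm = ConfusionMatrix(np.array([[126, 21, 0, 22], [73, 202, 24, 16],
...                                [5, 25, 56, 0], [0, 2, 0, 28]]),
...                      ("NNeo", "LSIL", "HSIL", "others"))
>>> round(100 * balanced_accuracy(cm), 2)      # macro recall, 4 classes
63.75
>>> cm3 = exclude_class(cm, "others")          # drops the others row AND column
>>> round(100 * balanced_accuracy(cm3), 2)
71.07
>>> round(qwk_statistic(cm3), 2)               # quadratic weighted kappa
0.67
>>> [round(100 * v, 2) for v in weighted_prf(cm3)]   # precision, sensitivity, F1
[74.15, 72.18, 72.11]
```

`balanced_accuracy` is the unweighted mean of per-class recall;
`weighted_prf` averages per-class precision/recall/F1 with actual-class
supports; `exclude_class` removes both the predicted row and the actual
column, so the two LSIL slides predicted "others" leave the evaluation
(532 slides remain). QWK is computed on counts over the ordered grades
only.

A phantom end-to-end run from the shell:

```sh
cervicad synth --n 20 --seed 1 --out cohort/
cervicad train-seg --data cohort/ --out seg_ck --epochs 10 --seed 1
cervicad train-cls --data cohort/ --out cls_ck --epochs 40 --seed 1 --supervision AT
cervicad predict --data cohort/ --seg-model seg_ck --cls-model cls_ck --out run/
cervicad evaluate --pred run/predictions.csv
```

`run/metrics.json` then contains the 4-class confusion matrix, balanced
accuracy, weighted precision/sensitivity/F1, QWK over the three ordinal
grades and the epithelium-detection balanced accuracy for the cohort.

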