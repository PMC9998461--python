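"""Reference worked examples and desk-scale phantom experiments.

Two kinds of reproducible computation live here:

* worked-example metrics -- the evaluation conventions applied to the
  reference confusion tables of the clinical validation this framework
  follows (111 annotated epithelial regions; an independent 600-slide
  test cohort with the non-representative class). These lock the metric
  definitions: balanced accuracy = macro recall, weighted
  precision/sensitivity/F1 with actual-class supports, QWK on counts,
  and class exclusion that drops both the predicted row and the actual
  column.

* desk-scale phantom experiments -- the full learning pipeline run on
  synthetic phantom slides at CPU-friendly sizes: U-Net epithelium
  segmentation, AT-tile ordinal classification, and the end-to-end
  worst-tile pipeline under oracle models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .labels import OTHERS, OrdinalLabel, label_name
from .metrics import (ConfusionMatrix, balanced_accuracy, detection_balanced_accuracy,
                      exclude_class, qwk_statistic, weighted_prf)

__all__ = [
    "VAL_CM_AE_AT", "VAL_CM_AE_AT_LS", "TEST_CM_ALL",
    "worked_example_metrics", "desk_phantom_config",
    "desk_scale_segmentation", "desk_scale_classification",
    "oracle_cohort", "injected_hsil_slide",
]

# Reference confusion matrices (rows = predicted, columns = actual).
# Validation set of 111 annotated epithelial regions, classifier trained
# on annotated epithelia + annotated tiles:
VAL_CM_AE_AT = np.array([[10, 7, 0],
                         [3, 45, 5],
                         [2, 11, 28]])
# Same validation set, training additionally using labelled slides:
VAL_CM_AE_AT_LS = np.array([[9, 5, 0],
                            [4, 52, 7],
                            [2, 6, 26]])
# Independent 600-slide test cohort, full pipeline, all four classes
# (NNeo, LSIL, HSIL, others):
TEST_CM_ALL = np.array([[126, 21, 0, 22],
                        [73, 202, 24, 16],
                        [5, 25, 56, 0],
                        [0, 2, 0, 28]])


def worked_example_metrics() -> dict:
    """Every slide-level statistic recomputed from the reference tables.

    Accuracy-like values are on the percent scale; QWK on [-1, 1].
    """
    cm_val = ConfusionMatrix(VAL_CM_AE_AT, ("NNeo", "LSIL", "HSIL"))
    cm_val_ls = ConfusionMatrix(VAL_CM_AE_AT_LS, ("NNeo", "LSIL", "HSIL"))
    cm_all = ConfusionMatrix(TEST_CM_ALL, ("NNeo", "LSIL", "HSIL", OTHERS))
    cm3 = exclude_class(cm_all, OTHERS)

    p_all, s_all, f_all = weighted_prf(cm_all)
    p3, s3, f3 = weighted_prf(cm3)
    _, s_val, _ = weighted_prf(cm_val)

    # Epithelium-detection split implied by the cohort table: "others"
    # slides are negative; a slide counts as detected-positive when it was
    # not predicted "others".
    actual_pos = np.array([True] * 534 + [False] * 66)
    pred_pos = np.array([True] * 532 + [False] * 2 + [True] * 38 + [False] * 28)

    out = {
        "val_balanced_accuracy_pct": {"value": 100 * balanced_accuracy(cm_val), "n": cm_val.total},
        "val_weighted_sensitivity_pct": {"value": 100 * s_val, "n": cm_val.total},
        "val_ls_balanced_accuracy_pct": {"value": 100 * balanced_accuracy(cm_val_ls),
                                         "n": cm_val_ls.total},
        "test_balanced_accuracy_all_pct": {"value": 100 * balanced_accuracy(cm_all),
                                           "n": cm_all.total},
        "test_weighted_precision_all_pct": {"value": 100 * p_all, "n": cm_all.total},
        "test_weighted_sensitivity_all_pct": {"value": 100 * s_all, "n": cm_all.total},
        "test_weighted_f1_all_pct": {"value": 100 * f_all, "n": cm_all.total},
        "test_balanced_accuracy_excl_others_pct": {"value": 100 * balanced_accuracy(cm3),
                                                   "n": cm3.total},
        "test_qwk_excl_others": {"value": qwk_statistic(cm3), "n": cm3.total},
        "test_weighted_precision_excl_others_pct": {"value": 100 * p3, "n": cm3.total},
        "test_weighted_sensitivity_excl_others_pct": {"value": 100 * s3, "n": cm3.total},
        "test_weighted_f1_excl_others_pct": {"value": 100 * f3, "n": cm3.total},
        "test_detection_balanced_accuracy_pct": {
            "value": 100 * detection_balanced_accuracy(pred_pos, actual_pos), "n": 600},
    }
    return out


def desk_phantom_config(seed: int = 0):
    """Desk-scale phantom: single fragment on 640x480, ribbon 24-40 px
    (the slide-scale geometry shrunk ~3x so training fits on one CPU)."""
    from .phantom import PhantomConfig

    return PhantomConfig(image_size=(640, 480), fragments_per_slide=(1, 1),
                         ribbon_thickness=(24, 40), seed=seed)


def _derived_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _graded_phantoms(seed: int, n: int, include_others: bool = False):
    from .phantom import generate_phantom_slide

    cfg = desk_phantom_config(seed)
    cycle = [OrdinalLabel.NNEO, OrdinalLabel.LSIL, OrdinalLabel.HSIL]
    if include_others:
        cycle = cycle + [OTHERS]
    seeds = _derived_seeds(seed, n)
    return [generate_phantom_slide(cfg, cycle[i % len(cycle)], int(seeds[i]))
            for i in range(n)]


def desk_scale_segmentation(seed: int, n_train_crops: int = 40, n_test_slides: int = 10,
                            crop_size: int = 256, epochs: int = 10) -> dict:
    """Train the tiny U-Net (depth 2, 8 filters) on phantom fragment crops
    and report pixel Dice on crops from held-out phantom slides."""
    from .datasets import build_segmentation_pairs, records_from_phantoms
    from .metrics import segmentation_metrics
    from .segmentation import SegConfig, predict_mask, train_segmenter

    phantoms = _graded_phantoms(seed, 64, include_others=True)
    records = records_from_phantoms(phantoms)
    # fill the training-crop budget slide by slide, then hold out crops
    # from entirely unseen slides
    train_pairs, test_pairs = [], []
    for rec in records:
        pairs = build_segmentation_pairs([rec], crop_size=crop_size)
        if len(train_pairs) < n_train_crops:
            train_pairs.extend(pairs)
        elif len(test_pairs) < n_test_slides:
            test_pairs.extend(pairs)
        else:
            break
    train_pairs = train_pairs[:n_train_crops]
    test_pairs = test_pairs[:n_test_slides]
    n_val = max(len(train_pairs) // 5, 1)
    cfg = SegConfig(input_mode="rgb", depth=2, base_filters=8, learning_rate=3e-3,
                    batch_size=4, epochs=epochs, seed=int(_derived_seeds(seed, 1)[0]))
    model = train_segmenter(train_pairs[n_val:], train_pairs[:n_val], cfg)
    dices = [segmentation_metrics(predict_mask(model, crop), mask)["dice"]
             for crop, mask in test_pairs]
    return {"dice_mean": float(np.mean(dices)), "n_test": len(test_pairs),
            "best_val_loss": model.best_val_loss}


def desk_scale_classification(seed: int, n_slides: int = 36, tile_size: int = 128,
                              epochs: int = 40, warmup_epochs: int = 25) -> dict:
    """Train the micro-CNN on fully supervised phantom AT tiles and report
    held-out tile balanced accuracy."""
    from .datasets import build_tile_dataset, records_from_phantoms
    from .mil import ClsConfig, build_bags, bag_balanced_accuracy, train_classifier

    phantoms = _graded_phantoms(seed, n_slides)
    records = records_from_phantoms(phantoms)
    manifest, tiles, annotations = build_tile_dataset(records, tile_size=tile_size,
                                                      tile_interval=tile_size * 3 / 8)
    bags = build_bags(manifest, annotations, tiles, "AT")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(bags))
    n_val = len(bags) // 4
    val = [bags[i] for i in order[:n_val]]
    train = [bags[i] for i in order[n_val:]]
    cfg = ClsConfig(input_size=64, widths=(8, 16, 32), learning_rate=3e-3, batch_size=16,
                    epochs=epochs, warmup_epochs=warmup_epochs,
                    seed=int(_derived_seeds(seed, 2)[1]))
    model = train_classifier(train, val, cfg)
    return {"balanced_accuracy": bag_balanced_accuracy(model, val),
            "n_val_tiles": len(val), "n_train_tiles": len(train)}


def oracle_cohort(seed: int, n_slides: int = 20) -> dict:
    """Run the full pipeline over a mixed phantom cohort with oracle
    models (ground-truth segmentation, annotation-based tile grades)."""
    from .oracles import OracleClassifier, OracleSegmenter
    from .phantom import generate_phantom_slide, largest_remainder_counts
    from .pipeline import PipelineConfig, run_cohort
    from .slide_io import SlideImage, warp_mask_to_crop

    cfg = desk_phantom_config(seed)
    counts = largest_remainder_counts(n_slides, cfg.class_mix)
    labels = [lab for lab in ("NNeo", "LSIL", "HSIL", OTHERS) for _ in range(counts.get(lab, 0))]
    seeds = _derived_seeds(seed + 1, n_slides)
    from .labels import parse_label

    phantoms = [generate_phantom_slide(cfg, parse_label(lab), int(s))
                for lab, s in zip(labels, seeds)]
    ids = [f"s{i:03d}" for i in range(n_slides)]
    manifest = pd.DataFrame([{"slide_id": sid, "label": label_name(ph.slide_label), "path": ""}
                             for sid, ph in zip(ids, phantoms)])
    lookup = dict(zip(ids, phantoms))

    class Seg:
        current = None

        def segment(self, crop):
            return warp_mask_to_crop(crop, self.current)

    seg = Seg()
    cls = OracleClassifier({sid: [(p, g) for p, g in ph.region_labels]
                            for sid, ph in lookup.items()})

    def loader(row):
        ph = lookup[row["slide_id"]]
        seg.current = ph.epithelium_mask
        return SlideImage(ph.image)

    pc = PipelineConfig(crop_size=256, tile_size=128, tile_interval=64)
    preds, report = run_cohort(manifest, seg, cls, config=pc, slide_loader=loader)
    cm = np.array(report["all_classes"]["confusion_matrix"])
    return {"accuracy": float(np.trace(cm) / cm.sum()),
            "balanced_accuracy_all": report["all_classes"]["balanced_accuracy"],
            "identity": bool(np.trace(cm) == cm.sum()), "n": int(cm.sum())}


def injected_hsil_slide(seed: int) -> dict:
    """An LSIL ribbon with one injected HSIL segment must be graded HSIL
    by the worst-tile rule."""
    from .oracles import OracleClassifier, OracleSegmenter
    from .phantom import generate_phantom_slide
    from .pipeline import PipelineConfig, diagnose_slide
    from .slide_io import SlideImage

    cfg = desk_phantom_config(seed)
    ph = generate_phantom_slide(
        cfg, OrdinalLabel.HSIL, int(_derived_seeds(seed + 2, 1)[0]),
        segment_labels=[OrdinalLabel.LSIL, OrdinalLabel.HSIL, OrdinalLabel.LSIL])
    seg = OracleSegmenter(ph.epithelium_mask)
    cls = OracleClassifier({"s": [(p, g) for p, g in ph.region_labels]})
    diag = diagnose_slide(SlideImage(ph.image), seg, cls,
                          PipelineConfig(crop_size=256, tile_size=128, tile_interval=64),
                          slide_id="s")
    return {"grade": int(diag.label), "n_tiles": diag.n_tiles}
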