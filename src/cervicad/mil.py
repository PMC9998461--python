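"""Ordinal multiple-instance tile classification.

Bags of 512x512 tiles are built at three supervision levels:

* LS (labelled slides)      -- all tiles of all epithelia of one slide,
                               labelled with the slide diagnosis;
* AE (annotated epithelium) -- the tiles of one labelled epithelial
                               region, labelled with the region grade;
* AT (annotated tiles)      -- single tiles whose center falls inside a
                               class polygon (full supervision).

Training follows the top-instance MIL scheme: at every epoch the current
model ranks each LS/AE bag by the expected value of the ordinal class
distribution, E = sum_i i * p_i, the worst (highest-expectation) tile is
selected and labelled with the bag label, and a gradient pass runs over
the selected tiles plus all AT tiles with the weighted-kappa loss
L = 1 - kappa. The observed matrix uses soft probability mass so the loss
is differentiable; on hard one-hot predictions it coincides exactly with
the count-matrix kappa statistic.

The classifier never sees the "others" class -- non-representative
slides carry no epithelium and therefore no tiles.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from skimage import transform

from . import nn
from .centerline import Tile
from .labels import CLASS_NAMES, UNCERTAIN, OrdinalLabel
from .metrics import ConfusionMatrix, balanced_accuracy, qwk_weight_matrix
from .slide_io import Region, points_in_polygon

__all__ = [
    "TileBag",
    "KappaLossTerms",
    "ClsConfig",
    "ClsModel",
    "build_bags",
    "expected_score",
    "rank_and_select",
    "qwk_weight_matrix",
    "qwk_loss",
    "qwk_loss_grad",
    "train_classifier",
]

N_CLASSES = 3


@dataclasses.dataclass
class TileBag:
    tiles: list
    bag_label: OrdinalLabel
    supervision: str  # LS | AE | AT
    bag_id: str

    def __post_init__(self):
        if self.supervision not in ("LS", "AE", "AT"):
            raise ValueError(f"unknown supervision level {self.supervision!r}")
        if not self.tiles:
            raise ValueError(f"bag {self.bag_id} is empty")
        if self.supervision == "AT" and len(self.tiles) != 1:
            raise ValueError("AT bags are fully supervised single tiles")
        self.bag_label = OrdinalLabel(self.bag_label)


@dataclasses.dataclass(frozen=True)
class KappaLossTerms:
    weight_matrix: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    kappa: float
    loss: float
    degenerate: bool = False


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
            raise ValueError("class probabilities must be non-negative and sum to 1")
    return p


def expected_score(p) -> float:
    """Expected ordinal score E = sum_i i * p_i, in [1, n]."""
    p = _check_probs(p)
    ranks = np.arange(1, len(p) + 1, dtype=float)
    return float(ranks @ p)


def rank_and_select(model, bag: TileBag):
    """Rank a bag's tiles by expected score (descending) and pick the worst.

    Ties are broken by higher HSIL probability, then by stable tile order.
    Returns (worst_tile, ranked) where ranked is a list of
    (tile, probabilities, expected score).
    """
    probs = model.predict_proba_tiles(bag.tiles)
    scores = probs @ np.arange(1, probs.shape[1] + 1, dtype=float)
    order = sorted(range(len(bag.tiles)),
                   key=lambda i: (-scores[i], -probs[i, -1], i))
    ranked = [(bag.tiles[i], probs[i], float(scores[i])) for i in order]
    return ranked[0][0], ranked


def qwk_loss(pred_probs, labels, n_classes: int = N_CLASSES) -> KappaLossTerms:
    """Weighted-kappa loss L = 1 - kappa on a batch of soft predictions.

    The observed matrix accumulates probability mass: x[y, yhat] is the
    total p(yhat) over batch items with actual grade y. The expected
    matrix is the outer product of the actual and predicted marginals,
    normalised to the same sum. A batch with (near-)zero expected
    disagreement is degenerate: kappa is defined as 0 with a flag.
    """
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.ndim != 2 or p.shape[1] != n_classes:
        raise ValueError(f"expected (batch, {n_classes}) probabilities")
    if len(p) != len(y):
        raise ValueError("batch size mismatch between predictions and labels")
    if ((y < 1) | (y > n_classes)).any():
        raise ValueError(f"labels must be ordinal ranks in 1..{n_classes}")
    w = qwk_weight_matrix(n_classes)
    x = np.zeros((n_classes, n_classes))
    for cls in range(1, n_classes + 1):
        sel = y == cls
        if sel.any():
            x[cls - 1] = p[sel].sum(axis=0)
    a = x.sum(axis=1)          # actual marginals (counts)
    q = x.sum(axis=0)          # predicted marginals (soft)
    total = a.sum()
    m = np.outer(a, q) / total
    den = float((w * m).sum())
    if den < 1e-12:
        return KappaLossTerms(w, x, m, kappa=0.0, loss=1.0, degenerate=True)
    num = float((w * x).sum())
    kappa = 1.0 - num / den
    degenerate = len(np.unique(y)) < 2
    return KappaLossTerms(w, x, m, kappa=kappa, loss=1.0 - kappa, degenerate=degenerate)


def qwk_loss_grad(pred_probs, labels, n_classes: int = N_CLASSES):
    """(loss, d loss / d pred_probs) for the soft weighted-kappa loss.

    The full Jacobian of the implemented loss, including the dependence of
    both marginals and the total on the probabilities, so it matches a
    finite-difference check in the ambient (unnormalised) space.
    """
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    terms = qwk_loss(p, y, n_classes)
    w = terms.weight_matrix
    den = float((w * terms.expected).sum())
    if den < 1e-12:
        return terms, np.zeros_like(p)
    a = terms.observed.sum(axis=1)
    q = terms.observed.sum(axis=0)
    total = a.sum()
    num = float((w * terms.observed).sum())
    dnum = w[y - 1]                                  # (batch, n)
    wq = (w @ q)                                     # (n,)
    aw = (a @ w)                                     # (n,)
    dden = (wq[y - 1][:, None] + aw[None, :] - den) / total
    grad = (dnum * den - num * dden) / den**2
    return terms, grad


def build_bags(manifest, annotations: dict, tiles: Sequence[Tile], supervision: str) -> list[TileBag]:
    """Assemble TileBags at one supervision level.

    ``manifest`` maps slides to diagnoses (columns slide_id, label);
    ``annotations`` maps slide_id to labelled Regions (level-0 polygon
    coordinates); ``tiles`` carry their slide_id and level-0 centers.
    Tiles whose center falls in an "uncertain" polygon are excluded from
    every bag.
    """
    if supervision not in ("LS", "AE", "AT"):
        raise ValueError(f"unknown supervision level {supervision!r}")
    slide_labels = {str(r["slide_id"]): str(r["label"]) for _, r in manifest.iterrows()}
    by_slide: dict[str, list[Tile]] = {}
    for tile in tiles:
        if tile.slide_id not in slide_labels:
            raise ValueError(f"tile at {tile.center} has no parent slide {tile.slide_id!r}")
        by_slide.setdefault(tile.slide_id, []).append(tile)

    def region_label(region: Region) -> object:
        name = region.label.strip().lower()
        if name == UNCERTAIN:
            return UNCERTAIN
        if name not in {c.lower() for c in CLASS_NAMES}:
            raise ValueError(f"polygon with unknown label {region.label!r}")
        return OrdinalLabel.from_name(name)

    def usable(slide_id: str, slide_tiles: list[Tile]) -> list[Tile]:
        regions = annotations.get(slide_id, [])
        uncertain = [r for r in regions if region_label(r) == UNCERTAIN]
        if not uncertain:
            return slide_tiles
        centers = np.array([t.center for t in slide_tiles], dtype=float) + 0.5
        drop = np.zeros(len(slide_tiles), dtype=bool)
        for r in uncertain:
            drop |= points_in_polygon(centers, r.polygon)
        return [t for t, d in zip(slide_tiles, drop) if not d]

    bags: list[TileBag] = []
    if supervision == "LS":
        for slide_id, slide_tiles in sorted(by_slide.items()):
            label = slide_labels[slide_id]
            if label.lower() not in {c.lower() for c in CLASS_NAMES}:
                continue  # "others" slides never enter training
            kept = usable(slide_id, slide_tiles)
            if kept:
                bags.append(TileBag(kept, OrdinalLabel.from_name(label), "LS", slide_id))
        return bags

    for slide_id, slide_tiles in sorted(by_slide.items()):
        regions = annotations.get(slide_id, [])
        kept = usable(slide_id, slide_tiles)
        if not kept:
            continue
        centers = np.array([t.center for t in kept], dtype=float) + 0.5
        for ri, region in enumerate(regions):
            label = region_label(region)
            if label == UNCERTAIN:
                continue
            inside = points_in_polygon(centers, region.polygon)
            members = [t for t, isin in zip(kept, inside) if isin]
            if not members:
                continue
            if supervision == "AE":
                bags.append(TileBag(members, label, "AE", f"{slide_id}/region{ri}"))
            else:
                for ti, tile in enumerate(members):
                    bags.append(TileBag([tile], label, "AT", f"{slide_id}/region{ri}/tile{ti}"))
    return bags


# ---------------------------------------------------------------------------
# Classifier training


@dataclasses.dataclass
class ClsConfig:
    """Defaults mirror full-scale training (lr 1e-5, batches of 16, 300
    epochs); desk-scale runs use larger rates and far fewer epochs."""

    input_size: int = 64
    widths: tuple[int, ...] = (8, 16, 32)
    learning_rate: float = 1e-5
    batch_size: int = 16
    epochs: int = 300
    #: uniform mixing applied to probabilities inside the training loss;
    #: keeps kappa gradients alive when the softmax saturates a class out
    prob_floor: float = 0.02
    #: cross-entropy epochs before switching to the kappa loss. A randomly
    #: initialised backbone (no pretrained weights) needs this: the kappa
    #: loss preserves a good 3-class solution but, started from noise, its
    #: denominator term rewards extreme-class marginals and the middle
    #: grade never forms.
    warmup_epochs: int = 0
    seed: int = 0


class ClsModel:
    """Micro-CNN tile classifier over the three ordered grades."""

    def __init__(self, net: nn.MicroCNN, config: ClsConfig):
        self.net = net
        self.config = config

    def tile_tensor(self, tile: Tile) -> np.ndarray:
        img = np.asarray(tile.image, dtype=np.float32) / 255.0
        size = self.config.input_size
        if img.shape[0] != size or img.shape[1] != size:
            img = transform.resize(img, (size, size), order=1, anti_aliasing=True,
                                   preserve_range=True).astype(np.float32)
        # H&E tiles are mostly bright; center/scale so the net starts in a
        # well-conditioned regime
        return ((img - 0.8) / 0.25).transpose(2, 0, 1)

    def predict_proba_tiles(self, tiles: Sequence[Tile]) -> np.ndarray:
        x = np.stack([self.tile_tensor(t) for t in tiles])
        return self.net.predict_proba(x)

    def save(self, path) -> None:
        meta = dataclasses.asdict(self.config)
        meta["widths"] = list(meta["widths"])
        nn.save_model(path, self.net, "microcnn", meta=meta)

    @classmethod
    def load(cls, path) -> "ClsModel":
        net, sidecar = nn.load_model(path)
        meta = dict(sidecar["meta"])
        meta["widths"] = tuple(meta["widths"])
        return cls(net, ClsConfig(**meta))

    def digest(self) -> str:
        return nn.model_digest(self.net)


def bag_balanced_accuracy(model, bags: Sequence[TileBag]) -> float:
    """Bag-level balanced accuracy: predicted class = argmax of the worst
    tile's probabilities."""
    preds, actuals = [], []
    for bag in bags:
        _, ranked = rank_and_select(model, bag)
        preds.append(int(np.argmax(ranked[0][1])) + 1)
        actuals.append(int(bag.bag_label))
    present = sorted(set(actuals))
    cm = ConfusionMatrix.from_labels(preds, actuals, classes=[1, 2, 3])
    keep = [c - 1 for c in present]
    sub = cm.counts[np.ix_([0, 1, 2], keep)]
    recalls = [sub[c - 1, j] / sub[:, j].sum() for j, c in enumerate(present)]
    return float(np.mean(recalls))


def train_classifier(bags: Sequence[TileBag], val_bags: Sequence[TileBag],
                     config: ClsConfig, log_path=None) -> ClsModel:
    """Two-phase MIL training; returns the checkpoint with the best
    bag-level validation balanced accuracy.

    Each epoch first ranks every LS/AE bag with the current model and
    selects its worst tile (labelled with the bag label), then runs
    mini-batch gradient steps with the weighted-kappa loss over the
    selected tiles plus all AT tiles. Fully seeded and deterministic.
    """
    if not bags:
        raise ValueError("no training bags")
    rng = np.random.default_rng(config.seed)
    net = nn.MicroCNN(in_channels=3, n_classes=N_CLASSES, widths=config.widths, rng=rng)
    model = ClsModel(net, config)
    opt = nn.Adam(net.params(), lr=config.learning_rate)

    # pre-compute input tensors once per distinct tile
    tile_ids: dict[int, int] = {}
    tensors: list[np.ndarray] = []
    for bag in list(bags) + list(val_bags):
        for tile in bag.tiles:
            if id(tile) not in tile_ids:
                tile_ids[id(tile)] = len(tensors)
                tensors.append(model.tile_tensor(tile))
    tensors = np.stack(tensors)

    at_instances = [(tile_ids[id(bag.tiles[0])], int(bag.bag_label))
                    for bag in bags if bag.supervision == "AT"]
    mil_bags = [bag for bag in bags if bag.supervision != "AT"]

    best_metric = -np.inf
    best_params = nn.checkpoint.clone_params(net)
    history = []
    for epoch in range(config.epochs):
        instances = list(at_instances)
        for bag in mil_bags:  # inference pass: top-instance selection
            idxs = [tile_ids[id(t)] for t in bag.tiles]
            probs = net.predict_proba(tensors[idxs])
            scores = probs @ np.arange(1, N_CLASSES + 1, dtype=float)
            order = sorted(range(len(idxs)), key=lambda i: (-scores[i], -probs[i, -1], i))
            instances.append((idxs[order[0]], int(bag.bag_label)))

        order = rng.permutation(len(instances))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            chunk = [instances[i] for i in order[start:start + config.batch_size]]
            xb = tensors[[i for i, _ in chunk]]
            yb = np.array([lab for _, lab in chunk], dtype=int)
            logits = net.forward(xb)
            probs = nn.softmax(logits, axis=1)
            if epoch < config.warmup_epochs:
                onehot = np.eye(N_CLASSES)[yb - 1]
                batch_loss = float(-np.log(np.clip(probs[np.arange(len(yb)), yb - 1],
                                                   1e-12, None)).mean())
                dz = (probs - onehot) / len(yb)
            else:
                eps = config.prob_floor
                mixed = (1.0 - eps) * probs + eps / N_CLASSES
                terms, dp = qwk_loss_grad(mixed, yb)
                if terms.degenerate:
                    continue  # single-grade batch carries no kappa signal
                batch_loss = terms.loss
                dp = (1.0 - eps) * dp
                dz = probs * (dp - (dp * probs).sum(axis=1, keepdims=True))
            if not np.isfinite(batch_loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            net.backward(dz.astype(np.float32))
            opt.step()
            epoch_loss += batch_loss
            n_batches += 1

        val_metric = bag_balanced_accuracy(model, val_bags) if val_bags else 0.0
        history.append({"epoch": epoch,
                        "train_loss": epoch_loss / max(n_batches, 1),
                        "val_balanced_accuracy": val_metric})
        if val_metric > best_metric:
            best_metric = val_metric
            best_params = nn.checkpoint.clone_params(net)

    nn.checkpoint.set_params(net, best_params)
    model.history = history
    model.best_val_metric = float(best_metric)
    if log_path is not None:
        import csv
        from pathlib import Path

        log_path = Path(log_path)
        log_path.parent.mkdir(parents=True, exist_ok=True)
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            writer.writeheader()
            writer.writerows(history)
    return model
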