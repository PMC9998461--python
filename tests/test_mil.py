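"""Ordinal MIL: bags, expected-score ranking and the weighted-kappa loss."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cervicad.centerline import Tile
from cervicad.labels import OrdinalLabel
from cervicad.metrics import ConfusionMatrix, qwk_statistic
from cervicad.mil import (TileBag, build_bags, expected_score, qwk_loss, qwk_loss_grad,
                          rank_and_select)
from cervicad.slide_io import Region

from conftest import StubTileModel


def _tile(center, slide_id="s0", eid=0):
    return Tile(image=np.zeros((8, 8, 3), np.uint8), center=center,
                slide_id=slide_id, epithelium_id=eid)


class TestExpectedScore:
    def test_degenerate_distributions(self):
        assert expected_score([1, 0, 0]) == 1.0
        assert expected_score([0, 0, 1]) == 3.0

    def test_direct_evaluation(self):
        assert expected_score([0.2, 0.5, 0.3]) == pytest.approx(2.1)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_under_upward_mass_shift(self, seed):
        """Moving mass from a lower to a higher grade raises the score."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(3))
        lo, hi = sorted(rng.choice(3, size=2, replace=False))
        delta = p[lo] * 0.5
        if delta == 0:
            return
        q = p.copy()
        q[lo] -= delta
        q[hi] += delta
        assert expected_score(q) > expected_score(p)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            expected_score([0.5, 0.2, 0.1])


class TestRankAndSelect:
    def test_worst_tile_has_highest_expected_score(self):
        bag = TileBag([_tile((0, 0)), _tile((1, 0)), _tile((2, 0))],
                      OrdinalLabel.LSIL, "LS", "b")
        model = StubTileModel([[0.9, 0.0, 0.1], [0.05, 0.0, 0.95], [0.45, 0.0, 0.55]])
        worst, ranked = rank_and_select(model, bag)
        assert worst is bag.tiles[1]
        assert [r[2] for r in ranked] == sorted([r[2] for r in ranked], reverse=True)

    def test_single_tile_bag(self):
        bag = TileBag([_tile((0, 0))], OrdinalLabel.HSIL, "AT", "b")
        worst, _ = rank_and_select(model=StubTileModel([[0.2, 0.3, 0.5]]), bag=bag)
        assert worst is bag.tiles[0]

    def test_ties_broken_by_hsil_probability_then_order(self):
        bag = TileBag([_tile((i, 0)) for i in range(3)], OrdinalLabel.LSIL, "AE", "b")
        # equal expected scores (2.0); middle tile has the highest p(HSIL)
        model = StubTileModel([[0.25, 0.5, 0.25], [0.35, 0.3, 0.35], [0.25, 0.5, 0.25]])
        worst, _ = rank_and_select(model, bag)
        assert worst is bag.tiles[1]
        # all-identical: stable order picks the first
        model = StubTileModel([[1 / 3] * 3] * 3)
        worst, _ = rank_and_select(model, bag)
        assert worst is bag.tiles[0]

    def test_adding_a_tile_never_lowers_selected_score(self):
        probs = [[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.1, 0.2, 0.7]]
        model = StubTileModel(probs)
        tiles = [_tile((i, 0)) for i in range(3)]
        prev = -np.inf
        for k in (1, 2, 3):
            bag = TileBag(tiles[:k], OrdinalLabel.LSIL, "AE", "b")
            _, ranked = rank_and_select(model, bag)
            assert ranked[0][2] >= prev
            prev = ranked[0][2]


class TestQwkLoss:
    def test_perfect_one_hot_batch_has_zero_loss(self):
        labels = np.array([1, 2, 3, 2, 1])
        probs = np.eye(3)[labels - 1]
        terms = qwk_loss(probs, labels)
        assert terms.kappa == pytest.approx(1.0)
        assert terms.loss == pytest.approx(0.0)
        assert not terms.degenerate

    def test_all_predicted_middle_hand_case(self):
        """labels (1,2,3), everything predicted LSIL: kappa 0, loss 1."""
        probs = np.tile([0.0, 1.0, 0.0], (3, 1))
        terms = qwk_loss(probs, np.array([1, 2, 3]))
        assert float((terms.weight_matrix * terms.observed).sum()) == pytest.approx(0.5)
        assert float((terms.weight_matrix * terms.expected).sum()) == pytest.approx(0.5)
        assert terms.kappa == pytest.approx(0.0)
        assert terms.loss == pytest.approx(1.0)

    def test_observed_and_expected_have_equal_sums(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=10)
        terms = qwk_loss(probs, rng.integers(1, 4, 10))
        assert terms.observed.sum() == pytest.approx(terms.expected.sum())

    def test_degenerate_single_class_batch_flagged(self):
        probs = np.tile([1.0, 0.0, 0.0], (4, 1))
        terms = qwk_loss(probs, np.array([1, 1, 1, 1]))
        assert terms.degenerate
        assert terms.kappa == 0.0 and terms.loss == 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_loss_bounded_between_zero_and_two(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        probs = rng.dirichlet(np.ones(3), size=n)
        labels = rng.integers(1, 4, n)
        loss = qwk_loss(probs, labels).loss
        assert 0.0 <= loss <= 2.0 + 1e-9

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_hard_label_kappa_matches_confusion_matrix_statistic(self, seed):
        """One-hot batches reduce exactly to the count-matrix kappa."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        labels = rng.integers(1, 4, n)
        if len(np.unique(labels)) < 2:
            return
        hard = rng.integers(1, 4, n)
        probs = np.eye(3)[hard - 1]
        counts = np.zeros((3, 3), dtype=int)
        for p, a in zip(hard, labels):
            counts[p - 1, a - 1] += 1
        cm = ConfusionMatrix(counts, (1, 2, 3))
        assert qwk_loss(probs, labels).kappa == pytest.approx(qwk_statistic(cm), abs=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        probs = rng.dirichlet(np.ones(3), size=n)
        labels = rng.integers(1, 4, n)
        if len(np.unique(labels)) < 2:
            return
        terms, grad = qwk_loss_grad(probs, labels)
        eps = 1e-7
        for i in range(0, n, 2):
            for j in range(3):
                p2 = probs.copy()
                p2[i, j] += eps
                num = (qwk_loss(p2, labels).loss - terms.loss) / eps
                assert grad[i, j] == pytest.approx(num, abs=1e-4)


class TestBuildBags:
    def _manifest(self, rows):
        return pd.DataFrame(rows)

    def test_labelled_slide_pools_all_epithelia(self):
        tiles = [_tile((i * 10, 0), "s0", eid=i // 5) for i in range(10)]
        manifest = self._manifest([{"slide_id": "s0", "label": "LSIL"}])
        bags = build_bags(manifest, {}, tiles, "LS")
        assert len(bags) == 1
        assert len(bags[0].tiles) == 10
        assert bags[0].bag_label == OrdinalLabel.LSIL

    def test_annotated_epithelium_bag(self):
        tiles = [_tile((10 + i, 10), "s0") for i in range(7)]
        poly = np.array([[0, 0], [40, 0], [40, 40], [0, 40]], float)
        manifest = self._manifest([{"slide_id": "s0", "label": "LSIL"}])
        bags = build_bags(manifest, {"s0": [Region(poly, "LSIL")]}, tiles, "AE")
        assert len(bags) == 1
        assert len(bags[0].tiles) == 7
        assert bags[0].bag_label == OrdinalLabel.LSIL

    def test_annotated_tiles_are_singletons(self):
        inside = [_tile((5 + i, 5), "s0") for i in range(3)]
        outside = [_tile((90, 90), "s0")]
        poly = np.array([[0, 0], [20, 0], [20, 20], [0, 20]], float)
        manifest = self._manifest([{"slide_id": "s0", "label": "HSIL"}])
        bags = build_bags(manifest, {"s0": [Region(poly, "HSIL")]}, inside + outside, "AT")
        assert len(bags) == 3
        assert all(len(b.tiles) == 1 and b.bag_label == OrdinalLabel.HSIL for b in bags)

    def test_uncertain_polygons_exclude_tiles_everywhere(self):
        tiles = [_tile((5, 5), "s0"), _tile((50, 50), "s0")]
        uncertain = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        manifest = self._manifest([{"slide_id": "s0", "label": "HSIL"}])
        bags = build_bags(manifest, {"s0": [Region(uncertain, "uncertain")]}, tiles, "LS")
        assert len(bags) == 1 and len(bags[0].tiles) == 1

    def test_orphan_tile_rejected(self):
        manifest = self._manifest([{"slide_id": "s0", "label": "LSIL"}])
        with pytest.raises(ValueError, match="parent slide"):
            build_bags(manifest, {}, [_tile((0, 0), "nope")], "LS")

    def test_unknown_polygon_label_rejected(self):
        poly = np.array([[0, 0], [9, 0], [9, 9]], float)
        manifest = self._manifest([{"slide_id": "s0", "label": "LSIL"}])
        with pytest.raises(ValueError, match="unknown label"):
            build_bags(manifest, {"s0": [Region(poly, "CIN9")]}, [_tile((3, 3), "s0")], "AE")

    def test_at_bag_must_be_singleton(self):
        with pytest.raises(ValueError):
            TileBag([_tile((0, 0)), _tile((1, 1))], OrdinalLabel.HSIL, "AT", "b")
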