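"""Metrics against brute-force oracles; thresholds; spatial blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from podomap.evaluation import (
    EvaluationError,
    compare_predictions_pearson,
    confusion_at,
    make_spatial_blocks,
    optimal_threshold,
    roc_auc,
    tss,
)
from podomap.grid import GridRaster, GridSpec


def brute_force_auc(labels, scores, weights):
    """Weighted concordant-pair probability, ties one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    weights = np.asarray(weights, float)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    num = den = 0.0
    for i in pos:
        for j in neg:
            w = weights[i] * weights[j]
            den += w
            if scores[i] > scores[j]:
                num += w
            elif scores[i] == scores[j]:
                num += 0.5 * w
    return num / den


class TestAuc:
    @pytest.mark.parametrize(
        "labels,scores,expected",
        [
            ([1, 0], [0.9, 0.1], 1.0),
            ([1, 0], [0.5, 0.5], 0.5),
            ([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2], 0.75),
        ],
    )
    def test_known_values(self, labels, scores, expected):
        assert roc_auc(labels, scores) == pytest.approx(expected)

    def test_single_class_errors(self):
        with pytest.raises(EvaluationError):
            roc_auc([1, 1], [0.2, 0.4])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 200)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse scores force ties
        weights = rng.uniform(0.1, 1.0, n)
        assert roc_auc(labels, scores, weights) == pytest.approx(
            brute_force_auc(labels, scores, weights)
        )


class TestTssConfusion:
    @pytest.mark.parametrize(
        "sens,spec,expected", [(1, 1, 1), (0.5, 0.5, 0.0), (0.801, 0.855, 0.656)]
    )
    def test_tss_formula(self, sens, spec, expected):
        assert tss(sens, spec) == pytest.approx(expected)

    def test_extreme_thresholds(self):
        labels = [1, 0, 1, 0]
        scores = [0.9, 0.6, 0.4, 0.1]
        assert confusion_at(labels, scores, threshold=0.0).sensitivity == 1.0
        cm = confusion_at(labels, scores, threshold=0.91)
        assert cm.specificity == 1.0 and cm.sensitivity == 0.0

    def test_enumerated_confusion(self):
        cm = confusion_at([1, 0, 1, 0], [0.9, 0.6, 0.4, 0.1], threshold=0.5)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)
        assert cm.pcc == pytest.approx(0.5)


def brute_force_threshold(labels, scores, weights):
    """Exhaustive search over every cut between distinct scores."""
    uniq = np.unique(scores)
    cands = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2]) if len(uniq) > 1 else uniq
    best = None
    for t in np.unique(cands):
        cm = confusion_at(labels, scores, weights, t)
        key = (cm.sensitivity + cm.specificity, cm.pcc, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return best[1]


class TestOptimalThreshold:
    def test_separated_scores_midpoint(self):
        res = optimal_threshold([0, 0, 1, 1], [0.1, 0.2, 0.7, 0.9])
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.threshold == pytest.approx(0.45)

    def test_tie_break_prefers_lower_threshold(self):
        res = optimal_threshold([1, 0, 1, 0], [0.9, 0.6, 0.4, 0.1])
        assert res.threshold == pytest.approx(0.25)
        assert res.tss == pytest.approx(0.5)

    def test_weight_halving_of_duplicates_invariant(self):
        labels = [1, 0, 1, 0]
        scores = [0.9, 0.6, 0.4, 0.1]
        res1 = optimal_threshold(labels, scores)
        # split the first presence into two half-weight duplicates
        res2 = optimal_threshold(
            [1] + labels, [0.9] + scores, [0.5, 0.5, 1, 1, 1]
        )
        assert res2.threshold == pytest.approx(res1.threshold)
        assert res2.tss == pytest.approx(res1.tss)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 100)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)
        weights = rng.uniform(0.1, 1.0, n)
        res = optimal_threshold(labels, scores, weights)
        assert res.threshold == pytest.approx(
            brute_force_threshold(labels, scores, weights)
        )
        # maximality of TSS among candidates, by construction
        for t in np.unique(scores):
            cm = confusion_at(labels, scores, weights, t)
            assert res.tss >= tss(cm.sensitivity, cm.specificity) - 1e-12


class TestSpatialBlocks:
    @pytest.fixture
    def spec(self):
        return GridSpec(100, 100, 0.0, 0.0, 5.0)  # 500 x 500 km

    def test_tiling_counts_and_balance(self, spec):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 500, size=(500, 2))
        fa = make_spatial_blocks(spec, pts, block_km=100.0, k=5, rng_seed=1)
        assert fa.n_block_rows * fa.n_block_cols == 25
        counts = np.bincount(list(fa.fold_of_block.values()))[1:]
        assert (counts == 5).all()  # 25 blocks over 5 folds, balanced

    def test_ten_blocks_two_each(self):
        spec = GridSpec(40, 100, 0.0, 0.0, 5.0)  # 500 x 200 km
        pts = np.random.default_rng(0).uniform((0, 0), (500, 200), size=(300, 2))
        fa = make_spatial_blocks(spec, pts, block_km=100.0, k=5, rng_seed=2)
        counts = np.bincount(list(fa.fold_of_block.values()))[1:]
        assert (counts == 2).all()

    def test_corner_point_belongs_to_block(self, spec):
        pts = np.array([[100.0, 100.0], [10.0, 10.0], [400.0, 400.0],
                        [250.0, 250.0], [350.0, 150.0]])
        fa = make_spatial_blocks(spec, pts, block_km=100.0, k=2, rng_seed=0)
        blocks = fa.block_of_points(spec, pts[:, 0], pts[:, 1])
        # (100,100) lies on the shared corner: half-open rule -> block col 1, row 1
        assert blocks[0] == 1 * fa.n_block_cols + 1

    def test_empty_fold_errors(self, spec):
        pts = np.array([[10.0, 10.0], [20.0, 20.0]])  # all in one block
        with pytest.raises(EvaluationError):
            make_spatial_blocks(spec, pts, block_km=500.0, k=2, rng_seed=0)


class TestPearson:
    def test_identity_and_inversion(self, spec4):
        a = GridRaster(spec4, np.arange(16, dtype=float).reshape(4, 4))
        b = GridRaster(spec4, -np.arange(16, dtype=float).reshape(4, 4) + 1)
        assert compare_predictions_pearson(a, a) == pytest.approx(1.0)
        assert compare_predictions_pearson(a, b) == pytest.approx(-1.0)

    def test_known_value(self):
        spec = GridSpec(1, 4, 0.0, 0.0, 1.0)
        a = GridRaster(spec, np.array([[0.0, 1.0, 2.0, 3.0]]))
        b = GridRaster(spec, np.array([[0.0, 1.0, 2.0, 4.0]]))
        expected = np.corrcoef([0, 1, 2, 3], [0, 1, 2, 4])[0, 1]
        assert compare_predictions_pearson(a, b) == pytest.approx(expected)

    def test_zero_variance_errors(self, spec4):
        a = GridRaster(spec4, np.ones((4, 4)))
        b = GridRaster(spec4, np.arange(16, dtype=float).reshape(4, 4))
        with pytest.raises(EvaluationError):
            compare_predictions_pearson(a, b)
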