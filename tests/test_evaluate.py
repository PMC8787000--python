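"""Score coupling, ROC metrics, Youden threshold, and the volume-vs-FN
trade-off, checked against exhaustive brute-force oracles."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tzs.boxes import Box
from tzs.evaluate import (
    EvalCurve,
    ScoreMap,
    UndefinedMetricError,
    auroc,
    auroc_score,
    couple_scores,
    expected_false_positives,
    highlight_patches,
    precision_at_threshold,
    region_auroc,
    volume_at_fn,
    volume_vs_fn_curve,
    youden_threshold,
)
from tzs.patches import partition_roi
from tzs.prior import PatchPrior


# ---------------------------------------------------------------- oracles
def auroc_pair_counting(scores, labels):
    """Exhaustive concordant-pair count (ties 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    """Best (lowest) threshold over every cut point, by direct evaluation."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    uniq = np.unique(scores)
    cands = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2, [np.nextafter(uniq[-1], 2)]])
    best_j, best_t = -np.inf, None
    for t in cands:
        pred = scores >= t
        j = np.sum(pred & y) / y.sum() + np.sum(~pred & ~y) / (~y).sum() - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t, best_j


score_grid = st.lists(
    st.sampled_from([round(0.1 * i, 1) for i in range(11)]), min_size=2, max_size=8
)


# ----------------------------------------------------------------- tests
class TestCoupling:
    def _prior(self, values, floor=1e-3):
        return PatchPrior(k=3, prob=np.asarray(values), floor=floor)

    def test_elementwise_product(self):
        raw = ScoreMap(k=3, scores=np.full(27, 0.8))
        prior = self._prior(np.full(27, 0.5), floor=0.5)
        out = couple_scores(raw, prior)
        assert out.coupled
        np.testing.assert_allclose(out.scores, 0.4)

    def test_unit_prior_is_identity(self):
        raw = ScoreMap(k=3, scores=np.linspace(0, 1, 27))
        out = couple_scores(raw, self._prior(np.ones(27), floor=1.0))
        np.testing.assert_array_equal(out.scores, raw.scores)

    def test_floor_bounds_coupled_score(self):
        raw = ScoreMap(k=3, scores=np.ones(27))
        out = couple_scores(raw, self._prior(np.full(27, 1e-3)))
        assert np.all(out.scores <= 1e-3)
        assert np.all(out.scores > 0)

    def test_coupling_never_increases(self):
        rng = np.random.default_rng(0)
        raw = ScoreMap(k=3, scores=rng.random(27))
        prior = self._prior(np.clip(rng.random(27), 1e-3, 1))
        out = couple_scores(raw, prior)
        assert np.all(out.scores <= raw.scores + 1e-15)

    def test_k_mismatch(self):
        with pytest.raises(ValueError):
            couple_scores(ScoreMap(k=3, scores=np.zeros(27)), self._prior(np.ones(27)).__class__(k=4, prob=np.ones(64), floor=1e-3))


class TestAUROC:
    def test_perfect_ranking(self):
        assert auroc_score([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc_score([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_worked_example_matches_pair_counting(self):
        scores, labels = [0.9, 0.4, 0.6, 0.2], [1, 0, 1, 0]
        assert auroc_score(scores, labels) == auroc_pair_counting(scores, labels)

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(score_grid, st.data())
    def test_matches_exhaustive_pair_counting(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if sum(labels) in (0, len(labels)):
            labels[0], labels[-1] = 0, 1
        assert auroc_score(scores, labels) == pytest.approx(
            auroc_pair_counting(scores, labels), abs=1e-12
        )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc_score([0.1, 0.2], [1, 1])

    def test_bootstrap_ci_brackets_point(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.uniform(0.4, 1, 30), rng.uniform(0, 0.6, 70)])
        labels = np.concatenate([np.ones(30, int), np.zeros(70, int)])
        res = auroc(scores, labels, n_bootstrap=200, seed=1)
        assert res.ci_low <= res.auroc <= res.ci_high
        assert res.n_pos == 30 and res.n_neg == 70
        res2 = auroc(scores, labels, n_bootstrap=200, seed=1)
        assert (res.ci_low, res.ci_high) == (res2.ci_low, res2.ci_high)


class TestPrecision:
    def test_separated(self):
        assert precision_at_threshold([0.9, 0.8, 0.1], [1, 1, 0], 0.5) == 1.0

    def test_threshold_zero_gives_prevalence(self):
        assert precision_at_threshold([0.9, 0.1, 0.5, 0.3], [1, 0, 0, 0], 0.0) == 0.25

    def test_mixed_hand_count(self):
        scores = [0.9, 0.7, 0.6, 0.4, 0.3, 0.1]
        labels = [1, 0, 1, 0, 1, 0]
        # >= 0.5 selects {0.9:1, 0.7:0, 0.6:1} -> TP=2, FP=1
        assert precision_at_threshold(scores, labels, 0.5) == pytest.approx(2 / 3)

    def test_no_predictions_signaled(self):
        with pytest.raises(UndefinedMetricError):
            precision_at_threshold([0.1, 0.2], [1, 0], 0.9)


class TestYouden:
    def test_separable_attains_j_one(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        t = youden_threshold(scores, labels)
        pred = np.asarray(scores) >= t
        assert np.array_equal(pred, np.asarray(labels, bool))

    def test_all_equal_scores(self):
        t = youden_threshold([0.5] * 4, [1, 0, 1, 0])
        assert t == 0.0  # lowest threshold; J = 0 everywhere

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(score_grid, st.data())
    def test_matches_exhaustive_search(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if sum(labels) in (0, len(labels)):
            labels[0], labels[-1] = 0, 1
        t_oracle, j_oracle = youden_exhaustive(scores, labels)
        t = youden_threshold(scores, labels)
        assert t == pytest.approx(t_oracle, abs=1e-12)

    def test_six_point_toy_set(self):
        scores = [0.95, 0.8, 0.7, 0.45, 0.3, 0.05]
        labels = [1, 1, 0, 1, 0, 0]
        t_oracle, _ = youden_exhaustive(scores, labels)
        assert youden_threshold(scores, labels) == pytest.approx(t_oracle)


class TestHighlight:
    def test_threshold_above_max_empty(self):
        m = ScoreMap(k=3, scores=np.linspace(0, 0.9, 27))
        idx, frac = highlight_patches(m, 0.95)
        assert idx.size == 0 and frac == 0.0

    def test_threshold_zero_all(self):
        m = ScoreMap(k=3, scores=np.linspace(0, 0.9, 27))
        idx, frac = highlight_patches(m, 0.0)
        assert idx.size == 27 and frac == 1.0

    def test_fraction_arithmetic(self):
        scores = np.zeros(125)
        scores[:19] = 0.9
        _, frac = highlight_patches(ScoreMap(k=5, scores=scores), 0.5)
        assert frac == pytest.approx(19 / 125)


class TestVolumeFnCurve:
    def test_perfect_classifier_reaches_prevalence_at_zero_fn(self):
        labels = [np.zeros(27, int) for _ in range(4)]
        maps = []
        for lab in labels:
            lab[3] = 1
            s = np.zeros(27)
            s[3] = 1.0
            maps.append(ScoreMap(k=3, scores=s))
        curve = volume_vs_fn_curve(maps, labels)
        assert volume_at_fn(curve, 0.0) == pytest.approx(1 / 27)

    def test_endpoints(self):
        rng = np.random.default_rng(0)
        maps = [ScoreMap(k=3, scores=rng.random(27)) for _ in range(3)]
        labels = [rng.integers(0, 2, 27) for _ in range(3)]
        curve = volume_vs_fn_curve(maps, labels)
        assert curve.fn_rate[0] == 0.0 and curve.volume_fraction[0] == 1.0
        assert curve.fn_rate[-1] == 1.0 and curve.volume_fraction[-1] == 0.0

    def test_monotonicity(self):
        rng = np.random.default_rng(1)
        maps = [ScoreMap(k=4, scores=rng.random(64)) for _ in range(5)]
        labels = [(rng.random(64) < 0.05).astype(int) for _ in range(5)]
        labels[0][0] = 1
        curve = volume_vs_fn_curve(maps, labels)
        assert np.all(np.diff(curve.fn_rate) >= -1e-12)
        assert np.all(np.diff(curve.volume_fraction) <= 1e-12)

    def test_random_scores_track_diagonal(self):
        """Under uniform random scores, E[volume fraction] = 1 - fn_rate."""
        rng = np.random.default_rng(2)
        maps = [ScoreMap(k=5, scores=rng.random(125)) for _ in range(40)]
        labels = [(rng.random(125) < 0.02).astype(int) for _ in range(40)]
        labels[0][0] = 1
        curve = volume_vs_fn_curve(maps, labels)
        gap = np.abs(curve.volume_fraction - (1.0 - curve.fn_rate))
        assert gap.mean() < 0.05

    def test_requires_a_positive(self):
        with pytest.raises(ValueError):
            volume_vs_fn_curve([ScoreMap(k=3, scores=np.zeros(27))], [np.zeros(27, int)])


class TestExpectedFalsePositives:
    def test_reference_binomial_case(self):
        mean, rounded = expected_false_positives(124, 0.14)
        assert mean == pytest.approx(17.36)
        assert rounded == 17

    @pytest.mark.parametrize("n,p,expected", [(10, 0.5, 5.0), (37, 0.0, 0.0), (0, 0.9, 0.0)])
    def test_closed_form(self, n, p, expected):
        mean, _ = expected_false_positives(n, p)
        assert mean == expected


class TestRegionAUROC:
    def test_degenerate_single_region_matches_global(self):
        # an ROI so flat along z/x it has one region per patch column is
        # impossible; instead feed all patches the same region by using a
        # grid on a tiny ROI and checking the pooled result for a region
        # that holds every positive
        roi = Box([0, 0, 0], [9, 9, 9])
        grid = partition_roi(roi, 3)
        rng = np.random.default_rng(0)
        maps = [ScoreMap(k=3, scores=rng.random(27)) for _ in range(4)]
        labels = [(rng.random(27) < 0.2).astype(int) for _ in range(4)]
        labels[0][0] = 1
        out = region_auroc(maps, labels, grid, n_bootstrap=10)
        pooled_scores = np.concatenate([m.scores for m in maps])
        pooled_labels = np.concatenate(labels)
        for region, res in out.items():
            if res is None:
                continue
            # oracle: brute-force pair counting restricted to the region
            centers = grid.centers()
            from tzs.prior import assign_region

            mask = np.tile(
                np.array([assign_region(c, roi) == region for c in centers]), 4
            )
            assert res.auroc == pytest.approx(
                auroc_pair_counting(pooled_scores[mask], pooled_labels[mask])
            )

    def test_region_without_positives_flagged(self):
        roi = Box([0, 0, 0], [9, 9, 9])
        grid = partition_roi(roi, 3)
        maps = [ScoreMap(k=3, scores=np.random.default_rng(1).random(27))]
        labels = [np.zeros(27, int)]
        labels[0][13] = 1  # only the central (umbilical) patch positive
        out = region_auroc(maps, labels, grid, n_bootstrap=10)
        assert out["hypogastric"] is None
        assert out["umbilical"] is not None


class TestScoreMapInvariants:
    def test_length_and_range_validated(self):
        with pytest.raises(ValueError):
            ScoreMap(k=3, scores=np.zeros(26))
        with pytest.raises(ValueError):
            ScoreMap(k=3, scores=np.full(27, 1.5))
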