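import numpy as np
import pytest

from oracles import pair_count_auc
from stsal import (FixationSet, SaliencyMap, auc_basic, make_fixations,
                   mean_auc, sample_saliency, shuffled_auc)
from stsal.evaluation import _auc_from_samples


def _map_from(values):
    return SaliencyMap(values=np.asarray(values, dtype=float))


def _fix(points, image_id="im"):
    return FixationSet(tuple(points), image_id=image_id)


class TestAucBasic:
    def test_constant_map_scores_exactly_half(self, rng):
        sal = _map_from(np.full((20, 30), 0.7))
        pos = make_fixations(13, (30, 20), seed=1)
        neg = make_fixations(17, (30, 20), seed=2)
        assert auc_basic(sal, pos, neg) == 0.5

    def test_perfect_separation_scores_one(self):
        v = np.zeros((10, 10))
        pos_pts = [(2.0, 3.0), (7.0, 8.0)]
        for x, y in pos_pts:
            v[int(y), int(x)] = 1.0
        sal = _map_from(v)
        assert auc_basic(sal, _fix(pos_pts), _fix([(0.0, 0.0), (5.0, 5.0)])) == 1.0

    def test_hand_listed_values_match_pair_count_oracle(self):
        v = np.array([[0.9, 0.4, 0.4, 0.7, 0.1],
                      [0.2, 0.4, 0.8, 0.3, 0.6]])
        sal = _map_from(v)
        pos = _fix([(0.0, 0.0), (1.0, 0.0), (2.0, 1.0), (3.0, 0.0), (4.0, 1.0)])
        neg = _fix([(4.0, 0.0), (0.0, 1.0), (1.0, 1.0), (2.0, 0.0), (3.0, 1.0)])
        pos_v = [v[int(y), int(x)] for x, y in pos.points]
        neg_v = [v[int(y), int(x)] for x, y in neg.points]
        assert auc_basic(sal, pos, neg) == pytest.approx(
            pair_count_auc(pos_v, neg_v), abs=1e-12)

    def test_random_samples_match_oracle_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(100):
            npos = int(rng.integers(1, 9))
            nneg = int(rng.integers(1, 9))
            pos = rng.choice(np.linspace(0, 1, 7), npos)
            neg = rng.choice(np.linspace(0, 1, 7), nneg)
            ours = _auc_from_samples(pos, neg)
            assert ours == pytest.approx(pair_count_auc(pos, neg), abs=1e-12)
            labels = np.r_[np.ones(npos), np.zeros(nneg)]
            assert ours == pytest.approx(
                roc_auc_score(labels, np.r_[pos, neg]), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        v = rng.uniform(0, 1, (16, 16))
        pos = make_fixations(10, (16, 16), seed=3)
        neg = make_fixations(10, (16, 16), seed=4)
        a1 = auc_basic(_map_from(v), pos, neg)
        a2 = auc_basic(_map_from(np.exp(3 * v)), pos, neg)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_reversed_map_reflects_auc(self, rng):
        # tie-free values: distinct saliency at every pixel
        v = rng.permutation(16 * 16).reshape(16, 16) / (16 * 16)
        pos = make_fixations(10, (16, 16), seed=5)
        neg = make_fixations(10, (16, 16), seed=6)
        a = auc_basic(_map_from(v), pos, neg)
        b = auc_basic(_map_from(1 - v), pos, neg)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_out_of_bounds_fixation_named_in_error(self):
        sal = _map_from(np.zeros((10, 10)))
        with pytest.raises(ValueError, match="99"):
            auc_basic(sal, _fix([(99.0, 1.0)]), _fix([(1.0, 1.0)]))

    def test_native_coordinates_are_rescaled(self):
        v = np.zeros((10, 10))
        v[5, 5] = 1.0
        sal = _map_from(v)
        # fixation at the center of a 100×100 native image hits (5,5)
        pos = _fix([(50.0, 50.0)])
        neg = _fix([(5.0, 5.0)])
        assert auc_basic(sal, pos, neg, native_size=(100, 100)) == 1.0


class TestShuffledAuc:
    def test_constant_map_is_exactly_half_for_any_pool(self, rng):
        sal = _map_from(np.full((20, 20), 0.3))
        fix = make_fixations(7, (20, 20), seed=0, image_id="a")
        pool = [make_fixations(9, (20, 20), seed=s) for s in (1, 2, 3)]
        for seed in (0, 99):
            res = shuffled_auc(sal, fix, pool, n_shuffles=5, seed=seed)
            assert res.auc == 0.5

    def test_indicator_map_with_disjoint_pool_scores_one(self):
        v = np.zeros((10, 10))
        pts = [(2.0, 2.0), (7.0, 3.0)]
        for x, y in pts:
            v[int(y), int(x)] = 1.0
        pool = [_fix([(0.0, 0.0), (9.0, 9.0)], "other")]
        res = shuffled_auc(_map_from(v), _fix(pts), pool, n_shuffles=4, seed=1)
        assert res.auc == 1.0

    def test_deterministic_for_fixed_seed(self, rng):
        sal = _map_from(rng.uniform(0, 1, (20, 20)))
        fix = make_fixations(8, (20, 20), seed=10)
        pool = [make_fixations(8, (20, 20), seed=s) for s in (11, 12)]
        a = shuffled_auc(sal, fix, pool, n_shuffles=10, seed=5)
        b = shuffled_auc(sal, fix, pool, n_shuffles=10, seed=5)
        assert a.auc == b.auc

    def test_empty_pool_rejected(self, rng):
        sal = _map_from(rng.uniform(0, 1, (20, 20)))
        fix = make_fixations(8, (20, 20), seed=10)
        with pytest.raises(ValueError):
            shuffled_auc(sal, fix, [], n_shuffles=5, seed=0)

    def test_center_bias_correction_lowers_auc(self):
        """Centered-Gaussian saliency + center-biased fixations: negatives
        shuffled from other images share the bias, so the shuffled AUC must
        fall below the uniform-negative AUC."""
        w, h = 80, 60
        yy, xx = np.mgrid[:h, :w]
        sal = _map_from(np.exp(-(((xx - w / 2) ** 2 + (yy - h / 2) ** 2)
                                 / (2 * 15.0**2))))
        fixes = [make_fixations(20, (w, h), seed=100 + i, center_sigma=12.0,
                                image_id=f"im{i}") for i in range(20)]
        basic, shuffled = [], []
        for i, fix in enumerate(fixes):
            neg = make_fixations(20, (w, h), seed=500 + i)
            basic.append(auc_basic(sal, fix, neg))
            others = fixes[:i] + fixes[i + 1:]
            shuffled.append(shuffled_auc(sal, fix, others, n_shuffles=20,
                                         seed=i).auc)
        assert np.mean(shuffled) < np.mean(basic)


class TestMeanAuc:
    def test_mean_over_results(self):
        from stsal import AUCResult
        rs = [AUCResult("a", 0.6, 5, 5, 1, 0), AUCResult("b", 0.8, 5, 5, 1, 0)]
        assert mean_auc(rs) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_auc([])

    def test_result_validates_range(self):
        from stsal import AUCResult
        with pytest.raises(ValueError):
            AUCResult("a", 1.2, 5, 5, 1, 0)
        with pytest.raises(ValueError):
            AUCResult("a", 0.5, 0, 5, 1, 0)


class TestSampling:
    def test_nearest_pixel_lookup(self):
        v = np.arange(12, dtype=float).reshape(3, 4)
        sal = _map_from(v)
        vals = sample_saliency(sal, _fix([(1.4, 0.6), (2.6, 1.5)]))
        assert vals[0] == v[1, 1]
        assert vals[1] == v[2, 3]

    def test_empty_fixation_set_rejected(self):
        with pytest.raises(ValueError):
            sample_saliency(_map_from(np.zeros((4, 4))), _fix([]))
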