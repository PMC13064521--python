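"""Feature extraction, under-sampling, boosting training, scoring, thresholds."""

import numpy as np
import pytest

from somacall import somatic_model as sm
from somacall.msa_variants import CandidateVariant
from somacall.realign_genotype import AlleleSupport, SampleSupport


def _variant(vtype="SNV", length=0):
    return CandidateVariant("chr1", 10, "A", "G", vtype, length, (0, 0), None, ["hap1"])


def _support(alt_t=10, depth_t=40, alt_n=1, depth_n=50):
    sup = AlleleSupport(
        tumor=SampleSupport(ref_fwd=(depth_t - alt_t) // 2, ref_rev=(depth_t - alt_t + 1) // 2,
                            alt_fwd=alt_t // 2, alt_rev=(alt_t + 1) // 2, depth=depth_t),
        normal=SampleSupport(ref_fwd=(depth_n - alt_n) // 2, ref_rev=(depth_n - alt_n + 1) // 2,
                             alt_fwd=alt_n // 2, alt_rev=(alt_n + 1) // 2, depth=depth_n),
    )
    return sup


class TestExtractFeatures:
    def test_abs_vaf_diff_arithmetic(self):
        x = sm.extract_features(_variant(), _support(10, 40, 1, 50), {})
        idx = sm.FEATURE_NAMES.index("abs_vaf_diff")
        assert x[idx] == pytest.approx(abs(10 / 40 - 1 / 50))

    def test_balanced_strand_bias(self):
        sup = _support(alt_t=10)
        x = sm.extract_features(_variant(), sup, {})
        assert x[sm.FEATURE_NAMES.index("strand_bias_tumor")] == 0.5

    def test_zero_denominator_sentinels(self):
        sup = AlleleSupport(tumor=SampleSupport(alt_fwd=5, ref_fwd=15, depth=20),
                            normal=SampleSupport())
        x = sm.extract_features(_variant(), sup, {})
        assert x[sm.FEATURE_NAMES.index("abs_vaf_diff")] == pytest.approx(0.25)
        assert x[sm.FEATURE_NAMES.index("strand_bias_normal")] == 0.0


class TestUndersample:
    def test_exact_ratio(self):
        labels = np.r_[np.ones(50), np.zeros(10_000)]
        keep = sm.undersample(labels, neg_per_pos=30, seed=1)
        kept = labels[keep]
        assert kept.sum() == 50 and (kept == 0).sum() == 1500

    def test_shortage_keeps_everything(self):
        labels = np.r_[np.ones(50), np.zeros(1000)]
        keep = sm.undersample(labels, neg_per_pos=30, seed=1)
        assert len(keep) == 1050

    def test_deterministic_per_seed(self):
        labels = np.r_[np.ones(10), np.zeros(500)]
        a = sm.undersample(labels, 5, seed=7)
        b = sm.undersample(labels, 5, seed=7)
        assert np.array_equal(a, b)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            sm.undersample(np.zeros(100), 30, 1)


class TestTrain:
    def test_toy_problem_auroc_and_feature_importance(self, toy_model):
        model, X, y = toy_model
        held_X, held_y = X[2000:], y[2000:]
        probs = np.array([sm.score(model, x) for x in held_X])
        order = np.argsort(probs)
        ranks = np.empty(len(probs))
        ranks[order] = np.arange(len(probs))
        pos, neg = ranks[held_y == 1], ranks[held_y == 0]
        auroc = (pos.mean() - (len(pos) - 1) / 2) / len(neg)
        assert auroc > 0.95
        ranges = [s.max() - s.min() for s in model.shapes]
        assert int(np.argmax(ranges)) == 0

    def test_constant_feature_flat_shape(self):
        rng = np.random.default_rng(3)
        X = rng.random((400, 3))
        X[:, 2] = 1.0
        y = (X[:, 0] > 0.5).astype(int)
        model = sm.train(X, y, rounds=40, seed=3)
        assert model.shapes[2].max() - model.shapes[2].min() < 1e-8

    def test_same_seed_identical_model(self):
        rng = np.random.default_rng(4)
        X = rng.random((300, 4))
        y = (X[:, 1] > 0.4).astype(int)
        m1 = sm.train(X, y, rounds=30, seed=4)
        m2 = sm.train(X, y, rounds=30, seed=4)
        assert m1.to_dict() == m2.to_dict()

    def test_training_loss_monotone(self):
        rng = np.random.default_rng(5)
        X = rng.random((500, 5))
        y = ((X[:, 0] + 0.3 * rng.standard_normal(500)) > 0.5).astype(int)
        hist = []
        sm.train(X, y, rounds=60, seed=5, loss_history=hist)
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((50, 2))
        with pytest.raises(ValueError):
            sm.train(X, np.zeros(50), rounds=5)

    def test_shape_recovery_on_additive_data(self):
        """Fitted shapes correlate > 0.9 with the true step functions."""
        rng = np.random.default_rng(11)
        n = 5000
        X = rng.random((n, 4))
        f0 = np.where(X[:, 0] > 0.5, 1.5, -1.5)
        f1 = np.where(X[:, 1] > 0.3, -1.0, 1.0)
        logit = f0 + f1
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        model = sm.train(X, y, rounds=120, seed=11)
        for f, truth_fn in [(0, lambda v: np.where(v > 0.5, 1.5, -1.5)),
                            (1, lambda v: np.where(v > 0.3, -1.0, 1.0))]:
            grid = np.linspace(0.01, 0.99, 50)
            fitted = np.array([model.shapes[f][model.bin_index(f, v)] for v in grid])
            truth = truth_fn(grid)
            corr = np.corrcoef(fitted, truth)[0, 1]
            assert corr > 0.9


class TestScoreExplain:
    def test_score_in_unit_interval(self, toy_model):
        model, X, _ = toy_model
        probs = [sm.score(model, x) for x in X[:1000]]
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_additivity_exact(self, toy_model):
        model, X, _ = toy_model
        for x in X[:50]:
            ex = sm.explain(model, x)
            total = ex["intercept"] + sum(ex["contributions"].values())
            assert abs(total - ex["logit"]) <= 1e-9
            assert sm.score(model, x) == ex["probability"]

    def test_informative_feature_ranks_first(self, toy_model):
        model, X, y = toy_model
        tops = []
        for x in X[:100]:
            ex = sm.explain(model, x)
            tops.append(max(ex["contributions"], key=lambda k: abs(ex["contributions"][k])))
        assert max(set(tops), key=tops.count) == "f0"

    def test_wrong_feature_count_rejected(self, toy_model):
        model, _, _ = toy_model
        with pytest.raises(ValueError):
            sm.score(model, np.zeros(3))


class TestThresholds:
    @pytest.mark.parametrize(
        "p,vtype,expected",
        [
            (0.92, "SNV", "PASS"),
            (0.92, "DEL", "LowScore"),
            (0.95, "INS", "PASS"),
            (0.90, "SNV", "PASS"),
            (0.8999, "SNV", "LowScore"),
            (0.9499, "DEL", "LowScore"),
            (0.92, "MNV", "PASS"),
        ],
    )
    def test_type_specific_cutoffs(self, p, vtype, expected):
        assert sm.apply_threshold(p, vtype) == expected

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            sm.apply_threshold(1.2, "SNV")
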