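import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abhumanize.ab_sequence import Chain, is_framework
from abhumanize.humanness_classifier import (
    ScoreReport,
    ThresholdMetrics,
    auc_score,
    calibrate_threshold,
    classify_chain_type,
    classify_pair,
    classify_sequence,
    feature_importance,
    mcc_threshold,
    roc_auc,
    split_dataset,
    train_chain_type_model,
    train_model,
    youden_threshold,
)
from abhumanize.repertoire_sim import signature_position_numbers


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_youden(scores, labels):
    """Exhaustive YJS maximum over every cutpoint (all midpoints + sentinels)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    distinct = np.unique(scores)
    candidates = np.concatenate([[0.0, 1.0], (distinct[:-1] + distinct[1:]) / 2.0])
    best = -np.inf
    for tau in candidates:
        pred = scores > tau
        sens = np.sum(pred & (labels == 1)) / np.sum(labels == 1)
        spec = np.sum(~pred & (labels == 0)) / np.sum(labels == 0)
        best = max(best, sens + spec - 1.0)
    return best


def pairwise_auc(scores, labels):
    """O(n^2) pairwise AUC oracle, ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# split_dataset
# ---------------------------------------------------------------------------

class TestSplit:
    def test_sizes_10(self):
        seqs = list(range(10))
        labels = [1] * 5 + [0] * 5
        s = split_dataset(seqs, labels, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (8, 1, 1)

    def test_deterministic(self, heavy_repertoire):
        labels = [1 if x.species == "human" else 0 for x in heavy_repertoire]
        a = split_dataset(heavy_repertoire, labels, seed=4)
        b = split_dataset(heavy_repertoire, labels, seed=4)
        assert [s.id for s in a.train] == [s.id for s in b.train]
        assert [s.id for s in a.test] == [s.id for s in b.test]

    def test_partitions_disjoint_union(self, heavy_repertoire):
        labels = [1 if x.species == "human" else 0 for x in heavy_repertoire]
        s = split_dataset(heavy_repertoire, labels, seed=4)
        ids = [x.id for part in (s.train, s.validation, s.test) for x in part]
        assert sorted(ids) == sorted(x.id for x in heavy_repertoire)

    def test_stratification(self, heavy_repertoire):
        labels = np.array([1 if x.species == "human" else 0 for x in heavy_repertoire])
        s = split_dataset(heavy_repertoire, labels, seed=4)
        global_frac = labels.mean()
        train_frac = s.train_labels.mean()
        # within 1 record of global proportion
        assert abs(train_frac - global_frac) <= 1.0 / len(s.train)

    def test_bad_fractions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_dataset([1, 2], [0, 1], fractions=(0.5, 0.2, 0.2))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# Training and scoring
# ---------------------------------------------------------------------------

class TestTrain:
    def test_separable_training_scores(self, v1_model, heavy_split):
        pos = [s for s, l in zip(heavy_split.train, heavy_split.train_labels)
               if l == 1 and s.v_gene == "V1"]
        neg = [s for s, l in zip(heavy_split.train, heavy_split.train_labels) if l == 0]
        pos_scores = v1_model.score_many(pos[:30])
        neg_scores = v1_model.score_many(neg[:30])
        assert pos_scores.min() > neg_scores.max()

    def test_germline_ordering(self, v1_model, germlines):
        human = next(g for g in germlines if g.v_gene == "V1").to_sequence("h")
        mouse = next(g for g in germlines if g.species == "mouse" and g.chain == Chain.HEAVY).to_sequence("m")
        assert v1_model.score(human) > v1_model.score(mouse)

    def test_scores_in_unit_interval(self, v1_model, heavy_repertoire):
        scores = v1_model.score_many(heavy_repertoire[:50])
        assert np.all((scores >= 0) & (scores <= 1))

    def test_scoring_deterministic(self, v1_model, heavy_repertoire):
        a = v1_model.score_many(heavy_repertoire[:20])
        b = v1_model.score_many(heavy_repertoire[:20])
        assert np.array_equal(a, b)

    def test_single_estimator_allowed(self, heavy_split):
        pos = [s for s, l in zip(heavy_split.train, heavy_split.train_labels) if l == 1][:20]
        neg = [s for s, l in zip(heavy_split.train, heavy_split.train_labels) if l == 0][:20]
        m = train_model(pos, neg, n_estimators=1, seed=0)
        assert 0.0 <= m.score(pos[0]) <= 1.0

    def test_single_class_rejected(self, heavy_split):
        pos = [s for s, l in zip(heavy_split.train, heavy_split.train_labels) if l == 1][:10]
        with pytest.raises(ValueError, match="non-empty"):
            train_model(pos, [], seed=0)

    def test_chain_mismatch_on_score(self, v1_model, kappa_repertoire):
        with pytest.raises(ValueError, match="chain mismatch"):
            v1_model.score(kappa_repertoire[0])


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

class TestYouden:
    def test_separable_case(self):
        scores = [0.9, 0.8, 0.1, 0.2]
        labels = [1, 1, 0, 0]
        tau, metrics = youden_threshold(scores, labels)
        assert metrics.youden_j == 1.0
        assert metrics.sensitivity == 1.0 and metrics.specificity == 1.0
        # smallest candidate cutpoint attaining YJS=1 is midpoint(0.2, 0.8)
        assert tau == pytest.approx(0.5)

    def test_yjs_identity(self):
        m = ThresholdMetrics(threshold=0.5, sensitivity=1.0, specificity=1.0, youden_j=1.0, mcc=1.0)
        assert m.youden_j == m.sensitivity + m.specificity - 1.0
        with pytest.raises(ValueError, match="identity"):
            ThresholdMetrics(threshold=0.5, sensitivity=0.9, specificity=0.9, youden_j=0.5, mcc=0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, width=32), min_size=4, max_size=50),
           st.randoms(use_true_random=False))
    def test_equals_bruteforce_oracle(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        _, metrics = youden_threshold(scores, labels)
        assert metrics.youden_j == pytest.approx(brute_force_youden(scores, labels))

    def test_ties_break_small(self):
        # any tau in (0.2, 0.8) attains YJS=1; candidates are midpoints ->
        # smallest winning candidate must be returned
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        tau, _ = youden_threshold(scores, labels)
        candidates = [0.0, 0.15, 0.5, 0.85, 1.0]
        winning = [c for c in candidates if 0.2 <= c < 0.8]
        assert tau == min(winning)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            youden_threshold([0.1, 0.2], [1, 1])

    def test_calibrate_sets_threshold(self, v1_model):
        assert v1_model.threshold is not None
        assert 0.0 <= v1_model.threshold <= 1.0

    def test_mcc_threshold_close_to_yjs(self, heavy_split, v1_model):
        scores = v1_model.score_many(heavy_split.validation)
        tau_y, _ = youden_threshold(scores, heavy_split.validation_labels)
        tau_m = mcc_threshold(scores, heavy_split.validation_labels)
        # soft check: reported, not asserted at a tight tolerance
        print(f"YJS-optimal tau={tau_y:.4f} MCC-optimal tau={tau_m:.4f} diff={abs(tau_y-tau_m):.4f}")


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.permutation([1] * 1000 + [0] * 1000)
        assert abs(auc_score(scores, labels) - 0.5) < 0.05

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(0, 1, width=16), min_size=4, max_size=100),
           st.randoms(use_true_random=False))
    def test_equals_pairwise_oracle(self, scores, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert auc_score(scores, labels) == pytest.approx(pairwise_auc(scores, labels))

    def test_model_roc_auc(self, v1_model, heavy_split):
        auc = roc_auc(v1_model, heavy_split.test, heavy_split.test_labels)
        assert auc > 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_score([0.1, 0.2], [0, 0])


# ---------------------------------------------------------------------------
# Classification rules
# ---------------------------------------------------------------------------

class FakeModel:
    def __init__(self, chain, v_gene, score, threshold):
        self.chain = chain
        self.v_gene = v_gene
        self._score = score
        self.threshold = threshold

    def score(self, seq):
        return self._score


class TestClassify:
    def test_any_model_above_threshold(self, heavy_repertoire):
        seq = heavy_repertoire[0]
        below = FakeModel(Chain.HEAVY, "V1", 0.2, 0.5)
        above = FakeModel(Chain.HEAVY, "V3", 0.9, 0.5)
        assert classify_sequence([below, above], seq).is_human is True
        assert classify_sequence([below], seq).is_human is False

    def test_score_equal_to_threshold_not_human(self, heavy_repertoire):
        seq = heavy_repertoire[0]
        at = FakeModel(Chain.HEAVY, "V1", 0.5, 0.5)
        assert classify_sequence([at], seq).is_human is False

    def test_best_model(self, heavy_repertoire):
        seq = heavy_repertoire[0]
        m1 = FakeModel(Chain.HEAVY, "V1", 0.2, 0.5)
        m2 = FakeModel(Chain.HEAVY, "V3", 0.4, 0.5)
        assert classify_sequence([m1, m2], seq).best_model == ("heavy", "V3")

    def test_chain_mismatch(self, kappa_repertoire):
        m = FakeModel(Chain.HEAVY, "V1", 0.2, 0.5)
        with pytest.raises(ValueError, match="chain mismatch"):
            classify_sequence([m], kappa_repertoire[0])

    @pytest.mark.parametrize("vh,vl,expected", [(True, True, True), (True, False, False),
                                                (False, True, False), (False, False, False)])
    def test_pair_conjunction(self, vh, vl, expected):
        rh = ScoreReport("h", Chain.HEAVY, {}, {}, ("heavy", "V1"), vh)
        rl = ScoreReport("l", Chain.KAPPA, {}, {}, ("kappa", "KV1"), vl)
        assert classify_pair(rh, rl) is expected

    def test_pair_requires_heavy_and_light(self):
        rh = ScoreReport("a", Chain.HEAVY, {}, {}, ("heavy", "V1"), True)
        rh2 = ScoreReport("b", Chain.HEAVY, {}, {}, ("heavy", "V3"), True)
        with pytest.raises(ValueError, match="one heavy and one light"):
            classify_pair(rh, rh2)


# ---------------------------------------------------------------------------
# Chain-type classifier
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def chain_type_model(kappa_repertoire, lambda_repertoire):
    kappa = [s for s in kappa_repertoire if s.species == "human"]
    lam = [s for s in lambda_repertoire if s.species == "human"]
    return train_chain_type_model(kappa[:80], lam[:80], n_estimators=30, seed=5)


class TestChainType:
    def test_held_out_kappa(self, chain_type_model, kappa_repertoire):
        held = [s for s in kappa_repertoire if s.species == "human"][80:100]
        assert all(classify_chain_type(chain_type_model, s) == Chain.KAPPA for s in held)

    def test_held_out_lambda(self, chain_type_model, lambda_repertoire):
        held = [s for s in lambda_repertoire if s.species == "human"][80:100]
        assert all(classify_chain_type(chain_type_model, s) == Chain.LAMBDA for s in held)

    def test_heavy_rejected(self, chain_type_model, heavy_repertoire):
        with pytest.raises(ValueError, match="light chains only"):
            chain_type_model.score(heavy_repertoire[0])
        with pytest.raises(ValueError, match="light chains"):
            classify_chain_type(chain_type_model, heavy_repertoire[0])

    def test_heavy_training_input_rejected(self, heavy_repertoire, kappa_repertoire):
        with pytest.raises(ValueError, match="light chains"):
            train_chain_type_model(kappa_repertoire[:5], heavy_repertoire[:5])


# ---------------------------------------------------------------------------
# Feature importance
# ---------------------------------------------------------------------------

class TestFeatureImportance:
    def test_importances_sum_to_one(self, v1_model):
        total = v1_model.forest.feature_importances_.sum()
        assert total == pytest.approx(1.0)

    def test_top_features_at_signature_positions(self, v1_model):
        top = feature_importance(v1_model, top_k=12)
        signature = set(signature_position_numbers(12))
        hits = sum(1 for f in top if f.position.number in signature)
        assert hits >= 8

    def test_majority_in_framework(self, v1_model):
        top = feature_importance(v1_model, top_k=10)
        assert sum(1 for f in top if f.in_framework) > 5

    def test_frequencies_in_unit_interval(self, v1_model):
        for f in feature_importance(v1_model, top_k=10):
            assert 0.0 <= f.frequency_positive <= 1.0
            assert 0.0 <= f.frequency_negative <= 1.0

    def test_top_k_validation(self, v1_model):
        with pytest.raises(ValueError):
            feature_importance(v1_model, top_k=0)
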