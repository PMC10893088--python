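"""Loss oracles, gradients, and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hypermda as h


class TestDiceLoss:
    def test_closed_form_examples(self):
        # X=1.4, U=3.04 -> 1 - 2.4/2.64
        assert h.dice_loss([0.8, 0.2, 0.6], [1, 0, 1], epsilon=1.0) == pytest.approx(
            1.0 - 2.4 / 2.64, abs=1e-12
        )
        # X=0.5, U=1.5 -> 1 - 1.5/2
        assert h.dice_loss([0.5, 0.5], [1, 0], epsilon=1.0) == pytest.approx(0.25, abs=1e-12)

    def test_perfect_prediction_limit(self):
        loss = h.dice_loss([1 - 1e-12], [1], epsilon=1.0)
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_classic_dice_form(self):
        q, t = [0.8, 0.2, 0.6], [1, 0, 1]
        # 1 - (2X+eps)/(U+eps) = 1 - 3.8/4.04
        assert h.dice_loss(q, t, epsilon=1.0, form="classic_dice") == pytest.approx(
            1.0 - 3.8 / 4.04, abs=1e-12
        )

    def test_monotone_in_predictions(self):
        rng = np.random.default_rng(0)
        q = rng.uniform(0.05, 0.95, size=12)
        t = rng.integers(0, 2, size=12).astype(float)
        t[0], t[1] = 1.0, 0.0
        base = h.dice_loss(q, t)
        up = q.copy()
        up[0] += 0.01  # raise a positive's score -> loss falls
        assert h.dice_loss(up, t) < base
        up = q.copy()
        up[1] += 0.01  # raise a negative's score -> loss rises
        assert h.dice_loss(up, t) > base

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_gradient_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 20))
        q = rng.uniform(0.05, 0.95, size=n)
        t = rng.integers(0, 2, size=n).astype(float)
        for form in ("as_printed", "classic_dice"):
            grad = h.dice_loss_grad(q, t, form=form)
            eps = 1e-6
            for i in range(n):
                qp, qm = q.copy(), q.copy()
                qp[i] += eps
                qm[i] -= eps
                num = (h.dice_loss(qp, t, form=form) - h.dice_loss(qm, t, form=form)) / (2 * eps)
                assert grad[i] == pytest.approx(num, abs=1e-5)

    def test_rejects_out_of_range_predictions(self):
        with pytest.raises(ValueError):
            h.dice_loss([0.0, 0.5], [1, 0])
        with pytest.raises(ValueError):
            h.dice_loss([0.5], [2])


class TestBCELoss:
    def test_half_probability_gives_log_two(self):
        assert h.bce_loss([0.5], [1]) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_confident_correct_predictions_vanish(self):
        assert h.bce_loss([1 - 1e-12, 1e-12], [1, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_element_loop(self):
        rng = np.random.default_rng(1)
        q = rng.uniform(0.01, 0.99, size=25)
        t = rng.integers(0, 2, size=25).astype(float)
        manual = -np.mean([
            ti * np.log(qi) + (1 - ti) * np.log(1 - qi) for qi, ti in zip(q, t)
        ])
        assert h.bce_loss(q, t) == pytest.approx(manual, abs=1e-12)


def brute_force_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_separation(self):
        report = h.compute_metrics([0.9, 0.1], [1, 0])
        assert report.auc == 1.0
        assert report.accuracy == 1.0
        assert report.f1 == 1.0

    def test_auc_matches_all_pairs_count(self):
        rng = np.random.default_rng(2)
        scores = np.round(rng.random(30), 2)  # rounding forces some ties
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        report = h.compute_metrics(scores, labels)
        assert report.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, size=2000)
        report = h.compute_metrics(scores, labels)
        assert 0.45 <= report.auc <= 0.55

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        a = h.compute_metrics(scores, labels)
        b = h.compute_metrics(1 / (1 + np.exp(-5 * scores)), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.auprc == pytest.approx(b.auprc, abs=1e-12)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            h.compute_metrics([0.2, 0.4], [1, 1])

    def test_pair_score_input_accepted(self):
        scores = [h.PairScore("m0", "d0", 0.9), h.PairScore("m1", "d0", 0.2)]
        report = h.compute_metrics(scores, [1, 0])
        assert report.auc == 1.0
        assert report.n_pos == 1 and report.n_neg == 1
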