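"""The trainable time-series combination network: discounting, the two
combination layers, the regularized loss, gradients, and training."""

import dataclasses

import numpy as np
import pytest

import evifuse as ev
from evifuse.evidence_theory import BPA
from evifuse.ts_combination import (
    CombinationWeights,
    CombinerConfig,
    combination_loss,
    combiner_gradient,
    discount_row,
    expanded_label,
    inter_combine,
    intra_combine,
    predict,
    predict_stream,
    train_combiner,
)


def random_revised_stream(rng, T, n):
    """Random valid revised-evidence rows: support, complement, uncertainty."""
    stream = np.zeros((T, n, n + 2))
    for i in range(n):
        triples = rng.dirichlet(np.ones(3), size=T)
        stream[:, i, i] = triples[:, 0]
        stream[:, i, n] = triples[:, 1]
        stream[:, i, n + 1] = triples[:, 2]
    return stream


class TestDiscountRow:
    def test_unit_weights_leave_row_unchanged(self):
        row = np.array([0.63, 0.0, 0.16, 0.21])
        np.testing.assert_allclose(discount_row(row, np.ones(4)), row)

    def test_worked_half_weights(self):
        row = np.array([0.63, 0.0, 0.16, 0.21])
        w = np.array([0.5, 0.5, 0.5, 1.0])
        np.testing.assert_allclose(discount_row(row, w), [0.315, 0.0, 0.08, 0.605])

    def test_tiny_weights_drive_to_ignorance(self):
        row = np.array([0.63, 0.0, 0.16, 0.21])
        w = np.array([1e-9, 1e-9, 1e-9, 1.0])
        out = discount_row(row, w)
        assert out[-1] == pytest.approx(1.0, abs=1e-8)

    def test_mass_conservation_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 7))
            row = rng.dirichlet(np.ones(n + 2))
            w = np.append(rng.uniform(0.01, 1.0, n + 1), 1.0)
            assert discount_row(row, w).sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_weights_error(self):
        row = np.array([0.5, 0.3, 0.2])
        with pytest.raises(ValueError):
            discount_row(row, np.array([1.2, 1.0, 1.0]))
        with pytest.raises(ValueError):
            discount_row(row, np.array([0.5, 0.5, 0.9]))  # last not pinned at 1


class TestIntraCombine:
    def test_single_interval_equals_discounted_row(self, frame6):
        row = np.zeros(8)
        row[0], row[6], row[7] = 0.6, 0.1, 0.3
        w = np.ones(8)
        b = intra_combine([row], w[None], 1, frame6)
        assert b.mass(frame6.singleton(1)) == pytest.approx(0.6)

    def test_two_identical_rows_reinforce(self, frame6):
        row = np.zeros(8)
        row[0], row[6], row[7] = 0.6, 0.1, 0.3
        b = intra_combine([row, row], np.ones((2, 8)), 1, frame6)
        assert b.mass(frame6.singleton(1)) == pytest.approx(0.72 / 0.88)
        assert b.mass(frame6.complement(1)) == pytest.approx(0.07 / 0.88)
        assert b.mass(frame6.theta) == pytest.approx(0.09 / 0.88)

    def test_focal_support_closed(self, frame6):
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(4):
            r = np.zeros(8)
            r[2], r[6], r[7] = rng.dirichlet(np.ones(3))
            rows.append(r)
        b = intra_combine(rows, np.ones((4, 8)), 3, frame6)
        allowed = {frame6.singleton(3), frame6.complement(3), frame6.theta}
        assert set(b.masses) <= allowed

    def test_empty_history_errors(self, frame6):
        with pytest.raises(ValueError, match="empty"):
            intra_combine([], np.ones((0, 8)), 1, frame6)


class TestInterCombine:
    def test_one_confident_rest_vacuous(self, frame6):
        bpas = [BPA.vacuous(frame6) for _ in range(6)]
        bpas[2] = BPA(frame6, {frame6.singleton(3): 0.95, frame6.theta: 0.05})
        ef = inter_combine(bpas, np.ones(6), None, frame6)
        assert predict(ef) == 3
        assert ef.bpa.mass(frame6.singleton(3)) == pytest.approx(0.95)

    def test_three_supports_argmax_is_strongest(self):
        frame = ev.ActivityFrame(3)
        bpas = [
            BPA(frame, {frame.singleton(i): s, frame.theta: 1 - s})
            for i, s in zip((1, 2, 3), (0.8, 0.1, 0.1))
        ]
        ef = inter_combine(bpas, np.ones(3), None, frame)
        assert predict(ef) == 1

    def test_theta_zero_filters_everything(self, frame6):
        bpas = [
            BPA(frame6, {frame6.singleton(i + 1): 0.7, frame6.theta: 0.3})
            for i in range(6)
        ]
        with pytest.warns(UserWarning, match="filtered"):
            ef = inter_combine(bpas, np.ones(6), 0.0, frame6)
        assert ef.low_confidence and ef.bpa.is_vacuous


class TestLossAndPredict:
    def test_perfect_evidence_zero_loss(self, frame6):
        ef = ev.FinalEvidence(BPA(frame6, {frame6.singleton(2): 1.0}))
        assert combination_loss(ef, 2) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_evidence_loss_ln_n(self, frame6):
        ef = ev.FinalEvidence(
            BPA(frame6, {frame6.singleton(i): 1 / 6 for i in range(1, 7)})
        )
        assert combination_loss(ef, 4) == pytest.approx(np.log(6))

    def test_penalty_term_added_exactly(self, frame6):
        cfg = CombinerConfig(history=(1,) * 6)
        w = CombinationWeights.zeros(cfg)  # mapped weights all 0.5
        ef = ev.FinalEvidence(BPA(frame6, {frame6.singleton(1): 1.0}))
        # 6 inter weights + 6*2 active intra weights, each 0.25 squared-mapped
        expected = 0.1 * (6 + 12) * 0.25
        assert combination_loss(ef, 1, w, lambda2=0.1) == pytest.approx(expected)

    def test_expanded_label_sizes(self, frame6):
        assert expanded_label(2, frame6).shape == (7,)
        assert expanded_label(2, frame6, powerset=True).shape == (63,)
        assert expanded_label(2, frame6).sum() == 1.0

    def test_predict_tie_breaks_low_and_vacuous_flags(self, frame6):
        tie = ev.FinalEvidence(
            BPA(frame6, {frame6.singleton(1): 0.4, frame6.singleton(2): 0.4,
                         frame6.theta: 0.2})
        )
        assert predict(tie) == 1
        vac = ev.FinalEvidence(BPA.vacuous(frame6))
        assert predict(vac) == 1
        assert vac.low_confidence


class TestBatchedForwardConsistency:
    """The vectorized training path must agree with the per-window
    reference path built from BPA objects."""

    @pytest.mark.parametrize("theta", [None, 0.6])
    def test_predictions_and_masses_agree(self, theta):
        rng = np.random.default_rng(5)
        n, T = 4, 40
        stream = random_revised_stream(rng, T, n)
        cfg = CombinerConfig(history=(2, 1, 0, 3), theta=theta, seed=0)
        weights = CombinationWeights(
            rng.normal(size=(4, 4)), rng.normal(size=4), cfg.history
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            preds, masses = predict_stream(
                stream, weights, cfg, return_masses=True
            )
        wi, we = weights.intra_weights(), weights.inter_weights()
        frame = ev.ActivityFrame(n)
        for t in range(T):
            intra = []
            for i in range(1, n + 1):
                rows, wrows = [], []
                for d in range(cfg.history[i - 1] + 1):
                    if t - d < 0:
                        break
                    rows.append(stream[t - d, i - 1])
                    w = np.ones(n + 2)
                    w[: n + 1] = wi[i - 1, d]
                    wrows.append(w)
                intra.append(intra_combine(rows, np.stack(wrows), i, frame))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ef = inter_combine(intra, we, theta, frame)
            np.testing.assert_allclose(
                masses[t, :n], ef.bpa.singleton_masses(), atol=1e-9
            )
            assert preds[t] == predict(ef)

    def test_sequence_start_uses_short_history(self):
        # vacuous padding at t < N must equal an explicit shorter fold
        rng = np.random.default_rng(9)
        stream = random_revised_stream(rng, 10, 3)
        cfg = CombinerConfig(history=(4, 4, 4), seed=0)
        preds, masses = predict_stream(stream, None, cfg, return_masses=True)
        frame = ev.ActivityFrame(3)
        intra = [
            intra_combine([stream[0, i - 1]], np.ones((1, 5)), i, frame)
            for i in range(1, 4)
        ]
        ef = inter_combine(intra, np.ones(3), None, frame)
        np.testing.assert_allclose(masses[0, :3], ef.bpa.singleton_masses(), atol=1e-9)

    def test_every_interval_mass_conserved(self):
        rng = np.random.default_rng(11)
        stream = random_revised_stream(rng, 50, 5)
        cfg = CombinerConfig(history=(2,) * 5, seed=0)
        w = CombinationWeights(rng.normal(size=(5, 3)), rng.normal(size=5), cfg.history)
        _, masses = predict_stream(stream, w, cfg, return_masses=True)
        np.testing.assert_allclose(masses.sum(axis=1), 1.0, atol=1e-9)

    def test_powerset_and_merged_agree_without_complement_mass(self):
        rng = np.random.default_rng(13)
        n, T = 3, 15
        stream = np.zeros((T, n, n + 2))
        for i in range(n):
            pair = rng.dirichlet(np.ones(2), size=T)
            stream[:, i, i] = pair[:, 0]
            stream[:, i, n + 1] = pair[:, 1]  # no complement mass anywhere
        cfg = CombinerConfig(history=(1, 1, 1), seed=0)
        merged = predict_stream(stream, None, cfg)
        full = predict_stream(stream, None, cfg, merger=False)
        np.testing.assert_array_equal(merged, full)


class TestPerPositionWeights:
    def test_equal_per_position_weights_match_shared_mode(self):
        rng = np.random.default_rng(31)
        stream = random_revised_stream(rng, 30, 3)
        hist = (1, 2, 0)
        alpha = rng.normal(size=(3, 3))
        alpha_inter = rng.normal(size=3)
        shared_cfg = CombinerConfig(history=hist, seed=0)
        pp_cfg = CombinerConfig(history=hist, per_position=True, seed=0)
        w_shared = CombinationWeights(alpha, alpha_inter, hist)
        w_pp = CombinationWeights(
            np.stack([alpha, alpha], axis=-1), alpha_inter, hist, per_position=True
        )
        _, m_shared = predict_stream(stream, w_shared, shared_cfg, return_masses=True)
        _, m_pp = predict_stream(stream, w_pp, pp_cfg, return_masses=True)
        np.testing.assert_allclose(m_shared, m_pp, atol=1e-12)

    def test_per_position_gradient_matches_central_differences(self):
        rng = np.random.default_rng(33)
        stream = random_revised_stream(rng, 10, 2)
        labels = rng.integers(1, 3, 10)
        hist = (1, 1)
        cfg = CombinerConfig(history=hist, per_position=True, lambda2=0.01, seed=0)
        w = CombinationWeights(
            rng.normal(size=(2, 2, 2)), rng.normal(size=2), hist, per_position=True
        )
        _, g_intra, _ = combiner_gradient(stream, labels, w, cfg)
        eps = 1e-6
        idx = (1, 0, 1)
        up = w.alpha_intra.copy()
        up[idx] += eps
        dn = w.alpha_intra.copy()
        dn[idx] -= eps
        lp, _, _ = combiner_gradient(
            stream, labels, CombinationWeights(up, w.alpha_inter, hist, True), cfg
        )
        lm, _, _ = combiner_gradient(
            stream, labels, CombinationWeights(dn, w.alpha_inter, hist, True), cfg
        )
        assert g_intra[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


class TestReductionToMaxout:
    def test_unit_weights_single_interval_agrees_with_dominant_classifier(self):
        rng = np.random.default_rng(17)
        n, T = 4, 60
        stream = np.zeros((T, n, n + 2))
        dominant = rng.integers(0, n, T)
        for i in range(n):
            s = np.where(dominant == i, 0.9, 0.05)
            stream[:, i, i] = s
            stream[:, i, n + 1] = 1.0 - s
        cfg = CombinerConfig(history=(0,) * n, seed=0)
        preds = predict_stream(stream, None, cfg, mode="inter")
        maxout = predict_stream(stream, None, cfg, mode="maxout")
        np.testing.assert_array_equal(preds, dominant + 1)
        np.testing.assert_array_equal(preds, maxout)


class TestGradientsAndTraining:
    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(21)
        n, T = 3, 12
        stream = random_revised_stream(rng, T, n)
        labels = rng.integers(1, n + 1, T)
        cfg = CombinerConfig(history=(1, 2, 0), lambda2=0.01, seed=0)
        w = CombinationWeights(rng.normal(size=(3, 3)), rng.normal(size=3), cfg.history)
        loss, g_intra, g_inter = combiner_gradient(stream, labels, w, cfg)
        eps = 1e-6
        for idx in [(0, 0), (1, 2), (2, 0)]:
            for arr, grad in ((w.alpha_intra, g_intra),):
                wp = CombinationWeights(w.alpha_intra.copy(), w.alpha_inter.copy(), cfg.history)
                wp.alpha_intra[idx] += eps
                lp, _, _ = combiner_gradient(stream, labels, wp, cfg)
                wm = CombinationWeights(w.alpha_intra.copy(), w.alpha_inter.copy(), cfg.history)
                wm.alpha_intra[idx] -= eps
                lm, _, _ = combiner_gradient(stream, labels, wm, cfg)
                assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)

    def test_training_reduces_loss(self, frame6):
        truths = ev.activity_bouts(400, 6, bout_length=20, seed=3)
        stream, labels = ev.generate_evidence_stream(
            ev.EvidenceStreamSpec(seed=4), frame6, truths
        )
        cfg = CombinerConfig(history=(1,) * 6, epochs=40, learning_rate=0.5, seed=0)
        l0, _, _ = combiner_gradient(stream, labels, CombinationWeights.zeros(cfg), cfg)
        w = train_combiner(stream, labels, cfg)
        l1, _, _ = combiner_gradient(stream, labels, w, cfg)
        assert l1 < l0

    def test_huge_penalty_crushes_mapped_weights(self, frame6):
        truths = ev.activity_bouts(200, 6, bout_length=20, seed=5)
        stream, labels = ev.generate_evidence_stream(
            ev.EvidenceStreamSpec(seed=6), frame6, truths
        )
        cfg = CombinerConfig(
            history=(0,) * 6, epochs=60, learning_rate=0.5, lambda2=50.0, seed=0,
            val_fraction=0.05,
        )
        w = train_combiner(stream, labels, cfg)
        # the penalty is on the mapped weights, so its large-lambda2 limit
        # drives W = sigmoid(alpha) toward 0, far below the 0.5 start
        assert np.all(w.inter_weights() < 0.1)
        assert np.all(w.intra_weights() < 0.1)

    def test_stream_too_short_errors(self, frame6):
        cfg = CombinerConfig(history=(6,) * 6)
        with pytest.raises(ValueError, match="shorter"):
            train_combiner(np.zeros((5, 6, 8)), np.ones(5, dtype=int), cfg)
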