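"""One-vs-rest label coding, the LSTM subnetwork bank, and weight counting."""

import numpy as np
import pytest

import evifuse as ev
from evifuse.evidence_generation import (
    EvidenceBank,
    LSTMSubnetwork,
    SubnetworkSpec,
    build_subnetwork,
    count_weights,
    emit_evidence,
    encode_label,
)


class TestEncodeLabel:
    def test_own_activity_one_hot(self, frame6):
        z = encode_label(3, 3, frame6)
        assert z[2] == 1.0 and z.sum() == 1.0

    def test_other_activity_maps_to_complement(self, frame6):
        z = encode_label(2, 3, frame6)
        assert z[6] == 1.0 and z.sum() == 1.0

    def test_full_coding_matrix_rows_sum_to_one(self, frame6):
        for a in range(1, 7):
            mat = np.stack([encode_label(a, c, frame6) for c in range(1, 7)])
            np.testing.assert_allclose(mat.sum(axis=1), 1.0)

    def test_out_of_range_errors(self, frame6):
        with pytest.raises(ValueError):
            encode_label(7, 1, frame6)


class TestCountWeights:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            ((1, 1, 1, 1), 17),
            ((2, 2, 2, 2), 68),
            ((6, 16, 16, 7), 3568),
        ],
    )
    def test_hand_expanded_values(self, spec, expected):
        assert count_weights(SubnetworkSpec(*spec)) == expected

    def test_matches_enumeration_of_constructed_network(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            spec = SubnetworkSpec(*(int(x) for x in rng.integers(1, 30, 4)))
            net = build_subnetwork(spec, seed=0)
            # direct enumeration of weight-matrix entries; biases excluded
            enumerated = sum(
                p.value.size for name, p in net.params.items() if not name.startswith("b")
            )
            assert count_weights(spec) == enumerated


class TestSubnetwork:
    def test_forward_is_probability_vector(self):
        net = build_subnetwork(SubnetworkSpec(3, 4, 4, 5), seed=1)
        probs = net.forward(np.random.default_rng(0).normal(size=(8, 3)))
        assert probs.shape == (5,)
        assert np.all(probs >= 0)
        assert probs.sum() == pytest.approx(1.0)

    def test_same_seed_same_parameters(self):
        a = build_subnetwork(SubnetworkSpec(3, 4, 4, 5), seed=7)
        b = build_subnetwork(SubnetworkSpec(3, 4, 4, 5), seed=7)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].value, b.params[k].value)

    def test_training_is_seed_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(40, 6, 2))
        targets = np.zeros((40, 3))
        targets[np.arange(40), rng.integers(0, 3, 40)] = 1.0
        nets = []
        for _ in range(2):
            net = build_subnetwork(SubnetworkSpec(2, 3, 3, 3), seed=11)
            net.train(x, targets, learning_rate=0.2, batch_size=16, epochs=5, seed=11)
            nets.append(net)
        for k in nets[0].params:
            np.testing.assert_array_equal(nets[0].params[k].value, nets[1].params[k].value)

    def test_initial_loss_near_uniform_cross_entropy(self):
        # small random logits => near-uniform softmax => CE ~= ln(n+1)
        net = build_subnetwork(SubnetworkSpec(2, 16, 16, 3), seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(64, 10, 2))
        targets = np.zeros((64, 3))
        targets[np.arange(64), rng.integers(0, 3, 64)] = 1.0
        probs = net.forward(x)
        loss = -np.mean(np.sum(targets * np.log(probs), axis=1))
        assert loss == pytest.approx(np.log(3), abs=0.15)

    def test_single_class_data_saturates_output(self):
        net = build_subnetwork(SubnetworkSpec(2, 4, 4, 3), seed=0)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(64, 8, 2))
        targets = np.tile([1.0, 0.0, 0.0], (64, 1))
        net.train(x, targets, learning_rate=0.5, batch_size=32, epochs=40, seed=0)
        probs = net.forward(x)
        assert np.all(probs[:, 0] > 0.9)

    def test_training_loss_trend_non_increasing(self, trained_bank2):
        bank, train, _ = trained_bank2
        sub = bank.subnetworks[0]
        # retrace a short run to get the logged history
        net = build_subnetwork(sub.spec, seed=0)
        targets = np.stack([encode_label(int(l), 1, bank.frame) for l in train.labels])
        hist = net.train(
            bank._normalize(train.windows), targets,
            learning_rate=0.3, batch_size=128, epochs=12, seed=0,
        )
        first, last = hist["loss"].iloc[0], hist["loss"].iloc[-1]
        assert last < first


class TestBank:
    def test_separable_bank_binary_accuracy(self, trained_bank2):
        bank, _, test = trained_bank2
        evidence = bank.evidence_batch(test.windows)
        for i in (1, 2):
            pred = np.argmax(evidence[:, i - 1, :], axis=1) == i - 1
            truth = test.labels == i
            assert np.mean(pred == truth) > 0.9

    def test_emit_evidence_rows_and_determinism(self, trained_bank2):
        bank, _, test = trained_bank2
        m1 = emit_evidence(bank, test.windows[0])
        m2 = emit_evidence(bank, test.windows[0])
        np.testing.assert_allclose(m1.values.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_rows_match_individual_subnetworks(self, trained_bank2):
        # parallel contract: each row depends only on its own subnetwork
        bank, _, test = trained_bank2
        w = test.windows[3]
        m = emit_evidence(bank, w)
        for i, sub in enumerate(bank.subnetworks):
            np.testing.assert_allclose(m.values[i], sub.forward(bank._normalize(w)))

    def test_argmax_tracks_activity_on_separable_windows(self, trained_bank2):
        bank, _, test = trained_bank2
        evidence = bank.evidence_batch(test.windows)
        for i in (1, 2):
            own = evidence[test.labels == i, i - 1, :]
            assert np.mean(np.argmax(own, axis=1) == i - 1) > 0.9

    def test_save_load_round_trip(self, trained_bank2, tmp_path):
        bank, _, test = trained_bank2
        path = tmp_path / "bank.npz"
        bank.save(path)
        back = EvidenceBank.load(path)
        np.testing.assert_allclose(
            back.evidence_batch(test.windows[:5]), bank.evidence_batch(test.windows[:5])
        )

    def test_label_outside_frame_errors(self, separable_windows, frame2):
        from evifuse.windowing import WindowSet

        bad = WindowSet(
            separable_windows.windows[:4], np.array([1, 2, 3, 1]), separable_windows.step
        )
        with pytest.raises(ValueError, match="labels"):
            ev.train_subnetwork_bank(bad, frame2, epochs=1)

    def test_total_weights_sums_specs(self, trained_bank2):
        bank, _, _ = trained_bank2
        assert bank.total_weights() == 2 * count_weights(bank.subnetworks[0].spec)
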