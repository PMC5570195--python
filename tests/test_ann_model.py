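import json
import math

import numpy as np
import pytest

from motifcore import (
    Alphabet,
    EncodingScheme,
    EnsembleMember,
    EnsembleModel,
    IndelPolicy,
    LigandRecord,
    NetworkParams,
    TrainConfig,
    forward,
    load_model,
    predict,
    save_model,
    train_member,
)
from motifcore.ann_model import gradients, init_network
from motifcore.errors import IntegrityError, ModelFormatError, ValidationError


def _params(W1, b1, W2, b2):
    return NetworkParams(
        W1=np.array(W1, dtype=float),
        b1=np.array(b1, dtype=float),
        W2=np.array(W2, dtype=float),
        b2=float(b2),
        hidden_size=len(b1),
        init_seed=0,
    )


class TestForward:
    def test_zero_weights_give_one_half(self):
        p = _params(np.zeros((3, 4)), np.zeros(3), np.zeros(3), 0.0)
        assert forward(p, np.ones(4)) == pytest.approx(0.5)

    def test_large_output_bias_saturates(self):
        p = _params(np.zeros((3, 4)), np.zeros(3), np.zeros(3), 20.0)
        assert forward(p, np.ones(4)) > 0.9999

    def test_matches_hand_computed_fixture(self):
        # independent step-by-step computation with plain math:
        # z1 = (0.335, -0.02); h = sigma(z1); o = sigma(W2.h + b2)
        p = _params([[0.1, -0.2, 0.3], [0.05, 0.0, -0.1]], [0.01, -0.02], [0.2, -0.3], 0.05)
        x = np.array([0.5, -1.0, 0.25])
        h0 = 1 / (1 + math.exp(-0.335))
        h1 = 1 / (1 + math.exp(0.02))
        expected = 1 / (1 + math.exp(-(0.2 * h0 - 0.3 * h1 + 0.05)))
        assert forward(p, x) == pytest.approx(expected, abs=1e-12)
        assert forward(p, x) == pytest.approx(0.5045236367798447, abs=1e-12)


class TestGradients:
    def test_backprop_matches_central_finite_differences(self, rng):
        """Analytic gradients of (t-o)^2 vs central differences, 20 networks."""
        for _ in range(20):
            dim, hidden = int(rng.integers(2, 8)), int(rng.integers(1, 5))
            params = init_network(dim, hidden, int(rng.integers(2**31)))
            x = rng.normal(size=dim)
            t = float(rng.uniform())
            grads = gradients(params, x, t)
            eps = 1e-6

            def loss() -> float:
                return (t - params.forward(x)) ** 2

            for name in ("W1", "b1", "W2"):
                arr = getattr(params, name)
                num = np.zeros_like(arr)
                it = np.nditer(arr, flags=["multi_index"])
                for _v in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + eps
                    up = loss()
                    arr[idx] = orig - eps
                    down = loss()
                    arr[idx] = orig
                    num[idx] = (up - down) / (2 * eps)
                denom = np.maximum(np.abs(num), 1e-4)
                assert np.max(np.abs(grads[name] - num) / denom) < 1e-6
            params.b2 += eps
            up = loss()
            params.b2 -= 2 * eps
            down = loss()
            params.b2 += eps
            num_b2 = (up - down) / (2 * eps)
            assert abs(grads["b2"] - num_b2) / max(abs(num_b2), 1e-4) < 1e-6


def _records(n, seq_fn, target_fn):
    return [LigandRecord(sequence=seq_fn(i), target=target_fn(i)) for i in range(n)]


class TestTrainMember:
    def test_converges_on_constant_high_target(self, dna):
        scheme = EncodingScheme("sparse", dna, motif_length=4)
        records = _records(20, lambda i: "ACGT", lambda i: 1.0)
        config = TrainConfig(hidden_sizes=(3,), n_seeds=1, learning_rate=0.5, epochs=60, seed=0)
        params = train_member(records, scheme, IndelPolicy(), config, member_seed=7)
        from motifcore.encoding import encode_cores

        out = params.forward_batch(encode_cores(["ACGT"], None, 4, scheme))[0]
        assert out > 0.9

    def test_zero_learning_rate_is_identity(self, dna):
        scheme = EncodingScheme("sparse", dna, motif_length=4)
        records = _records(10, lambda i: "ACGT", lambda i: 0.5)
        config = TrainConfig(hidden_sizes=(3,), n_seeds=1, learning_rate=0.0, epochs=3, seed=0)
        trained = train_member(records, scheme, IndelPolicy(), config, member_seed=7)
        rng = np.random.default_rng(7)
        fresh = init_network(scheme.dimension, 3, int(rng.integers(2**31)))
        np.testing.assert_allclose(trained.W1, fresh.W1)
        np.testing.assert_allclose(trained.W2, fresh.W2)

    def test_same_seed_is_bit_identical(self, dna, fast_config):
        scheme = EncodingScheme("sparse", dna, motif_length=4)
        rng = np.random.default_rng(0)
        records = _records(
            30,
            lambda i: "".join(np.random.default_rng(i).choice(list("ACGT"), 6)),
            lambda i: float(rng.uniform()),
        )
        a = train_member(records, scheme, IndelPolicy(), fast_config, member_seed=11)
        b = train_member(records, scheme, IndelPolicy(), fast_config, member_seed=11)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)
        assert a.b2 == b.b2


def _tiny_model(dna, members=1):
    scheme = EncodingScheme("sparse", dna, motif_length=4)
    ms = [
        EnsembleMember(init_network(scheme.dimension, 3, seed), scheme, IndelPolicy())
        for seed in range(members)
    ]
    return EnsembleModel(members=ms, motif_length=4, alphabet=dna)


class TestPredict:
    def test_single_member_equals_best_core_score(self, dna):
        model = _tiny_model(dna)
        res = predict(model, "ACGTAC")
        from motifcore import best_core

        m = model.members[0]
        aln, score = best_core("ACGTAC", m.params, None, m.scheme, m.policy)
        assert res.prediction == pytest.approx(score)
        assert res.consensus_core == aln.core_symbols

    def test_identical_members_average_to_the_same(self, dna):
        one = _tiny_model(dna, members=1)
        many = EnsembleModel(members=one.members * 3, motif_length=4, alphabet=dna)
        assert predict(many, "ACGTAC").prediction == pytest.approx(
            predict(one, "ACGTAC").prediction
        )

    def test_mean_of_known_member_outputs(self, dna):
        class Fixed:
            def __init__(self, v):
                self.v = v

            def forward_batch(self, X):
                return np.full(X.shape[0], self.v)

        model = _tiny_model(dna, members=3)
        for m, v in zip(model.members, (0.2, 0.4, 0.9)):
            m.params.forward_batch = Fixed(v).forward_batch
        assert predict(model, "ACGT").prediction == pytest.approx(0.5)

    def test_member_order_does_not_change_prediction(self, dna):
        model = _tiny_model(dna, members=3)
        rev = EnsembleModel(members=list(reversed(model.members)), motif_length=4, alphabet=dna)
        assert predict(model, "ACGTACG").prediction == pytest.approx(
            predict(rev, "ACGTACG").prediction
        )

    def test_receptor_name_on_plain_model_is_an_error(self, dna):
        model = _tiny_model(dna)
        with pytest.raises(ValidationError, match="receptor"):
            predict(model, "ACGT", receptor_name="A1")


class TestSerialization:
    def test_round_trip_predictions_identical(self, dna, tmp_path, rng):
        model = _tiny_model(dna, members=2)
        path = tmp_path / "m.json"
        save_model(model, path)
        loaded = load_model(path)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 9))))
            assert predict(loaded, seq).prediction == predict(model, seq).prediction

    def test_corrupted_checksum_detected(self, dna, tmp_path):
        model = _tiny_model(dna)
        path = tmp_path / "m.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        doc["payload"]["members"][0]["b2"] = 0.123456
        path.write_text(json.dumps(doc))
        with pytest.raises(IntegrityError, match="checksum"):
            load_model(path)

    def test_truncated_file_detected(self, dna, tmp_path):
        model = _tiny_model(dna)
        path = tmp_path / "m.json"
        save_model(model, path)
        path.write_text(path.read_text()[:-40])
        with pytest.raises(IntegrityError):
            load_model(path)

    def test_version_mismatch_detected(self, dna, tmp_path):
        model = _tiny_model(dna)
        path = tmp_path / "m.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_pan_specific_flag_survives_round_trip(self, dna, tmp_path):
        model = _tiny_model(dna)
        path = tmp_path / "m.json"
        save_model(model, path)
        loaded = load_model(path)
        with pytest.raises(ValidationError):
            predict(loaded, "ACGT", receptor_name="A1")
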