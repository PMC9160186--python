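import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from earssvep.cnn import (
    ArchitectureSpec,
    SoftmaxTriple,
    SsvepCnn,
    TrainConfig,
    build_model,
    softmax,
)

from conftest import make_peak_images

FAST = TrainConfig(max_epochs=15, seed=0)


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(softmax(np.zeros(3)), np.full(3, 1 / 3))

    def test_hand_evaluated_example(self):
        np.testing.assert_allclose(
            softmax(np.array([np.log(2), 0.0, 0.0])), [0.5, 0.25, 0.25]
        )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        z=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        c=st.floats(-100, 100),
    )
    def test_shift_invariance_and_normalization(self, z, c):
        z = np.asarray(z)
        p = softmax(z)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(p, softmax(z + c), atol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([np.inf, 0.0, 0.0]))


class TestArchitecture:
    def test_first_layer_has_eight_5x5_filters(self):
        model = build_model(input_width=5)
        assert model.conv1.W.shape == (5, 5, 1, 8)
        assert model.conv2.W.shape == (3, 3, 8, 16)
        assert model.dense2.W.shape[1] == 3

    @pytest.mark.parametrize("w", [1, 2, 3, 4, 5])
    def test_every_window_width_constructible(self, w):
        model = build_model(input_width=w)
        p = model.predict_proba(np.random.default_rng(0).random((2, 125, w)))
        assert p.shape == (2, 3)

    def test_width_outside_range_rejected(self):
        with pytest.raises(ValueError, match="1..5"):
            build_model(input_width=6)

    def test_same_seed_identical_initialization(self):
        a, b = build_model(seed=4), build_model(seed=4)
        for pa, pb in zip(
            (p for l in a._layers for p in l.params),
            (p for l in b._layers for p in l.params),
        ):
            assert np.array_equal(pa, pb)

    def test_parameter_count_reported(self):
        model = build_model(input_width=2)
        expected = (
            5 * 5 * 1 * 8 + 8
            + 3 * 3 * 8 * 16 + 16
            + 496 * 256 + 256
            + 256 * 3 + 3
        )
        assert model.n_parameters == expected


class TestTraining:
    def test_learns_separable_peaks(self):
        rng = np.random.default_rng(1)
        x, y = make_peak_images(90, 2, rng, noise=0.1)
        model = SsvepCnn(input_width=2, seed=1)
        history = model.fit(x, y, TrainConfig(max_epochs=40, seed=1))
        assert len(history) == 40
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]
        acc = (model.predict(x) == y).mean()
        # peak-row oracle is perfect on these inputs; the CNN should be too
        oracle = np.array([7, 10, 13])[np.newaxis, :]
        assert ((x.argmax(axis=1)[:, 0][:, None] == oracle).argmax(axis=1) == y).all()
        assert acc >= 0.95

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(2)
        x, y = make_peak_images(30, 2, rng)
        y[:] = 0
        with pytest.raises(ValueError, match="absent"):
            SsvepCnn(input_width=2, seed=0).fit(x, y, FAST)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            SsvepCnn(input_width=2, seed=0).fit(
                np.zeros((0, 125, 2)), np.zeros(0, dtype=int), FAST
            )

    def test_seeded_reproducibility_of_loss_history(self):
        rng = np.random.default_rng(3)
        x, y = make_peak_images(60, 2, rng, noise=0.3)
        h1 = SsvepCnn(input_width=2, seed=9).fit(x, y, TrainConfig(max_epochs=5, seed=9))
        h2 = SsvepCnn(input_width=2, seed=9).fit(x, y, TrainConfig(max_epochs=5, seed=9))
        np.testing.assert_array_equal(h1["train_loss"], h2["train_loss"])

    def test_validation_history_recorded(self):
        rng = np.random.default_rng(4)
        x, y = make_peak_images(60, 1, rng, noise=0.2)
        model = SsvepCnn(input_width=1, seed=0)
        h = model.fit(x[:40], y[:40], FAST, validation=(x[40:], y[40:]))
        assert {"val_loss", "val_accuracy"} <= set(h.columns)

    def test_shrinking_training_data_does_not_help(self):
        # mean test accuracy over seeds is non-increasing when training
        # shrinks from the full set to a quarter of it
        accs = {1.0: [], 0.25: []}
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            x, y = make_peak_images(120, 1, rng, noise=0.6)
            xt, yt, xe, ye = x[:80], y[:80], x[80:], y[80:]
            for frac in accs:
                n = int(frac * len(xt))
                m = SsvepCnn(input_width=1, seed=seed)
                m.fit(xt[:n], yt[:n], TrainConfig(max_epochs=25, seed=seed))
                accs[frac].append((m.predict(xe) == ye).mean())
        assert np.mean(accs[1.0]) >= np.mean(accs[0.25])


class TestInference:
    def test_probabilities_sum_to_one(self):
        model = build_model(input_width=3)
        p = model.predict_proba(np.random.default_rng(0).random((7, 125, 3)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_determinism(self):
        model = build_model(input_width=2)
        img = np.random.default_rng(1).random((125, 2))
        a = model.predict_softmax(img)
        b = model.predict_softmax(img)
        assert np.array_equal(a.probs, b.probs)

    def test_width_mismatch_names_expected_width(self):
        model = build_model(input_width=2)
        with pytest.raises(ValueError, match="2"):
            model.predict_proba(np.zeros((1, 125, 4)))

    def test_softmax_triple_contract(self):
        with pytest.raises(ValueError, match="sum"):
            SoftmaxTriple(probs=np.array([0.5, 0.4, 0.3]))
        t = SoftmaxTriple(probs=np.array([0.2, 0.5, 0.3]))
        assert t.predicted_index == 1
        assert t.predicted_freq == 11.0

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        x, y = make_peak_images(30, 2, rng, noise=0.2)
        model = SsvepCnn(input_width=2, seed=2)
        model.fit(x, y, FAST)
        path = tmp_path / "model.npz"
        model.save(path)
        clone = SsvepCnn.load(path)
        np.testing.assert_array_equal(model.predict_proba(x), clone.predict_proba(x))
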