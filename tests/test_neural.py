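"""Network construction, batching, training smoke and memory-limit tests.

Training tests run at deliberately tiny scale: the point is convergence
behaviour and contracts, not headline accuracy (that lives in the
acceptance suite).
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from somnostage import synthetic_psg as sp
from somnostage import autodiff as ad
from somnostage.neural import (
    ALLOWED_UNITS,
    CNNLSTMConfig,
    LSTMConfig,
    LSTM_CATALOGUE,
    build_cnn_lstm,
    build_feature_lstm,
    make_feature_data,
    make_raw_data,
    predict_stages,
    sample_sequences,
    train_network,
)


@pytest.fixture(scope="module")
def feature_sets():
    roster = sp.generate_dataset(4, 1, "healthy", seed=5, duration_min=60)
    data = [make_feature_data(e.recording, e.hypnogram) for e in roster]
    return data[:3], data[3:]


class TestSampleSequences:
    def test_full_length_sequence_starts_at_zero(self, rng):
        assert np.all(sample_sequences(8, 8, 16, rng) == 0)

    def test_starts_uniform_by_chi_square(self):
        rng = np.random.default_rng(0)
        starts = sample_sequences(100, 8, 10_000, rng)
        assert starts.min() >= 0 and starts.max() <= 92
        observed = np.bincount(starts, minlength=93)
        chi2 = ((observed - observed.mean()) ** 2 / observed.mean()).sum()
        p = stats.chi2.sf(chi2, df=92)
        assert p > 0.01

    def test_fixed_seed_reproducible(self):
        a = sample_sequences(50, 8, 20, np.random.default_rng(3))
        b = sample_sequences(50, 8, 20, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_too_short_recording_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            sample_sequences(5, 8, 4, rng)


class TestBuildFeatureLSTM:
    def test_forward_shape_and_simplex(self):
        model = build_feature_lstm(LSTMConfig(units_per_layer=8, sequence_len=8), seed=0)
        probs = model.predict_proba_batch(np.random.default_rng(0).standard_normal((1, 8, 20)))
        assert probs.shape == (1, 8, 5)
        assert np.allclose(probs.sum(axis=-1), 1.0)

    def test_bidirectional_doubles_recurrent_width(self):
        uni = build_feature_lstm(LSTMConfig(units_per_layer=32, bidirectional=False))
        bi = build_feature_lstm(LSTMConfig(units_per_layer=32, bidirectional=True))
        assert bi.recurrent_out_width == 2 * uni.recurrent_out_width

    def test_catalogue_instantiates(self):
        assert len(LSTM_CATALOGUE) == 8
        assert sum(flag for _, flag in LSTM_CATALOGUE) == 6
        for cfg, _ in LSTM_CATALOGUE:
            build_feature_lstm(cfg)

    def test_invalid_unit_count_rejected(self):
        with pytest.raises(ValueError, match="units"):
            LSTMConfig(units_per_layer=12)

    def test_spectrogram_input_width(self):
        model = build_feature_lstm(LSTMConfig(input_kind="spectrogram"))
        assert model.config.input_width == 197


class TestBuildCNNLSTM:
    def test_plain_block_has_eleven_conv_layers(self):
        model = build_cnn_lstm(CNNLSTMConfig(conv_block="plain", width_multiplier=0.25))
        assert model.n_conv_layers == 11

    def test_residual_block_has_nineteen_conv_layers(self):
        model = build_cnn_lstm(CNNLSTMConfig(conv_block="residual", width_multiplier=0.25))
        assert model.n_conv_layers == 19

    def test_emg_scalar_bypass_width(self):
        with_emg = build_cnn_lstm(CNNLSTMConfig(inputs="eeg+eog+emg", width_multiplier=0.25))
        without = build_cnn_lstm(CNNLSTMConfig(inputs="eeg+eog", width_multiplier=0.25))
        assert with_emg.lstm_input_width == without.lstm_input_width + 1

    def test_forward_pass_emits_simplex_rows(self):
        model = build_cnn_lstm(CNNLSTMConfig(width_multiplier=0.125, sequence_len=8))
        rng = np.random.default_rng(0)
        x = {
            "EEG": rng.standard_normal((1, 8, 2560)),
            "EOG_L": rng.standard_normal((1, 8, 2560)),
            "EOG_R": rng.standard_normal((1, 8, 2560)),
            "EMG_SCALAR": rng.standard_normal((1, 8)),
        }
        probs = model.predict_proba_batch(x)
        assert probs.shape == (1, 8, 5)
        assert np.allclose(probs.sum(axis=-1), 1.0)

    def test_invalid_block_kind_rejected(self):
        with pytest.raises(ValueError, match="conv_block"):
            CNNLSTMConfig(conv_block="dense")


class TestTraining:
    def test_loss_decreases_and_curves_have_full_length(self, feature_sets):
        train, val = feature_sets
        model = build_feature_lstm(LSTMConfig(units_per_layer=8, sequence_len=8), seed=0)
        model, curves = train_network(
            model, train, val, n_iterations=5, seed=0, batches_per_iteration=10
        )
        assert len(curves.train_loss) == len(curves.val_acc) == 5
        assert curves.train_loss[-1] < curves.train_loss[0]
        assert curves.val_acc[-1] > 0.5

    def test_gradient_step_reduces_batch_loss(self, feature_sets):
        train, _ = feature_sets
        model = build_feature_lstm(LSTMConfig(units_per_layer=8, sequence_len=8), seed=1)
        model.fit_normalizer(train)
        x = model._batch_inputs(train[0], np.array([0, 4]))
        y = np.stack([train[0].labels[0:8], train[0].labels[4:12]])
        loss0 = float(ad.cross_entropy(model.forward(x, training=True), y).data)
        opt = ad.Adam(model.params(), lr=1e-3)
        for _ in range(5):
            loss = ad.cross_entropy(model.forward(x, training=True), y)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert float(ad.cross_entropy(model.forward(x, training=False), y).data) < loss0

    def test_predict_stages_contracts(self, feature_sets):
        train, val = feature_sets
        model = build_feature_lstm(LSTMConfig(units_per_layer=8, sequence_len=8), seed=0)
        model, _ = train_network(model, train, val, n_iterations=2, seed=0, batches_per_iteration=5)
        stages, post = predict_stages(model, val[0])
        assert len(stages) == val[0].n_epochs
        assert np.allclose(post.probs.sum(axis=1), 1.0)
        assert stages == post.argmax_stages()

    def test_short_recording_padded_with_warning(self, feature_sets, caplog):
        train, val = feature_sets
        model = build_feature_lstm(LSTMConfig(units_per_layer=8, sequence_len=8), seed=0)
        model.fit_normalizer(train)
        short = sp.generate_dataset(1, 1, "healthy", seed=9, duration_min=2)[0]
        data = make_feature_data(short.recording, short.hypnogram)
        assert data.n_epochs < 8
        with caplog.at_level("WARNING"):
            stages, post = predict_stages(model, data)
        assert len(stages) == data.n_epochs
        assert any("padding" in m for m in caplog.messages)


class TestMemoryLimit:
    def test_outputs_independent_of_epochs_outside_window(self, feature_sets):
        """Perturbing epochs beyond the sequence window leaves the windowed
        output bit-identical (the network has no global memory)."""
        train, val = feature_sets
        model = build_feature_lstm(LSTMConfig(units_per_layer=8, sequence_len=8), seed=0)
        model, _ = train_network(model, train, val, n_iterations=1, seed=0, batches_per_iteration=5)
        data = val[0]
        x1 = model._batch_inputs(data, np.array([0]))
        perturbed = np.copy(data.features)
        perturbed[20:] += 100.0  # far outside the [0, 8) window
        from somnostage.neural import SequenceData

        data2 = SequenceData(labels=data.labels, features=perturbed)
        x2 = model._batch_inputs(data2, np.array([0]))
        np.testing.assert_array_equal(
            model.predict_proba_batch(x1), model.predict_proba_batch(x2)
        )
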