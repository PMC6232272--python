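"""Sequence networks for sleep staging.

Two families of models, both emitting a probability simplex over
(W, N1, N2, N3, R) for every epoch of an input sequence:

* feature-based LSTMs: three stacked (optionally bidirectional) LSTM
  layers of 8, 16, 32 or 128 units over the 20 engineered features or the
  197-bin spectrogram, followed by a 5-way dense output;
* raw-signal CNN-LSTMs: one convolutional block per raw channel (a plain
  11-layer block or a 19-layer residual variant), applied per epoch;
  separate blocks for the two EOG channels since their correlation
  distinguishes eye-movement types; the per-epoch EMG 15-30 Hz power
  enters as a single scalar bypassing the CNN. Block outputs are
  concatenated and fed through two bidirectional 32-unit LSTM layers with
  batch normalization before, between and after.

Training minimizes cross-entropy over dynamically sampled batches of
sequences whose start epochs are drawn uniformly at random (sequences may
intersect), with sequence lengths of 8, 32 or 128 epochs. Temporal memory
is deliberately limited to the sequence window: global sleep architecture
must not bias scoring of naps or disturbed sleep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, BatchNorm, Tensor
from .classical import PosteriorMatrix
from .core import STAGES, Hypnogram, Recording
from .features import LOG_EPS, extract_features, emg_power, spectrogram

logger = logging.getLogger(__name__)

_N = len(STAGES)

ALLOWED_UNITS = (8, 16, 32, 128)
ALLOWED_SEQUENCE_LENS = (8, 32, 128)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LSTMConfig:
    """Feature-based LSTM: 3 layers, unit count from the fixed catalogue."""

    units_per_layer: int = 8
    bidirectional: bool = True
    input_kind: str = "features"  # features | spectrogram
    sequence_len: int = 8
    n_layers: int = 3

    def __post_init__(self) -> None:
        if self.units_per_layer not in ALLOWED_UNITS:
            raise ValueError(f"units must be one of {ALLOWED_UNITS}")
        if self.sequence_len not in ALLOWED_SEQUENCE_LENS:
            raise ValueError(f"sequence length must be one of {ALLOWED_SEQUENCE_LENS}")
        if self.input_kind not in ("features", "spectrogram"):
            raise ValueError("input_kind must be 'features' or 'spectrogram'")
        if self.n_layers != 3:
            raise ValueError("the feature LSTM is fixed at three layers")

    @property
    def input_width(self) -> int:
        return 20 if self.input_kind == "features" else 197


#: Catalogue of unit-count/directionality combinations. The published set
#: comprises six configurations; the exact six are ambiguous given four
#: unit counts and two directionalities, so all eight instantiate and the
#: flag marks the ones taken as the published set.
LSTM_CATALOGUE: list[tuple[LSTMConfig, bool]] = [
    (LSTMConfig(units_per_layer=u, bidirectional=b), not (u == 128 and not b) and not (u == 16 and not b))
    for u in ALLOWED_UNITS
    for b in (True, False)
]


@dataclass(frozen=True)
class CNNLSTMConfig:
    """Raw-data CNN-LSTM. ``width_multiplier`` scales all conv widths for
    desk-scale runs; 1.0 is the full-size network."""

    conv_block: str = "plain"  # plain (11 layers) | residual (19 layers)
    inputs: str = "eeg+eog+emg"  # eeg | eeg+eog | eeg+eog+emg
    sequence_len: int = 8
    width_multiplier: float = 1.0
    lstm_units: int = 32
    lstm_layers: int = 2

    def __post_init__(self) -> None:
        if self.conv_block not in ("plain", "residual"):
            raise ValueError("conv_block must be 'plain' or 'residual'")
        if self.inputs not in ("eeg", "eeg+eog", "eeg+eog+emg"):
            raise ValueError("inputs must be 'eeg', 'eeg+eog' or 'eeg+eog+emg'")
        if self.sequence_len not in ALLOWED_SEQUENCE_LENS:
            raise ValueError(f"sequence length must be one of {ALLOWED_SEQUENCE_LENS}")
        if self.lstm_units != 32 or self.lstm_layers != 2:
            raise ValueError("the CNN-LSTM head is fixed at 2 bidirectional layers of 32 units")

    @property
    def raw_channels(self) -> tuple[str, ...]:
        return ("EEG",) if self.inputs == "eeg" else ("EEG", "EOG_L", "EOG_R")

    @property
    def use_emg_scalar(self) -> bool:
        return self.inputs == "eeg+eog+emg"


@dataclass
class LearningCurves:
    """Per-iteration cross-entropy loss and accuracy, train and validation."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def to_csv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        ).to_csv(path, index=False)


@dataclass
class SequenceData:
    """Network-ready view of one recording: per-epoch inputs and labels."""

    labels: np.ndarray  # (n_epochs,) int stage indices
    features: Optional[np.ndarray] = None  # (n_epochs, D)
    raw: Optional[dict[str, np.ndarray]] = None  # role -> (n_epochs, n_samples)
    emg_scalar: Optional[np.ndarray] = None  # (n_epochs,)

    @property
    def n_epochs(self) -> int:
        return self.labels.size


def make_feature_data(recording: Recording, hypnogram: Hypnogram, input_kind: str = "features") -> SequenceData:
    """Extract the per-epoch input a feature LSTM consumes."""
    if input_kind == "features":
        x = extract_features(recording, hypnogram.epoch_len_s).values
    elif input_kind == "spectrogram":
        spec = spectrogram(recording, hypnogram.epoch_len_s)
        x = spec.log10()
    else:
        raise ValueError(f"unknown input kind {input_kind!r}")
    n = min(x.shape[0], len(hypnogram))
    return SequenceData(labels=hypnogram.as_indices()[:n], features=x[:n])


def make_raw_data(recording: Recording, hypnogram: Hypnogram) -> SequenceData:
    """Per-epoch raw channel blocks plus the EMG power scalar."""
    L = hypnogram.epoch_len_s
    raw = {}
    n_epochs = len(hypnogram)
    for role in ("EEG", "EOG_L", "EOG_R"):
        ch = recording.channel(role)
        n = int(round(ch.fs_hz * L))
        m = min(n_epochs, ch.samples.size // n)
        raw[role] = ch.samples[: m * n].reshape(m, n)
    emg = recording.channel("EMG")
    n = int(round(emg.fs_hz * L))
    m = min(n_epochs, emg.samples.size // n)
    scal = np.atleast_1d(emg_power(emg.samples[: m * n].reshape(m, n), emg.fs_hz))
    n_use = min(m, min(v.shape[0] for v in raw.values()))
    return SequenceData(
        labels=hypnogram.as_indices()[:n_use],
        raw={k: v[:n_use] for k, v in raw.items()},
        emg_scalar=scal[:n_use],
    )


# ---------------------------------------------------------------------------
# Sequence batching
# ---------------------------------------------------------------------------


def sample_sequences(
    n_epochs: int, sequence_len: int, batch_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Random sequence start indices: each range [s, s+L) with s uniform on
    {0, ..., n_epochs - L}; sequences may intersect."""
    if n_epochs < sequence_len:
        raise ValueError(f"recording of {n_epochs} epochs is shorter than the sequence length {sequence_len}")
    return rng.integers(0, n_epochs - sequence_len + 1, size=batch_size)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class LSTMLayer:
    """Single-direction LSTM over (B, T, D) inputs; forget-gate bias 1."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        self.units = units
        self.Wx = ad.parameter((in_dim, 4 * units), rng, scale=1.0 / math.sqrt(in_dim))
        self.Wh = ad.parameter((units, 4 * units), rng, scale=1.0 / math.sqrt(units))
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0
        self.b = ad.parameter(b)

    def params(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b]

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.units)))
        c = Tensor(np.zeros((B, self.units)))
        outs: list[Tensor] = []
        steps = range(T - 1, -1, -1) if reverse else range(T)
        for t in steps:
            xt = ad.select_time(x, t)
            z = xt.matmul(self.Wx) + h.matmul(self.Wh) + self.b
            i, f, g, o = ad.split_last(z, 4)
            c = ad.sigmoid(f) * c + ad.sigmoid(i) * ad.tanh(g)
            h = ad.sigmoid(o) * ad.tanh(c)
            outs.append(h)
        if reverse:
            outs.reverse()
        return ad.stack_time(outs)


class BiLSTM:
    """Bidirectional LSTM: forward and backward passes concatenated."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        self.fwd = LSTMLayer(in_dim, units, rng)
        self.bwd = LSTMLayer(in_dim, units, rng)
        self.out_width = 2 * units

    def params(self) -> list[Tensor]:
        return self.fwd.params() + self.bwd.params()

    def __call__(self, x: Tensor) -> Tensor:
        return ad.concat_last([self.fwd(x), self.bwd(x, reverse=True)])


class ConvBlock:
    """Stacked 1-D conv + ReLU with periodic max pooling, ending in global
    average pooling so each epoch maps to one feature vector.

    Plain variant: 11 conv layers, widths doubling 16 -> 64 at each pool
    (pool of 2 after every second layer). Residual variant: an input conv
    plus nine two-conv residual units (19 weight layers) at constant width,
    pooling after every second unit; skip connections keep gradients alive.
    All widths scale with the width multiplier.
    """

    KERNEL = 7

    def __init__(self, kind: str, width_multiplier: float, rng: np.random.Generator):
        self.kind = kind
        w = lambda base: max(1, int(round(base * width_multiplier)))
        self.convs: list[tuple[Tensor, Tensor]] = []
        if kind == "plain":
            widths = [16, 16, 32, 32, 64, 64, 64, 64, 64, 64, 64]
            self.pool_after = {1, 3, 5, 7, 9}
            cin = 1
            for base in widths:
                cout = w(base)
                self._add_conv(cin, cout, rng)
                cin = cout
            self.out_width = cin
        elif kind == "residual":
            cw = w(32)
            self._add_conv(1, cw, rng)
            for _ in range(9):
                self._add_conv(cw, cw, rng)
                self._add_conv(cw, cw, rng)
            self.pool_after_unit = {1, 3, 5, 7}
            self.out_width = cw
        else:
            raise ValueError(f"unknown conv block kind {kind!r}")

    def _add_conv(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        scale = math.sqrt(2.0 / (self.KERNEL * cin))
        self.convs.append(
            (ad.parameter(rng.standard_normal((self.KERNEL, cin, cout)) * scale), ad.parameter(np.zeros(cout)))
        )

    @property
    def n_conv_layers(self) -> int:
        return len(self.convs)

    def params(self) -> list[Tensor]:
        return [p for wb in self.convs for p in wb]

    def __call__(self, x: Tensor) -> Tensor:
        if self.kind == "plain":
            for i, (w, b) in enumerate(self.convs):
                x = ad.relu(ad.conv1d(x, w, b))
                if i in self.pool_after:
                    x = ad.maxpool1d(x)
            return ad.mean_time(x)
        # residual
        w0, b0 = self.convs[0]
        x = ad.relu(ad.conv1d(x, w0, b0))
        for u in range(9):
            w1, b1 = self.convs[1 + 2 * u]
            w2, b2 = self.convs[2 + 2 * u]
            y = ad.conv1d(ad.relu(ad.conv1d(x, w1, b1)), w2, b2)
            x = ad.relu(x + y)
            if u in self.pool_after_unit:
                x = ad.maxpool1d(x)
        return ad.mean_time(x)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


class FeatureLSTM:
    """Three-layer (bi)LSTM over per-epoch feature vectors."""

    def __init__(self, config: LSTMConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.layers: list = []
        width = config.input_width
        for _ in range(config.n_layers):
            if config.bidirectional:
                layer = BiLSTM(width, config.units_per_layer, rng)
                width = layer.out_width
            else:
                layer = LSTMLayer(width, config.units_per_layer, rng)
                width = config.units_per_layer
            self.layers.append(layer)
        self.recurrent_out_width = width
        self.W_out = ad.parameter((width, _N), rng, scale=1.0 / math.sqrt(width))
        self.b_out = ad.parameter(np.zeros(_N))
        self._mean: Optional[np.ndarray] = None
        self._std: Optional[np.ndarray] = None

    @property
    def sequence_len(self) -> int:
        return self.config.sequence_len

    def params(self) -> list[Tensor]:
        ps = [p for layer in self.layers for p in layer.params()]
        return ps + [self.W_out, self.b_out]

    def fit_normalizer(self, train_set: Sequence[SequenceData]) -> None:
        x = np.concatenate([d.features for d in train_set], axis=0)
        self._mean = x.mean(axis=0)
        std = x.std(axis=0)
        self._std = np.where(std > 0, std, 1.0)

    def _batch_inputs(self, data: SequenceData, starts: np.ndarray) -> np.ndarray:
        L = self.config.sequence_len
        x = np.stack([data.features[s : s + L] for s in starts])
        if self._mean is not None:
            x = (x - self._mean) / self._std
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> Tensor:
        t: Tensor = Tensor(x)
        for layer in self.layers:
            t = layer(t)
        return t.matmul(self.W_out) + self.b_out

    def predict_proba_batch(self, x: np.ndarray) -> np.ndarray:
        return ad.softmax(self.forward(x, training=False).data)


class CNNLSTM:
    """Per-channel conv blocks + EMG scalar bypass + 2x bidirectional LSTM."""

    def __init__(self, config: CNNLSTMConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks = {role: ConvBlock(config.conv_block, config.width_multiplier, rng) for role in config.raw_channels}
        feat_width = sum(b.out_width for b in self.blocks.values()) + (1 if config.use_emg_scalar else 0)
        self.lstm_input_width = feat_width
        self.bn_before = BatchNorm(feat_width)
        self.lstm1 = BiLSTM(feat_width, config.lstm_units, rng)
        self.bn_between = BatchNorm(self.lstm1.out_width)
        self.lstm2 = BiLSTM(self.lstm1.out_width, config.lstm_units, rng)
        self.bn_after = BatchNorm(self.lstm2.out_width)
        self.W_out = ad.parameter((self.lstm2.out_width, _N), rng, scale=1.0 / math.sqrt(self.lstm2.out_width))
        self.b_out = ad.parameter(np.zeros(_N))
        self._raw_scale: dict[str, float] = {}
        self._emg_mean: float = 0.0
        self._emg_std: float = 1.0

    @property
    def sequence_len(self) -> int:
        return self.config.sequence_len

    @property
    def n_conv_layers(self) -> int:
        return next(iter(self.blocks.values())).n_conv_layers

    def params(self) -> list[Tensor]:
        ps = [p for b in self.blocks.values() for p in b.params()]
        for bn in (self.bn_before, self.bn_between, self.bn_after):
            ps += bn.params()
        ps += self.lstm1.params() + self.lstm2.params()
        return ps + [self.W_out, self.b_out]

    def fit_normalizer(self, train_set: Sequence[SequenceData]) -> None:
        for role in self.config.raw_channels:
            x = np.concatenate([d.raw[role] for d in train_set], axis=0)
            s = float(x.std())
            self._raw_scale[role] = 1.0 / s if s > 0 else 1.0
        if self.config.use_emg_scalar:
            e = np.log10(np.concatenate([d.emg_scalar for d in train_set]) + LOG_EPS)
            self._emg_mean = float(e.mean())
            self._emg_std = float(e.std()) or 1.0

    def _batch_inputs(self, data: SequenceData, starts: np.ndarray) -> dict[str, np.ndarray]:
        L = self.config.sequence_len
        out: dict[str, np.ndarray] = {}
        for role in self.config.raw_channels:
            scale = self._raw_scale.get(role, 1.0)
            out[role] = np.stack([data.raw[role][s : s + L] for s in starts]) * scale
        if self.config.use_emg_scalar:
            e = np.log10(np.stack([data.emg_scalar[s : s + L] for s in starts]) + LOG_EPS)
            out["EMG_SCALAR"] = (e - self._emg_mean) / self._emg_std
        return out

    def forward(self, x: dict[str, np.ndarray], training: bool = False) -> Tensor:
        parts: list[Tensor] = []
        B = L = None
        for role in self.config.raw_channels:
            arr = x[role]
            B, L, S = arr.shape
            t = Tensor(arr.reshape(B * L, S, 1))
            feat = self.blocks[role](t)  # (B*L, F)
            parts.append(ad.reshape(feat, (B, L, feat.shape[-1])))
        if self.config.use_emg_scalar:
            parts.append(Tensor(x["EMG_SCALAR"][:, :, None]))
        t = ad.concat_last(parts) if len(parts) > 1 else parts[0]
        t = self.bn_before(t, training)
        t = self.lstm1(t)
        t = self.bn_between(t, training)
        t = self.lstm2(t)
        t = self.bn_after(t, training)
        return t.matmul(self.W_out) + self.b_out

    def predict_proba_batch(self, x: dict[str, np.ndarray]) -> np.ndarray:
        return ad.softmax(self.forward(x, training=False).data)


def build_feature_lstm(config: LSTMConfig, seed: int = 0) -> FeatureLSTM:
    return FeatureLSTM(config, seed)


def build_cnn_lstm(config: CNNLSTMConfig, seed: int = 0) -> CNNLSTM:
    return CNNLSTM(config, seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _class_weights(train_set: Sequence[SequenceData]) -> np.ndarray:
    """Inverse-frequency weights normalized to mean 1 (N1 is scarce)."""
    counts = np.zeros(_N)
    for d in train_set:
        np.add.at(counts, d.labels, 1)
    w = np.where(counts > 0, counts.sum() / np.maximum(counts, 1), 0.0)
    nz = w > 0
    w[nz] = w[nz] / w[nz].mean()
    w[~nz] = 1.0
    return w


def _evaluate(model, data_set: Sequence[SequenceData]) -> tuple[float, float]:
    """Unweighted cross-entropy loss and accuracy over sequential windows."""
    L = model.sequence_len
    losses, weights, correct, total = [], [], 0, 0
    for data in data_set:
        n = data.n_epochs
        starts = list(range(0, max(n - L, 0) + 1, L))
        if starts and starts[-1] + L < n:
            starts.append(n - L)
        for s0 in starts:
            x = model._batch_inputs(data, np.array([s0]))
            probs = model.predict_proba_batch(x)[0]
            y = data.labels[s0 : s0 + L]
            p = np.clip(probs[np.arange(L), y], 1e-300, None)
            losses.append(-np.log(p).sum())
            weights.append(L)
            correct += int((probs.argmax(axis=1) == y).sum())
            total += L
    return float(np.sum(losses) / np.sum(weights)), correct / max(total, 1)


def train_network(
    model,
    train_set: Sequence[SequenceData],
    val_set: Sequence[SequenceData],
    n_iterations: int = 50,
    seed: int = 0,
    batches_per_iteration: int = 100,
    batch_size: int = 32,
    lr: float = 1e-3,
    class_weighting: bool = True,
    checkpoint_best: bool = False,
):
    """Train by cross-entropy over randomly sampled sequence batches.

    One iteration is a fixed number of sampled batches; loss and accuracy
    are recorded on the training and validation sets after every iteration.
    Class imbalance is handled by inverse-frequency weighting of the loss
    (switchable off). No early stopping: a fixed iteration count is run;
    with ``checkpoint_best`` the parameters from the best validation-loss
    iteration are restored at the end.
    """
    rng = np.random.default_rng(seed)
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    model.fit_normalizer(train_set)
    weights = _class_weights(train_set) if class_weighting else None
    opt = Adam(model.params(), lr=lr)
    curves = LearningCurves()
    L = model.sequence_len
    best: Optional[tuple[float, list[np.ndarray]]] = None
    for it in range(n_iterations):
        for _ in range(batches_per_iteration):
            recs = rng.integers(0, len(train_set), size=batch_size)
            starts = np.array(
                [sample_sequences(train_set[r].n_epochs, L, 1, rng)[0] for r in recs]
            )
            # group by recording to assemble the batch
            xs, ys = [], []
            for r, s0 in zip(recs, starts):
                xs.append((train_set[r], s0))
                ys.append(train_set[r].labels[s0 : s0 + L])
            y = np.stack(ys)
            if isinstance(model, CNNLSTM):
                batches = [model._batch_inputs(d, np.array([s0])) for d, s0 in xs]
                x = {k: np.concatenate([b[k] for b in batches], axis=0) for k in batches[0]}
            else:
                x = np.concatenate([model._batch_inputs(d, np.array([s0])) for d, s0 in xs], axis=0)
            logits = model.forward(x, training=True)
            loss = ad.cross_entropy(logits, y, weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at iteration {it + 1}: loss={loss.data!r}; "
                    "reduce the learning rate or inspect the inputs"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
        tl, ta = _evaluate(model, train_set)
        vl, va = _evaluate(model, val_set)
        curves.train_loss.append(tl)
        curves.train_acc.append(ta)
        curves.val_loss.append(vl)
        curves.val_acc.append(va)
        logger.info("iteration %d/%d: train loss %.4f acc %.3f | val loss %.4f acc %.3f", it + 1, n_iterations, tl, ta, vl, va)
        if checkpoint_best and (best is None or vl < best[0]):
            best = (vl, [p.data.copy() for p in model.params()])
    if checkpoint_best and best is not None:
        for p, d in zip(model.params(), best[1]):
            p.data = d
    return model, curves


# ---------------------------------------------------------------------------
# Whole-recording scoring
# ---------------------------------------------------------------------------


def predict_stages(model, data: SequenceData) -> tuple[list[str], PosteriorMatrix]:
    """Score a whole recording by striding sequences of the model's length.

    Windows overlap by half a sequence and their probabilities are
    averaged before the argmax. Recordings shorter than one sequence are
    padded by repeating the last epoch (with a warning); the padding is
    discarded from the output.
    """
    L = model.sequence_len
    n = data.n_epochs
    padded = data
    if n < L:
        logger.warning("recording of %d epochs shorter than sequence length %d; padding by repetition", n, L)
        reps = L - n

        def pad(a):
            return np.concatenate([a, np.repeat(a[-1:], reps, axis=0)], axis=0)

        padded = SequenceData(
            labels=pad(data.labels),
            features=None if data.features is None else pad(data.features),
            raw=None if data.raw is None else {k: pad(v) for k, v in data.raw.items()},
            emg_scalar=None if data.emg_scalar is None else pad(data.emg_scalar),
        )
        n = L
    stride = max(L // 2, 1)
    starts = sorted({min(s, n - L) for s in range(0, n, stride)})
    prob_sum = np.zeros((n, _N))
    counts = np.zeros(n)
    for s0 in starts:
        x = model._batch_inputs(padded, np.array([s0]))
        probs = model.predict_proba_batch(x)[0]
        prob_sum[s0 : s0 + L] += probs
        counts[s0 : s0 + L] += 1
    probs = prob_sum / counts[:, None]
    probs = probs[: data.n_epochs]
    probs = probs / probs.sum(axis=1, keepdims=True)
    stages = [STAGES[i] for i in probs.argmax(axis=1)]
    return stages, PosteriorMatrix(probs)
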