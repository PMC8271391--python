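"""Network families and training for joint-curve regression.

Three families map the three tensor layouts to the 18 joint-curve channels:

* ``mlp`` (flat layout): two hidden dense layers with dropout, linear output
  of size 18 × T;
* ``lstm`` (sequence layout): two stacked recurrent layers, a per-timestep
  linear read-out of the 18 channels;
* ``cnn`` (image layout): a five-block convolution/pooling stack followed by
  two dense layers and a linear 18 × T output; ``cnn_frozen_conv`` is the
  same architecture with the convolution/pooling parameters excluded from
  training (only the dense head learns), initialized from a seeded draw.

Training minimizes mean absolute error with Adam, stops early once the
validation loss stops improving, and restores the best-epoch weights.

The public surface follows the statsmodels idiom: a
:class:`JointPredictionModel` is built from scaled
:class:`~imugait.preprocess.DatasetTensors` plus a :class:`NetSpec`;
``fit()`` returns a :class:`JointPredictionResults` carrying the fitted
network, the loss history and prediction/metric/summary helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import DatasetTensors, Scaler

FAMILY_LAYOUT = {
    "mlp": "flat",
    "lstm": "sequence",
    "cnn": "image",
    "cnn_frozen_conv": "image",
}

#: Published-scale hyperparameters per family (joint-angle task): widths,
#: learning rate, dropout, activation.
TABLE_ANGLES = {
    "mlp": ((6000, 4000), 3e-4, 0.5, "relu"),
    "lstm": ((32, 32), 3e-4, 0.7, "tanh"),
    "cnn": ((3000, 6000), 3e-5, 0.4, "relu"),
}
TABLE_MOMENTS = {
    "mlp": ((3000, 1000), 3e-4, 0.5, "relu"),
    "lstm": ((128, 1024), 3e-4, 0.4, "tanh"),
    "cnn": ((2000, 4000), 1e-4, 0.4, "relu"),
}


@dataclass(frozen=True)
class NetSpec:
    """Architecture + training hyperparameters of one network."""

    family: str
    layer_widths: tuple[int, int]
    learning_rate: float
    dropout: float
    activation: str = "relu"
    epochs: int = 40
    patience: int = 5
    batch_size: int = 64
    seed: int = 0
    conv_channels: tuple[int, ...] = (8, 16, 24, 24, 16)

    def __post_init__(self) -> None:
        if self.family not in FAMILY_LAYOUT:
            raise ValueError(f"unknown family {self.family!r}")
        if any(w < 1 for w in self.layer_widths):
            raise ValueError("layer widths must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be relu or tanh")


#: Desk-scale learning rates: the published rates suit the published widths;
#: the 100×-smaller nets train on far fewer samples and need larger steps.
_DESK_LR = {"mlp": 3e-4, "lstm": 3e-3, "cnn": 1e-3, "cnn_frozen_conv": 1e-3}


def desk_scale_spec(family: str, target: str = "angles", scale: float = 100.0,
                    seed: int = 0, epochs: int = 40) -> NetSpec:
    """Desk-scale profile of a published configuration.

    Layer widths are divided by ``scale`` (floor 1); the learning rate is
    adapted to the shrunken net and dropout is disabled (nets this small
    underfit with the published rates on a noiseless synthetic cohort).
    Intended for CPU-only runs of the full pipeline in minutes.
    """
    table = TABLE_ANGLES if target == "angles" else TABLE_MOMENTS
    base = "cnn" if family == "cnn_frozen_conv" else family
    widths, _, _, act = table[base]
    if base == "lstm":
        # recurrent hidden sizes are already desk-scale; shrinking them to
        # near-zero units would destroy the family rather than scale it
        scaled = tuple(max(16, int(round(w / scale))) for w in widths)
    else:
        scaled = tuple(max(1, int(round(w / scale))) for w in widths)
    return NetSpec(
        family=family,
        layer_widths=scaled,
        learning_rate=_DESK_LR[family],
        dropout=0.0,
        activation=act,
        epochs=epochs,
        seed=seed,
    )


@dataclass
class TrainHistory:
    """Per-epoch MAE losses plus the stopping bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0


def _activation(name: str):
    from .nn import ReLU, Tanh

    return ReLU() if name == "relu" else Tanh()


class RegressionNet:
    """A built (possibly fitted) network bound to one layout.

    Handles the layout-specific reshaping between tensors and the network's
    native input/output spaces: sequence tensors are channel-major
    ``(n, C, T)`` while the recurrent stack runs time-major ``(n, T, C)``;
    flat and image families emit a flat ``18·T`` vector.
    """

    def __init__(self, spec: NetSpec, layout: str, in_shape: tuple, out_shape: tuple):
        if FAMILY_LAYOUT[spec.family] != layout:
            raise ValueError(f"family {spec.family!r} requires layout "
                             f"{FAMILY_LAYOUT[spec.family]!r}, got {layout!r}")
        from .nn import (
            Conv2D, Dense, Dropout, Flatten, LSTM, MaxPool2D, Sequential,
        )

        self.spec = spec
        self.layout = layout
        self.in_shape = tuple(in_shape)
        self.out_shape = tuple(out_shape)
        rng = np.random.default_rng(spec.seed)
        w1, w2 = spec.layer_widths
        layers: list = []
        if spec.family == "mlp":
            n_in = int(np.prod(in_shape))
            n_out = int(np.prod(out_shape))
            layers = [
                Dense(n_in, w1, rng), _activation(spec.activation),
                Dropout(spec.dropout),
                Dense(w1, w2, rng), _activation(spec.activation),
                Dropout(spec.dropout),
                Dense(w2, n_out, rng),
            ]
        elif spec.family == "lstm":
            n_ch, _ = in_shape  # (channels, time)
            out_ch = out_shape[0]
            layers = [
                LSTM(n_ch, w1, rng),
                Dropout(spec.dropout),
                LSTM(w1, w2, rng),
                Dropout(spec.dropout),
                Dense(w2, out_ch, rng),
            ]
        else:  # cnn / cnn_frozen_conv
            side = in_shape[0]
            chans = spec.conv_channels
            kernels = (7, 5, 3, 3, 3)
            strides = (2, 1, 1, 1, 1) if side <= 64 else (4, 1, 1, 1, 1)
            pools = (True, True, False, False, True)
            conv_layers: list = []
            c_prev = in_shape[-1]
            for c, k, s, p in zip(chans, kernels, strides, pools):
                conv_layers.append(Conv2D(c_prev, c, k, s, rng))
                conv_layers.append(_activation(spec.activation))
                if p:
                    conv_layers.append(MaxPool2D(2))
                c_prev = c
            if spec.family == "cnn_frozen_conv":
                for layer in conv_layers:
                    layer.trainable = False
            probe = Sequential(conv_layers).forward(np.zeros((1, *in_shape)))
            n_flat = int(np.prod(probe.shape[1:]))
            n_out = int(np.prod(out_shape))
            layers = conv_layers + [
                Flatten(),
                Dense(n_flat, w1, rng), _activation(spec.activation),
                Dropout(spec.dropout),
                Dense(w1, w2, rng), _activation(spec.activation),
                Dropout(spec.dropout),
                Dense(w2, n_out, rng),
            ]
        self.net = Sequential(layers)

    # -- layout adapters ---------------------------------------------------
    def _to_net_x(self, X: np.ndarray) -> np.ndarray:
        if self.spec.family == "lstm":
            return X.transpose(0, 2, 1)  # (n, T, C)
        return X

    def _to_net_y(self, Y: np.ndarray) -> np.ndarray:
        if self.spec.family == "lstm":
            return Y.transpose(0, 2, 1)
        return Y

    def _from_net_y(self, out: np.ndarray) -> np.ndarray:
        if self.spec.family == "lstm":
            return out.transpose(0, 2, 1)
        return out

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        return self._from_net_y(self.net.forward(self._to_net_x(X), train, rng))

    def n_trainable(self) -> int:
        return self.net.n_trainable()


def build_model(spec: NetSpec, layout: str, in_shape: tuple,
                out_shape: tuple) -> RegressionNet:
    """Construct an untrained network for a layout (see module docstring)."""
    return RegressionNet(spec, layout, in_shape, out_shape)


def train_model(
    model: RegressionNet,
    train: DatasetTensors,
    val: DatasetTensors,
    spec: NetSpec | None = None,
) -> TrainHistory:
    """Fit in place with Adam on MAE; early stopping on validation loss.

    The epoch counter stops as soon as the validation loss has failed to
    improve for more than ``patience`` consecutive epochs; the best-epoch
    weights are restored before returning.  Deterministic given the spec
    seed (single-threaded numpy).
    """
    from .nn import Adam, mae_loss

    spec = spec or model.spec
    rng = np.random.default_rng(spec.seed + 1)
    opt = Adam(model.net, lr=spec.learning_rate)
    Xtr = model._to_net_x(train.X)
    Ytr = model._to_net_y(train.Y)
    Xval = model._to_net_x(val.X)
    Yval = model._to_net_y(val.Y)
    n = Xtr.shape[0]
    hist = TrainHistory()
    best = math.inf
    best_weights = model.net.get_weights()
    bad_epochs = 0
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, spec.batch_size):
            idx = order[i : i + spec.batch_size]
            pred = model.net.forward(Xtr[idx], train=True, rng=rng)
            loss, g = mae_loss(pred, Ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}; lr={spec.learning_rate}"
                )
            model.net.backward(g)
            opt.step()
            losses.append(loss)
        val_loss, _ = mae_loss(model.net.forward(Xval), Yval)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(float(val_loss))
        hist.stop_epoch = epoch + 1
        if val_loss < best:
            best = val_loss
            hist.best_epoch = epoch + 1
            best_weights = model.net.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > spec.patience:
                break
    model.net.set_weights(best_weights)
    return hist


def predict(model: RegressionNet, tensors: DatasetTensors,
            y_scaler: Scaler | None = None) -> np.ndarray:
    """Predict in original units, reshaped to (n, 18, T).

    ``y_scaler`` defaults to the scaler carried by the tensors; flat/image
    outputs are unflattened channel-major.
    """
    out = model.forward(tensors.X)
    scaler = y_scaler or tensors.y_scaler
    if scaler is not None:
        out = scaler.inverse(out.reshape(tensors.Y.shape))
    n = out.shape[0]
    if out.ndim == 2:  # flat 18·T
        out = out.reshape(n, 18, -1)
    return out


# ---------------------------------------------------------------------------
# hyperband search


@dataclass
class SearchSpace:
    """Bounds for the hyperband search.  Widths and learning rate are drawn
    log-uniformly, dropout uniformly; activation from the listed choices."""

    width1: tuple[int, int] = (16, 512)
    width2: tuple[int, int] = (16, 512)
    learning_rate: tuple[float, float] = (1e-5, 1e-2)
    dropout: tuple[float, float] = (0.0, 0.8)
    activations: tuple[str, ...] = ("relu", "tanh")

    def sample(self, family: str, rng: np.random.Generator, seed: int) -> NetSpec:
        def log_int(lo, hi):
            if lo == hi:
                return lo
            return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))

        lr_lo, lr_hi = self.learning_rate
        lr = lr_lo if lr_lo == lr_hi else float(
            np.exp(rng.uniform(np.log(lr_lo), np.log(lr_hi)))
        )
        return NetSpec(
            family=family,
            layer_widths=(log_int(*self.width1), log_int(*self.width2)),
            learning_rate=lr,
            dropout=float(rng.uniform(*self.dropout)),
            activation=str(rng.choice(list(self.activations))),
            seed=seed,
        )

    def strictly_inside(self, spec: NetSpec) -> bool:
        checks = [
            (self.width1, spec.layer_widths[0]),
            (self.width2, spec.layer_widths[1]),
            (self.learning_rate, spec.learning_rate),
            (self.dropout, spec.dropout),
        ]
        return all(lo == hi or lo < v < hi for (lo, hi), v in checks)


def hyperband_search(
    space: SearchSpace | list[NetSpec],
    budget: int,
    layout: str,
    train: DatasetTensors,
    val: DatasetTensors,
    seed: int = 0,
    family: str | None = None,
    max_epochs: int = 27,
    eta: int = 3,
) -> NetSpec:
    """Hyperband hyperparameter search (successive halving, factor ``eta``).

    ``budget`` is the number of brackets to run, from the most exploratory
    (many configurations, few epochs) downward.  A list of explicit specs is
    treated as a single successive-halving bracket over that list.  The
    winning spec's continuous parameters are checked to lie strictly inside
    the search bounds; a boundary winner raises, signalling the bounds are
    too tight.  Deterministic given the seed.
    """
    if budget < 1:
        raise ValueError("budget must be at least one bracket")
    rng = np.random.default_rng(seed)

    def evaluate(spec: NetSpec, n_epochs: int) -> float:
        run_spec = replace(spec, epochs=n_epochs, patience=max(1, n_epochs))
        model = build_model(run_spec, layout, train.X.shape[1:], train.Y.shape[1:])
        hist = train_model(model, train, val, run_spec)
        return min(hist.val_loss)

    def halving(specs: list[NetSpec], r0: int) -> tuple[NetSpec, float]:
        specs = list(specs)
        r = r0
        while True:
            scores = [evaluate(s, max(1, r)) for s in specs]
            order = np.argsort(scores)
            if len(specs) == 1:
                return specs[0], scores[0]
            keep = max(1, len(specs) // eta)
            specs = [specs[i] for i in order[:keep]]
            r *= eta
            if len(specs) == 1:
                return specs[0], evaluate(specs[0], min(r, max_epochs))

    if isinstance(space, list):
        if not space:
            raise ValueError("empty search space")
        best_spec, _ = halving(space, max(1, max_epochs // eta))
        return best_spec

    s_max = int(math.log(max_epochs, eta))
    best_spec, best_score = None, math.inf
    for s in range(s_max, -1, -1)[:budget]:
        n = int(math.ceil((s_max + 1) / (s + 1) * eta**s))
        r0 = max(1, int(max_epochs * eta**-s))
        specs = [space.sample(family or FAMILY_LAYOUT_INV[layout], rng,
                              int(rng.integers(0, 2**31 - 1))) for _ in range(n)]
        spec, score = halving(specs, r0)
        if score < best_score:
            best_spec, best_score = spec, score
    if not space.strictly_inside(best_spec):
        raise RuntimeError(
            "hyperband winner lies on a search boundary; widen the bounds"
        )
    return best_spec


FAMILY_LAYOUT_INV = {"flat": "mlp", "sequence": "lstm", "image": "cnn"}


# ---------------------------------------------------------------------------
# statsmodels-style model / results pair


class JointPredictionModel:
    """Joint-curve regression model bound to scaled dataset tensors.

    Parameters
    ----------
    train, val : DatasetTensors
        Scaled tensors (see :func:`imugait.preprocess.fit_scalers`); the
        validation partition drives early stopping.  ``val`` may equal
        ``train`` for tiny closed-loop experiments.
    spec : NetSpec
        Architecture and training hyperparameters.
    """

    def __init__(self, train: DatasetTensors, val: DatasetTensors, spec: NetSpec):
        self.train_tensors = train
        self.val_tensors = val
        self.spec = spec
        self.net = build_model(spec, train.layout, train.X.shape[1:],
                               train.Y.shape[1:])

    def fit(self) -> "JointPredictionResults":
        history = train_model(self.net, self.train_tensors, self.val_tensors,
                              self.spec)
        return JointPredictionResults(self, history)


class JointPredictionResults:
    """Fitted network plus training history, metrics and a summary table."""

    def __init__(self, model: JointPredictionModel, history: TrainHistory):
        self.model = model
        self.history = history

    def predict(self, tensors: DatasetTensors) -> np.ndarray:
        """Predictions in original units, (n, 18, T)."""
        return predict(self.model.net, tensors,
                       self.model.train_tensors.y_scaler)

    def metrics(self, tensors: DatasetTensors, truth: np.ndarray):
        """Per-channel nRMSE and Pearson r against original-unit targets."""
        from .evaluate import channel_metrics

        return channel_metrics(self.predict(tensors), truth)

    def summary(self) -> str:
        s = self.model.spec
        lines = [
            "Joint prediction results",
            "=" * 40,
            f"family            {s.family}",
            f"layer widths      {s.layer_widths[0]}-{s.layer_widths[1]}",
            f"learning rate     {s.learning_rate:g}",
            f"dropout           {s.dropout:g}",
            f"activation        {s.activation}",
            f"trainable params  {self.model.net.n_trainable()}",
            f"epochs run        {self.history.stop_epoch}",
            f"best epoch        {self.history.best_epoch}",
            f"final train MAE   {self.history.train_loss[-1]:.5f}",
            f"best val MAE      {min(self.history.val_loss):.5f}",
        ]
        return "\n".join(lines)
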