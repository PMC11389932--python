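"""CNN accessibility models, statsmodels-style.

``SequenceRegression`` and ``SequenceClassifier`` are model objects built from
a training and a validation :class:`~peakvar.seqdata.SequenceDataset`; their
``fit()`` returns a :class:`CNNResults` carrying the selected weights, the
per-epoch loss history, prediction / evaluation / attribution methods and a
``summary()`` table. Transfer learning (pre-train on accessibility, fine-tune
on reporter-assay activity) hangs off the results object via ``fine_tune``.

The architectures follow the open-chromatin CNN family: one or more
convolution blocks (ReLU), max pooling, dropout, an optional dense sigmoid
layer and a single output unit — linear for regression of peak signal,
sigmoid for open/closed classification. Model selection always returns the
weights from the epoch with the lowest validation loss.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import nn
from .seqdata import SequenceDataset


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvBlock:
    """One convolution (ReLU) optionally followed by max pooling + dropout."""

    n_filters: int
    kernel: int = 8
    stride: int = 1
    pool_size: int | None = None
    pool_stride: int | None = None
    dropout: float = 0.0
    l2: float = 0.0


@dataclass(frozen=True)
class ModelSpec:
    """Architecture of a sequence-to-scalar CNN.

    Either supply ``conv_layers`` (a stack of (filters, kernel, stride)
    convolutions followed by ONE pooling layer + dropout — the bulk DNase
    architecture), or ``blocks`` for architectures that alternate convolution
    and pooling (the scATAC architecture). ``kind`` decides the output unit:
    linear for ``regression``, sigmoid for ``classifier``.
    """

    kind: str = "regression"
    input_length: int = 1000
    conv_layers: tuple = ((1000, 8, 1), (200, 8, 1), (200, 8, 1))
    pool: tuple = (13, 13)
    dropout: float = 0.5
    dense_units: int = 100
    dense_activation: str = "sigmoid"
    blocks: tuple = ()

    def __post_init__(self):
        if self.kind not in ("regression", "classifier"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not self.blocks and not self.conv_layers:
            raise ValueError("at least one convolution layer is required")
        if self.dense_activation not in ("sigmoid", "relu", "none"):
            raise ValueError(f"unknown dense activation {self.dense_activation!r}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def output_activation(self) -> str:
        return "sigmoid" if self.kind == "classifier" else "none"

    def as_blocks(self) -> tuple:
        if self.blocks:
            return tuple(
                b if isinstance(b, ConvBlock) else ConvBlock(**b) for b in self.blocks
            )
        blocks = []
        n = len(self.conv_layers)
        for i, (f, k, s) in enumerate(self.conv_layers):
            last = i == n - 1
            blocks.append(
                ConvBlock(
                    f,
                    k,
                    s,
                    pool_size=self.pool[0] if last else None,
                    pool_stride=self.pool[1] if last else None,
                    dropout=self.dropout if last else 0.0,
                )
            )
        return tuple(blocks)


@dataclass(frozen=True)
class TrainSpec:
    """SGD training configuration.

    ``loss`` is one of ``mse``, ``weighted_mse`` (with ``loss_threshold`` /
    ``loss_factor`` up-weighting high-signal peaks) or ``cross_entropy``.
    The cyclic schedule is triangular between ``min_lr`` and ``max_lr`` with
    period ``cycle_epochs`` epochs.
    """

    loss: str = "mse"
    loss_threshold: float = 4.0
    loss_factor: float = 3.0
    learning_rate: float = 0.01
    momentum: float = 0.0
    batch_size: int = 100
    epochs: int = 30
    lr_schedule: str = "constant"
    min_lr: float = 1e-3
    max_lr: float = 1e-1
    cycle_epochs: int = 2
    max_grad_norm: float | None = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss not in ("mse", "weighted_mse", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def make_loss(self) -> nn.Loss:
        if self.loss == "mse":
            return nn.MSELoss()
        if self.loss == "weighted_mse":
            return nn.WeightedMSELoss(self.loss_threshold, self.loss_factor)
        return nn.BCEWithLogitsLoss()


def build_model(spec: ModelSpec, seed: int = 0) -> nn.Network:
    """Instantiate the (untrained) network a :class:`ModelSpec` describes.

    Raises ``ValueError`` when the input is shorter than the receptive field.
    """
    rng = np.random.default_rng(seed)
    layers = []
    L = spec.input_length
    channels = 4
    for block in spec.as_blocks():
        conv = nn.Conv1D(channels, block.n_filters, block.kernel, block.stride,
                         l2=block.l2, rng=rng)
        L = conv.out_length(L)
        layers.extend([conv, nn.ReLU()])
        channels = block.n_filters
        if block.pool_size:
            pool = nn.MaxPool1D(block.pool_size, block.pool_stride)
            L = pool.out_length(L)
            layers.append(pool)
        if block.dropout:
            layers.append(nn.Dropout(block.dropout))
    layers.append(nn.Flatten())
    features = L * channels
    if spec.dense_units:
        layers.append(nn.Dense(features, spec.dense_units, rng=rng))
        if spec.dense_activation == "sigmoid":
            layers.append(nn.Sigmoid())
        elif spec.dense_activation == "relu":
            layers.append(nn.ReLU())
        features = spec.dense_units
    layers.append(nn.Dense(features, 1, rng=rng))
    # the output stays linear inside the network; classifier probabilities are
    # produced by applying a sigmoid at prediction time (numerically stable
    # cross-entropy during training)
    return nn.Network(layers)


# ---------------------------------------------------------------------------
# model objects
# ---------------------------------------------------------------------------

class SequenceModel:
    """Base model: data + specs in, ``fit()`` out."""

    kind: str = "regression"

    def __init__(self, train_data: SequenceDataset, val_data: SequenceDataset,
                 spec: ModelSpec | None = None, train_spec: TrainSpec | None = None):
        if len(val_data) == 0:
            raise ValueError("validation set must be non-empty")
        spec = spec or self.default_spec(train_data.X.shape[1])
        if spec.kind != self.kind:
            raise ValueError(f"spec kind {spec.kind!r} does not match {self.kind!r}")
        if train_data.X.shape[1] != spec.input_length:
            raise ValueError(
                f"training input length {train_data.X.shape[1]} != spec "
                f"input_length {spec.input_length}"
            )
        if val_data.X.shape[1] != spec.input_length:
            raise ValueError("validation input length differs from spec")
        self.train_data = train_data
        self.val_data = val_data
        self.spec = spec
        self.train_spec = train_spec or self.default_train_spec()

    def default_spec(self, input_length):
        raise NotImplementedError

    def default_train_spec(self):
        return TrainSpec()

    def fit(self, start_weights=None) -> "CNNResults":
        """Train with SGD and return the min-validation-loss epoch's weights."""
        tspec = self.train_spec
        rng = np.random.default_rng(tspec.seed)
        network = build_model(self.spec, seed=tspec.seed)
        if start_weights is not None:
            network.set_weights(start_weights)
        else:
            # start the output unit at the marginal prediction (label mean /
            # base-rate logit) so early gradients are not dominated by a
            # constant offset, which can silence ReLU features
            out_bias = network.layers[-1].b
            if self.kind == "regression":
                out_bias[:] = float(np.mean(self.train_data.y))
            else:
                rate = float(np.clip(np.mean(self.train_data.y), 1e-3, 1 - 1e-3))
                out_bias[:] = np.log(rate / (1 - rate))
        loss = tspec.make_loss()
        if self.kind == "classifier" and tspec.loss != "cross_entropy":
            loss = nn.BCEWithLogitsLoss()

        X, y = self.train_data.X, self.train_data.y
        n = len(y)
        batch = min(tspec.batch_size, n)
        n_batches = int(np.ceil(n / batch))
        if tspec.lr_schedule == "cyclic":
            schedule = nn.CyclicLR(tspec.min_lr, tspec.max_lr,
                                   period_steps=max(2, tspec.cycle_epochs * n_batches))
        else:
            schedule = nn.ConstantLR(tspec.learning_rate)
        opt = nn.SGD(network, schedule, momentum=tspec.momentum,
                     max_grad_norm=tspec.max_grad_norm)

        history = []
        best = (np.inf, None, -1)
        for epoch in range(1, tspec.epochs + 1):
            order = rng.permutation(n)
            epoch_losses = []
            for b in range(n_batches):
                idx = order[b * batch : (b + 1) * batch]
                raw = network.forward(X[idx], training=True, rng=rng)
                batch_loss = loss.value(raw, y[idx])
                if not np.isfinite(batch_loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; the "
                        "learning rate is probably too high"
                    )
                epoch_losses.append(batch_loss)
                network.backward(loss.grad(raw, y[idx]))
                opt.step()
            val_raw = _forward_batched(network, self.val_data.X)
            val_loss = loss.value(val_raw, self.val_data.y)
            if not np.isfinite(val_loss):
                raise RuntimeError(
                    f"non-finite validation loss at epoch {epoch}; the "
                    "learning rate is probably too high"
                )
            history.append(
                {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                 "val_loss": float(val_loss)}
            )
            if val_loss < best[0]:
                best = (val_loss, network.get_weights(), epoch)
        network.set_weights(best[1])
        return CNNResults(
            spec=self.spec,
            train_spec=tspec,
            network=network,
            history=pd.DataFrame(history),
            selected_epoch=best[2],
        )


class SequenceRegression(SequenceModel):
    """CNN regression of quantitative accessibility signal on sequence."""

    kind = "regression"

    def default_spec(self, input_length):
        return ModelSpec(kind="regression", input_length=input_length,
                         conv_layers=((64, 8, 1),), pool=(13, 13), dropout=0.2,
                         dense_units=32)


class SequenceClassifier(SequenceModel):
    """CNN classification of open (peak) vs closed (GC-matched background)."""

    kind = "classifier"

    def default_spec(self, input_length):
        return ModelSpec(kind="classifier", input_length=input_length,
                         conv_layers=((64, 8, 1),), pool=(13, 13), dropout=0.2,
                         dense_units=32)

    def default_train_spec(self):
        return TrainSpec(loss="cross_entropy")


def _forward_batched(network, X, batch_size=256):
    outs = [
        network.forward(X[i : i + batch_size], training=False)
        for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(outs, axis=0)


class CNNResults:
    """Fitted-model results: weights, history, prediction and diagnostics."""

    def __init__(self, spec, train_spec, network, history, selected_epoch,
                 pretrain_history=None):
        self.spec = spec
        self.train_spec = train_spec
        self.network = network
        self.history = history
        self.selected_epoch = selected_epoch
        self.pretrain_history = pretrain_history

    # -- prediction ---------------------------------------------------------
    def predict(self, X, batch_size=256) -> np.ndarray:
        """Model output for a batch of one-hot matrices.

        Regression: the raw signal prediction. Classifier: the sigmoid
        probability, strictly inside (0, 1). Deterministic given the weights.
        """
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1] != self.spec.input_length or X.shape[2] != 4:
            raise ValueError(
                f"expected input of shape (n, {self.spec.input_length}, 4), "
                f"got {X.shape}"
            )
        raw = _forward_batched(self.network, X, batch_size).ravel()
        if self.spec.kind == "classifier":
            return np.clip(nn.sigmoid(raw), 1e-12, 1 - 1e-12)
        return raw

    def evaluate(self, data: SequenceDataset) -> dict:
        pred = self.predict(data.X)
        if self.spec.kind == "classifier":
            return evaluate_classifier(pred, data.y)
        return evaluate_regression(pred, data.y)

    # -- attribution --------------------------------------------------------
    def contribution_scores(self, onehot, reference=None) -> np.ndarray:
        """Per-position, per-base contribution scores against a reference.

        The default reference is the all-zero matrix (an all-N sequence).
        Scores satisfy completeness: they sum to f(x) - f(reference).
        See :mod:`peakvar.attribution`.
        """
        from .attribution import contribution_scores

        return contribution_scores(self, onehot, reference)

    # -- transfer learning --------------------------------------------------
    def fine_tune(self, train_data, val_data, learning_rate, epochs,
                  batch_size=None, seed=None, loss="mse") -> "CNNResults":
        """Continue training all weights on a new labelled dataset."""
        if train_data.X.shape[1] != self.spec.input_length:
            raise ValueError(
                "fine-tuning data input length differs from the pretrained model"
            )
        if epochs == 0:
            return CNNResults(self.spec, self.train_spec,
                              copy.deepcopy(self.network),
                              pd.DataFrame(columns=["epoch", "train_loss", "val_loss"]),
                              self.selected_epoch,
                              pretrain_history=self.history)
        tspec = TrainSpec(
            loss=loss,
            learning_rate=learning_rate,
            momentum=self.train_spec.momentum,
            batch_size=batch_size or self.train_spec.batch_size,
            epochs=epochs,
            seed=self.train_spec.seed if seed is None else seed,
        )
        cls = SequenceClassifier if self.spec.kind == "classifier" else SequenceRegression
        model = cls(train_data, val_data, spec=self.spec, train_spec=tspec)
        results = model.fit(start_weights=self.network.get_weights())
        results.pretrain_history = self.history
        return results

    # -- reporting / persistence -------------------------------------------
    @property
    def n_params(self):
        return int(sum(w.size for w in self.network.get_weights()))

    def summary(self) -> str:
        spec, h = self.spec, self.history
        lines = [
            "CNN sequence model results",
            "=" * 42,
            f"kind:            {spec.kind}",
            f"input length:    {spec.input_length} bp",
            f"parameters:      {self.n_params}",
            f"epochs run:      {len(h)}",
            f"selected epoch:  {self.selected_epoch} (min validation loss)",
        ]
        if len(h):
            row = h[h.epoch == self.selected_epoch].iloc[0]
            lines.append(f"train loss:      {row.train_loss:.5g}")
            lines.append(f"val loss:        {row.val_loss:.5g}")
        lines.append("-" * 42)
        for block in spec.as_blocks():
            pool = (f" -> maxpool {block.pool_size}/{block.pool_stride}"
                    if block.pool_size else "")
            drop = f" -> dropout {block.dropout}" if block.dropout else ""
            lines.append(
                f"conv {block.n_filters}@{block.kernel} stride {block.stride}"
                f"{pool}{drop}"
            )
        if spec.dense_units:
            lines.append(f"dense {spec.dense_units} ({spec.dense_activation})")
        lines.append(f"output: 1 unit ({spec.output_activation or 'linear'})")
        return "\n".join(lines)

    def save(self, prefix):
        """Write weights (npz) plus a JSON sidecar with specs and history."""
        weights = self.network.get_weights()
        np.savez_compressed(
            f"{prefix}.weights.npz", **{f"w{i}": w for i, w in enumerate(weights)}
        )
        sidecar = {
            "spec": asdict(self.spec),
            "train_spec": asdict(self.train_spec),
            "selected_epoch": int(self.selected_epoch),
            "history": self.history.to_dict(orient="list"),
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "CNNResults":
        with open(f"{prefix}.json") as fh:
            sidecar = json.load(fh)
        sidecar["spec"]["conv_layers"] = tuple(
            tuple(c) for c in sidecar["spec"]["conv_layers"]
        )
        sidecar["spec"]["pool"] = tuple(sidecar["spec"]["pool"])
        sidecar["spec"]["blocks"] = tuple(
            ConvBlock(**b) if isinstance(b, dict) else ConvBlock(*b)
            for b in sidecar["spec"]["blocks"]
        )
        spec = ModelSpec(**sidecar["spec"])
        tspec = TrainSpec(**sidecar["train_spec"])
        network = build_model(spec, seed=tspec.seed)
        data = np.load(f"{prefix}.weights.npz")
        network.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return cls(spec, tspec, network, pd.DataFrame(sidecar["history"]),
                   sidecar["selected_epoch"])


# ---------------------------------------------------------------------------
# transfer learning
# ---------------------------------------------------------------------------

def pretrain_finetune(
    accessibility_train, accessibility_val,
    mpra_train, mpra_val,
    spec: ModelSpec | None = None,
    pretrain_train_spec: TrainSpec | None = None,
    finetune_lr: float = 0.08,
    finetune_epochs: int = 50,
    seed: int = 0,
):
    """Pre-train on accessibility signal, fine-tune on reporter activity.

    Phase 1 fits a regression on peak windows (signal labels) plus GC-matched
    negatives labelled 0; phase 2 continues training all weights on MPRA
    activity with its own learning rate. Returns the fine-tuned
    :class:`CNNResults` (whose ``pretrain_history`` holds phase 1) and the
    pretrained results.
    """
    if accessibility_train.X.shape[1] != mpra_train.X.shape[1]:
        raise ValueError(
            "accessibility and MPRA phases must share one input length "
            f"({accessibility_train.X.shape[1]} vs {mpra_train.X.shape[1]})"
        )
    tspec = pretrain_train_spec or TrainSpec(seed=seed)
    if tspec.seed != seed:
        tspec = TrainSpec(**{**asdict(tspec), "seed": seed})
    model = SequenceRegression(accessibility_train, accessibility_val,
                               spec=spec, train_spec=tspec)
    pretrained = model.fit()
    finetuned = pretrained.fine_tune(
        mpra_train, mpra_val, learning_rate=finetune_lr, epochs=finetune_epochs,
        seed=seed,
    )
    return finetuned, pretrained


# ---------------------------------------------------------------------------
# transforms and metrics
# ---------------------------------------------------------------------------

def logit(p, eps: float = 1e-7):
    """Inverse sigmoid with clipping: log(p'/(1-p')), p' = clip(p, eps, 1-eps).

    Puts classifier probabilities on an unbounded scale before differencing
    ref/alt alleles.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def evaluate_regression(pred, truth) -> dict:
    """Pearson r, Spearman rho (ties mid-ranked) and MSE; NaN when constant."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.size < 3 or pred.shape != truth.shape:
        raise ValueError("need >= 3 paired values")
    out = {"mse": float(np.mean((pred - truth) ** 2))}
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        out["pearson_r"] = float("nan")
        out["spearman_rho"] = float("nan")
    else:
        out["pearson_r"] = float(sps.pearsonr(pred, truth).statistic)
        out["spearman_rho"] = float(sps.spearmanr(pred, truth).statistic)
    return out


def evaluate_classifier(pred, labels) -> dict:
    """auROC and auPRC; requires both classes present."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    pred = np.asarray(pred, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if pred.size < 3 or pred.shape != labels.shape:
        raise ValueError("need >= 3 paired values")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return {
        "auroc": float(roc_auc_score(labels, pred)),
        "auprc": float(average_precision_score(labels, pred)),
    }


# ---------------------------------------------------------------------------
# full-size and desk-scale presets
# ---------------------------------------------------------------------------

PRESETS: dict[str, tuple[ModelSpec, TrainSpec]] = {
    # full-size bulk DNase 1000 bp architectures
    "dnase_regression": (
        ModelSpec("regression", 1000, ((1000, 8, 1), (200, 8, 1), (200, 8, 1)),
                  (13, 13), 0.5, 100, "sigmoid"),
        TrainSpec(loss="mse", learning_rate=0.01, batch_size=100, epochs=100),
    ),
    "dnase_classifier": (
        ModelSpec("classifier", 1000, ((1000, 8, 1), (200, 8, 1), (200, 8, 1)),
                  (13, 13), 0.5, 100, "sigmoid"),
        TrainSpec(loss="cross_entropy", learning_rate=0.01, batch_size=64,
                  epochs=100),
    ),
    # 500 bp scATAC pseudobulk architecture: alternating conv/pool blocks,
    # weighted MSE (threshold 4, factor 3), cyclic learning rate
    "scatac_regression": (
        ModelSpec(
            "regression", 500, dense_units=0,
            blocks=(
                ConvBlock(500, 8, 1, pool_size=4, pool_stride=4, dropout=0.001),
                ConvBlock(250, 8, 1, pool_size=4, pool_stride=4, dropout=0.25,
                          l2=0.01),
                ConvBlock(100, 8, 1, pool_size=4, pool_stride=4, dropout=0.25,
                          l2=0.01),
            ),
        ),
        TrainSpec(loss="weighted_mse", lr_schedule="cyclic", batch_size=100,
                  epochs=100),
    ),
    # 150 bp transfer-learning pair
    "transfer_dnase": (
        ModelSpec("regression", 150, ((200, 8, 1), (200, 8, 1)), (13, 13), 0.8,
                  100, "sigmoid"),
        TrainSpec(loss="mse", learning_rate=0.01, momentum=0.0, batch_size=100,
                  epochs=100),
    ),
    "mpra_quarter": (
        ModelSpec("regression", 150, ((1000, 8, 1), (100, 8, 1), (100, 8, 1)),
                  (13, 13), 0.8, 50, "sigmoid"),
        TrainSpec(loss="mse", learning_rate=0.02, batch_size=100, epochs=100),
    ),
    # desk-scale presets used by the bundled synthetic benchmark; the
    # regression mirrors the generator's max-match structure (wide pooling,
    # direct linear readout) for per-base variant sensitivity
    "synthetic_regression": (
        ModelSpec("regression", 500, dense_units=0, dense_activation="none",
                  blocks=(ConvBlock(64, 8, 1, pool_size=61, pool_stride=61),)),
        TrainSpec(loss="mse", learning_rate=0.005, batch_size=64, epochs=60,
                  momentum=0.9),
    ),
    "synthetic_classifier": (
        ModelSpec("classifier", 500, ((32, 8, 1),), (13, 13), 0.2, 32, "sigmoid"),
        TrainSpec(loss="cross_entropy", learning_rate=0.05, batch_size=32,
                  epochs=60, momentum=0.9),
    ),
    "synthetic_transfer": (
        ModelSpec("regression", 150, ((32, 8, 1),), (13, 13), 0.2, 32,
                  "sigmoid"),
        TrainSpec(loss="mse", learning_rate=0.01, batch_size=32, epochs=80,
                  momentum=0.9),
    ),
}


def get_preset(name: str):
    try:
        spec, tspec = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return spec, tspec
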