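"""Fully connected softmax classifier for lesion subtyping, plus the
lesion-grouped data splitting and the architecture-sweep protocol.

The network is input -> [dense(nodes) -> ELU -> batchnorm] x L -> dense(5)
-> softmax, trained with Adam (beta1 = 0.9, beta2 = 0.999) on categorical
cross-entropy with minibatches of 200. Features are z-scored with statistics
fit on the training split only. Implemented directly on numpy so that
training is bit-reproducible given a seed.

Splitting is grouped by lesion: voxels of one lesion never straddle the test
boundary, which is what makes the test accuracy an honest estimate on
spatially correlated voxel data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contrasts import CLASSES
from .errors import NumericalError, ValidationError

#: feature columns per model variant, in fixed documented order
FEATURE_SETS = {
    "DBSI": [
        "dbsi_fiber_fraction", "dbsi_fiber_fa", "dbsi_fiber_ad", "dbsi_fiber_rd",
        "dbsi_restricted_fraction", "dbsi_hindered_fraction", "dbsi_water_fraction",
        "dbsi_b0_norm", "t1_ir", "t2_ir",
    ],
    "DTI": ["dti_adc", "dti_fa", "dti_ad", "dti_rd", "t1_ir", "t2_ir"],
    "MTR": ["mtr", "t1_ir", "t2_ir"],
    "cMRI": ["t1_ir", "t2_ir"],
}


@dataclass
class DnnConfig:
    """Architecture and optimization settings of one classifier."""

    n_hidden_layers: int = 10
    nodes_per_layer: int = 100
    batchnorm: bool = True
    minibatch: int = 200
    learning_rate: float = 1.0e-3
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 150
    seed: int = 0
    feature_variant: str = "DBSI"
    early_stopping: bool = False
    patience: int = 20
    stop_at_val_accuracy: float | None = None  # optional stop once reached

    def __post_init__(self):
        if self.n_hidden_layers < 0:
            raise ValidationError("n_hidden_layers must be >= 0")
        if self.nodes_per_layer < 1 or self.minibatch < 1:
            raise ValidationError("nodes_per_layer and minibatch must be >= 1")
        if self.feature_variant not in FEATURE_SETS:
            raise ValidationError(
                f"unknown feature_variant {self.feature_variant!r}; "
                f"choose from {sorted(FEATURE_SETS)}"
            )

    @property
    def input_width(self) -> int:
        return len(FEATURE_SETS[self.feature_variant])


def build_features(records, variant: str) -> np.ndarray:
    """Assemble the feature matrix of a variant from a voxel table.

    Accepts a DataFrame (rows -> matrix) or a single mapping (-> vector).
    Missing columns raise a validation error naming the first absentee.
    """
    if variant not in FEATURE_SETS:
        raise ValidationError(f"unknown feature variant {variant!r}")
    cols = FEATURE_SETS[variant]
    if isinstance(records, pd.DataFrame):
        missing = [c for c in cols if c not in records.columns]
        if missing:
            raise ValidationError(f"missing metric column {missing[0]!r} for variant {variant}")
        return records[cols].to_numpy(dtype=float)
    missing = [c for c in cols if c not in records]
    if missing:
        raise ValidationError(f"missing metric {missing[0]!r} for variant {variant}")
    return np.array([float(records[c]) for c in cols])


# ---------------------------------------------------------------------------
# Lesion-grouped splitting
# ---------------------------------------------------------------------------

@dataclass
class Partitions:
    """Disjoint voxel index sets plus the lesion -> partition map."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    lesion_assignment: dict

    def __post_init__(self):
        sets = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValidationError("partitions overlap")

    @property
    def n_total(self) -> int:
        return len(self.train_idx) + len(self.val_idx) + len(self.test_idx)


def grouped_split(
    lesion_ids,
    lesion_classes,
    ratios=(8, 1, 1),
    seed: int = 0,
) -> Partitions:
    """Split voxels 8:1:1 by whole lesions, stratified by class.

    Within each class, lesions are shuffled and greedily assigned to the
    partition with the largest remaining voxel deficit relative to its
    target share, so realized voxel proportions track the ratios as closely
    as the lesion sizes permit. No lesion ever contributes voxels to more
    than one partition.
    """
    lesion_ids = np.asarray(lesion_ids)
    lesion_classes = np.asarray(lesion_classes)
    if lesion_ids.shape != lesion_classes.shape:
        raise ValidationError("lesion_ids and lesion_classes must align")
    targets = np.asarray(ratios, dtype=float)
    targets = targets / targets.sum()
    rng = np.random.default_rng(seed)

    df = pd.DataFrame({"lesion": lesion_ids, "cls": lesion_classes})
    per_lesion = df.groupby("lesion", sort=True).agg(cls=("cls", "first"), size=("cls", "size"))
    assignment: dict[str, int] = {}
    for cls_name in sorted(per_lesion["cls"].unique()):
        block = per_lesion[per_lesion["cls"] == cls_name]
        if len(block) < 3:
            raise ValidationError(
                f"class {cls_name!r} has only {len(block)} lesion(s); "
                "grouped splitting needs at least 3 per class"
            )
        order = rng.permutation(len(block))
        total = block["size"].sum()
        deficit = targets * total
        for i in order:
            lesion = block.index[i]
            part = int(np.argmax(deficit))
            assignment[lesion] = part
            deficit[part] -= block["size"].iloc[i]
        # guarantee every partition sees at least one lesion of the class
        parts_present = set(assignment[l] for l in block.index)
        for missing_part in {0, 1, 2} - parts_present:
            donor_part = max(
                parts_present,
                key=lambda p: sum(assignment[l] == p for l in block.index),
            )
            donors = [l for l in block.index if assignment[l] == donor_part]
            smallest = min(donors, key=lambda l: block.loc[l, "size"])
            assignment[smallest] = missing_part
            parts_present = set(assignment[l] for l in block.index)

    part_per_voxel = np.array([assignment[l] for l in lesion_ids])
    return Partitions(
        train_idx=np.flatnonzero(part_per_voxel == 0),
        val_idx=np.flatnonzero(part_per_voxel == 1),
        test_idx=np.flatnonzero(part_per_voxel == 2),
        lesion_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

_BN_EPS = 1.0e-5


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x, fx):
    return np.where(x > 0, 1.0, fx + 1.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Mlp:
    """Plain-numpy MLP with per-layer batch normalization (float32)."""

    def __init__(self, widths, batchnorm, rng):
        # widths: [in, h, h, ..., out]
        self.batchnorm = batchnorm
        self.W, self.b = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / fan_in)  # He-uniform-equivalent
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32))
            self.b.append(np.zeros(fan_out, dtype=np.float32))
        n_hidden = len(widths) - 2
        self.gamma = [np.ones(widths[i + 1], dtype=np.float32) for i in range(n_hidden)]
        self.beta = [np.zeros(widths[i + 1], dtype=np.float32) for i in range(n_hidden)]
        self.run_mean = [np.zeros(widths[i + 1], dtype=np.float32) for i in range(n_hidden)]
        self.run_var = [np.ones(widths[i + 1], dtype=np.float32) for i in range(n_hidden)]
        self.momentum = 0.9

    @property
    def n_hidden(self):
        return len(self.W) - 1

    def params(self):
        return self.W + self.b + self.gamma + self.beta

    def forward(self, X, training):
        cache = {"a": [X], "z": [], "bn": []}
        h = X
        for i in range(self.n_hidden):
            z = h @ self.W[i] + self.b[i]
            act = _elu(z)
            if self.batchnorm:
                if training:
                    mu = act.mean(axis=0)
                    var = act.var(axis=0)
                    self.run_mean[i] = self.momentum * self.run_mean[i] + (1 - self.momentum) * mu
                    self.run_var[i] = self.momentum * self.run_var[i] + (1 - self.momentum) * var
                else:
                    mu, var = self.run_mean[i], self.run_var[i]
                inv = 1.0 / np.sqrt(var + _BN_EPS)
                xhat = (act - mu) * inv
                h = self.gamma[i] * xhat + self.beta[i]
                cache["bn"].append((xhat, inv))
            else:
                h = act
                cache["bn"].append(None)
            cache["z"].append(z)
            cache["a"].append(h)
        logits = h @ self.W[-1] + self.b[-1]
        return logits, cache

    def backward(self, cache, probs, onehot):
        n = probs.shape[0]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        gg = [None] * len(self.gamma)
        gbeta = [None] * len(self.beta)
        delta = (probs - onehot) / n  # d loss / d logits
        gW[-1] = cache["a"][-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        dh = delta @ self.W[-1].T
        for i in range(self.n_hidden - 1, -1, -1):
            if self.batchnorm:
                xhat, inv = cache["bn"][i]
                gg[i] = (dh * xhat).sum(axis=0)
                gbeta[i] = dh.sum(axis=0)
                m = dh.shape[0]
                dxhat = dh * self.gamma[i]
                dact = inv * (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0))
            else:
                gg[i] = np.zeros_like(self.gamma[i])
                gbeta[i] = np.zeros_like(self.beta[i])
                dact = dh
            z = cache["z"][i]
            act = _elu(z)
            dz = dact * _elu_grad(z, act)
            gW[i] = cache["a"][i].T @ dz
            gb[i] = dz.sum(axis=0)
            dh = dz @ self.W[i].T
        return gW + gb + gg + gbeta


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps=1.0e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


@dataclass
class TrainedModel:
    """Weights, config, scaling parameters, and the per-epoch history."""

    net: _Mlp
    config: DnnConfig
    classes: tuple
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    history: pd.DataFrame
    epochs_to_target: float = float("inf")  # first epoch reaching 0.90 val acc

    def save(self, path):
        """Single-archive checkpoint (npz weights + embedded JSON config)."""
        path = Path(path)
        arrays = {"scaler_mean": self.scaler_mean, "scaler_sd": self.scaler_sd}
        net = self.net
        for i, (w, b) in enumerate(zip(net.W, net.b)):
            arrays[f"W{i}"], arrays[f"b{i}"] = w, b
        for i in range(net.n_hidden):
            arrays[f"gamma{i}"] = net.gamma[i]
            arrays[f"beta{i}"] = net.beta[i]
            arrays[f"rmean{i}"] = net.run_mean[i]
            arrays[f"rvar{i}"] = net.run_var[i]
        meta = {
            "config": self.config.__dict__,
            "classes": list(self.classes),
            "n_layers": len(net.W),
            "batchnorm": net.batchnorm,
            "epochs_to_target": None if np.isinf(self.epochs_to_target) else self.epochs_to_target,
        }
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        arrays["history_csv"] = np.frombuffer(
            self.history.to_csv(index=False).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        import io

        data = np.load(path)
        meta = json.loads(bytes(data["meta_json"]).decode())
        config = DnnConfig(**meta["config"])
        net = _Mlp.__new__(_Mlp)
        net.batchnorm = meta["batchnorm"]
        n_layers = meta["n_layers"]
        net.W = [data[f"W{i}"] for i in range(n_layers)]
        net.b = [data[f"b{i}"] for i in range(n_layers)]
        net.gamma = [data[f"gamma{i}"] for i in range(n_layers - 1)]
        net.beta = [data[f"beta{i}"] for i in range(n_layers - 1)]
        net.run_mean = [data[f"rmean{i}"] for i in range(n_layers - 1)]
        net.run_var = [data[f"rvar{i}"] for i in range(n_layers - 1)]
        net.momentum = 0.9
        history = pd.read_csv(io.BytesIO(bytes(data["history_csv"])))
        ett = meta["epochs_to_target"]
        return cls(
            net=net, config=config, classes=tuple(meta["classes"]),
            scaler_mean=data["scaler_mean"], scaler_sd=data["scaler_sd"],
            history=history,
            epochs_to_target=float("inf") if ett is None else ett,
        )


VAL_TARGET = 0.90  # validation accuracy landmark recorded per training run


def _encode_labels(labels, classes):
    lookup = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([lookup[l] for l in labels])
    except KeyError as err:
        raise ValidationError(f"unknown class label {err.args[0]!r}") from None


def train(
    config: DnnConfig,
    partitions: Partitions,
    features: np.ndarray,
    labels,
    classes=CLASSES,
) -> TrainedModel:
    """Train one classifier on the training split; returns the model with its
    per-epoch history (train loss, validation accuracy).

    Only training/validation rows of ``features`` are ever read; the test
    partition is untouched until prediction time.
    """
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features[np.concatenate([partitions.train_idx, partitions.val_idx])])):
        raise ValidationError("non-finite feature values in train/validation splits")
    if features.shape[1] != config.input_width:
        raise ValidationError(
            f"feature width {features.shape[1]} does not match variant "
            f"{config.feature_variant} (expects {config.input_width})"
        )
    y = _encode_labels(labels, classes)
    rng = np.random.default_rng(config.seed)

    X_train = features[partitions.train_idx]
    y_train = y[partitions.train_idx]
    X_val = features[partitions.val_idx]
    y_val = y[partitions.val_idx]

    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X_train = ((X_train - mean) / sd).astype(np.float32)
    X_val = ((X_val - mean) / sd).astype(np.float32)

    widths = [config.input_width] + [config.nodes_per_layer] * config.n_hidden_layers + [len(classes)]
    net = _Mlp(widths, config.batchnorm and config.n_hidden_layers > 0, rng)
    opt = _Adam(net.params(), config.learning_rate, config.beta1, config.beta2)
    onehot_train = np.eye(len(classes), dtype=np.float32)[y_train]

    history = []
    epochs_to_target = float("inf")
    best_val, best_epoch = -np.inf, 0
    n = len(X_train)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.minibatch):
            idx = order[start : start + config.minibatch]
            if len(idx) < 2:
                continue  # batch statistics are undefined on a single sample
            logits, cache = net.forward(X_train[idx], training=True)
            probs = _softmax(logits)
            loss = -np.mean(
                np.log(np.clip(probs[np.arange(len(idx)), y_train[idx]], 1e-12, None))
            )
            if not np.isfinite(loss):
                raise NumericalError(
                    "NaN/inf training loss; lower the learning rate "
                    f"(currently {config.learning_rate})"
                )
            losses.append(loss)
            grads = net.backward(cache, probs, onehot_train[idx])
            opt.step(net.params(), grads)
        logits_val, _ = net.forward(X_val, training=False)
        val_acc = float(np.mean(np.argmax(logits_val, axis=1) == y_val)) if len(y_val) else np.nan
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc})
        if np.isinf(epochs_to_target) and val_acc >= VAL_TARGET:
            epochs_to_target = epoch
        if val_acc > best_val:
            best_val, best_epoch = val_acc, epoch
        if config.stop_at_val_accuracy is not None and val_acc >= config.stop_at_val_accuracy:
            break
        if config.early_stopping and epoch - best_epoch >= config.patience:
            break

    return TrainedModel(
        net=net,
        config=config,
        classes=tuple(classes),
        scaler_mean=mean,
        scaler_sd=sd,
        history=pd.DataFrame(history),
        epochs_to_target=epochs_to_target,
    )


def predict_proba(model: TrainedModel, features) -> np.ndarray:
    """Per-class probability rows (softmax outputs, inference mode)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.config.input_width:
        raise ValidationError(
            f"feature width {X.shape[1]} does not match model input "
            f"{model.config.input_width}"
        )
    X = ((X - model.scaler_mean) / model.scaler_sd).astype(np.float32)
    logits, _ = model.net.forward(X, training=False)
    return _softmax(logits.astype(np.float64))


def predict(model: TrainedModel, features) -> np.ndarray:
    """Class labels; argmax with ties broken toward the lowest class index."""
    probs = predict_proba(model, features)
    return np.array(model.classes)[np.argmax(probs, axis=1)]


# ---------------------------------------------------------------------------
# Architecture sweep
# ---------------------------------------------------------------------------

def sweep_architecture(
    layer_range,
    node_range,
    n_random_states: int,
    features: np.ndarray,
    labels,
    lesion_ids,
    base_config: DnnConfig | None = None,
    classes=CLASSES,
) -> pd.DataFrame:
    """Grid protocol over depth and width.

    For each (layers, nodes) pair the data are re-split and the network
    retrained under ``n_random_states`` seeds; the table records mean and sd
    of the final validation accuracy and the median number of epochs needed
    to reach 90% validation accuracy (inf when never reached), sorted by
    (layers, nodes).
    """
    layer_range = list(layer_range)
    node_range = list(node_range)
    if not layer_range or not node_range or n_random_states < 1:
        raise ValidationError("layer/node ranges and n_random_states must be non-empty")
    base_config = base_config or DnnConfig()
    labels = np.asarray(labels)
    rows = []
    for layers in sorted(layer_range):
        for nodes in sorted(node_range):
            accs, epochs = [], []
            for state in range(n_random_states):
                seed = 10_000 * (state + 1) + base_config.seed
                parts = grouped_split(lesion_ids, labels, seed=seed)
                cfg = replace(
                    base_config,
                    n_hidden_layers=layers,
                    nodes_per_layer=nodes,
                    seed=seed,
                )
                model = train(cfg, parts, features, labels, classes=classes)
                accs.append(model.history["val_accuracy"].iloc[-1])
                epochs.append(model.epochs_to_target)
            rows.append({
                "layers": layers,
                "nodes": nodes,
                "mean_val_accuracy": float(np.mean(accs)),
                "sd_val_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "median_epochs_to_90": float(np.median(epochs)),
                "n_reached_90": int(np.sum(np.isfinite(epochs))),
                "n_states": n_random_states,
            })
    return pd.DataFrame(rows).sort_values(["layers", "nodes"]).reset_index(drop=True)
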