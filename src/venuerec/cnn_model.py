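"""The abstract-classification network: three stacked 1-D convolution +
ReLU + max-pool stages over the m-by-k abstract matrix, followed by two
fully connected hidden layers and a softmax head, trained with Adam on the
cross-entropy loss with an L2 weight penalty.

The implementation is plain numpy: convolutions are valid (no padding),
realised as a sliding-window im2col followed by a matrix product, and the
backward pass and the Adam update are written out explicitly so a single
seeded run is exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np

from .embeddings import AbstractMatrix

__all__ = [
    "ModelConfig",
    "CNNModel",
    "ClassScores",
    "TrainingDiverged",
    "layer_length_plan",
    "conv_valid",
    "maxpool2",
    "softmax",
    "cross_entropy_loss",
    "prepare_dataset",
    "predict_proba",
    "vocab_digest",
    "train",
]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Defaults are the reference configuration: sequence length ``m=350``,
    word-vector dimension ``k=200``, convolution stages (kernel count,
    window) = (256,3), (128,4), (96,5), max-pooling window 2 with stride 2,
    ReLU activations, dropout 0.2 on the fully connected layers, and an L2
    weight penalty. Hidden widths, the L2 coefficient, the Adam learning
    rate and the batch size are not pinned by the reference configuration
    and are surfaced here rather than hard-coded.
    """

    m: int = 350
    k: int = 200
    conv_stages: tuple[tuple[int, int], ...] = ((256, 3), (128, 4), (96, 5))
    pool_window: int = 2
    pool_stride: int = 2
    dropout_rate: float = 0.2
    l2_coefficient: float = 1e-4
    hidden_sizes: tuple[int, int] = (512, 256)
    n_classes: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 10
    seed: int = 0
    global_max_pool: bool = False  # reduce stage-3 output to r3 features instead of flattening
    trainable_embeddings: bool = True
    class_weighting: str | None = None  # None or "inverse_frequency"

    def __post_init__(self):
        if self.pool_window != 2 or self.pool_stride != 2:
            raise ValueError("only pool_window=2, pool_stride=2 is supported")
        layer_length_plan(self)  # validates stage geometry

    @property
    def n_features(self) -> int:
        """Size of the flattened stage-3 output feeding the dense head."""
        r3 = self.conv_stages[-1][0]
        if self.global_max_pool:
            return r3
        return r3 * layer_length_plan(self)[-1][1]

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, obj: Mapping) -> "ModelConfig":
        obj = dict(obj)
        obj["conv_stages"] = tuple(tuple(s) for s in obj["conv_stages"])
        obj["hidden_sizes"] = tuple(obj["hidden_sizes"])
        return cls(**obj)


def layer_length_plan(config: ModelConfig | None = None, *, m: int | None = None,
                      windows: Sequence[int] | None = None) -> list[tuple[int, int]]:
    """Per-stage (convolved length, pooled length) for the stage geometry.

    Pure arithmetic: stage t maps an input of length L to a valid-convolution
    output of length ``L - h_t + 1`` and then halves it with floor (a
    trailing unpaired element is dropped). Raises ``ValueError`` naming the
    offending stage if any convolved length is non-positive or too short to
    pool (pooling needs length >= 2).
    """
    if config is not None:
        m = config.m
        windows = [h for _, h in config.conv_stages]
    if m is None or windows is None:
        raise TypeError("either config or (m, windows) must be given")
    plan = []
    length = m
    for t, h in enumerate(windows, start=1):
        conv_len = length - h + 1
        if conv_len <= 0:
            raise ValueError(
                f"stage {t}: convolution window {h} exceeds input length {length} "
                f"(output length {conv_len} <= 0)"
            )
        if conv_len < 2:
            raise ValueError(
                f"stage {t}: convolved length {conv_len} is too short to max-pool (needs >= 2)"
            )
        pooled = conv_len // 2
        plan.append((conv_len, pooled))
        length = pooled
    return plan


# --- elementary operations --------------------------------------------------

def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def conv_valid(
    inputs: np.ndarray,
    kernels: Sequence[np.ndarray],
    biases: Sequence[float] | np.ndarray | None = None,
    activation: Callable[[np.ndarray], np.ndarray] | None = relu,
) -> list[np.ndarray]:
    """Valid 1-D convolution of an L-by-d input with d-by-h kernels.

    Feature map j at position i is
    ``activation(sum(kernel_j * inputs[i:i+h, :].T) + bias_j)`` — the kernel
    slides along the sequence axis and spans all d input channels, producing
    one length ``L - h + 1`` vector per kernel.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    L, d = inputs.shape
    if biases is None:
        biases = np.zeros(len(kernels))
    maps = []
    for kernel, bias in zip(kernels, np.asarray(biases, dtype=float)):
        kernel = np.asarray(kernel, dtype=np.float64)
        dk, h = kernel.shape
        if dk != d:
            raise ValueError(f"kernel spans {dk} channels but input has {d}")
        if L < h:
            raise ValueError(f"input length {L} shorter than kernel window {h}")
        # windows: (L-h+1, d, h) where window i holds input rows i..i+h-1
        windows = np.lib.stride_tricks.sliding_window_view(inputs, h, axis=0)
        fmap = np.tensordot(windows, kernel, axes=([1, 2], [0, 1])) + bias
        maps.append(activation(fmap) if activation is not None else fmap)
    return maps


def maxpool2(feature_map: np.ndarray) -> np.ndarray:
    """Max-pool a 1-D feature map with window 2, stride 2.

    A trailing unpaired element of an odd-length map is dropped, so the
    output length is ``floor(L / 2)``.
    """
    v = np.asarray(feature_map)
    L = v.shape[0]
    if L < 2:
        raise ValueError(f"cannot max-pool a length-{L} map (needs >= 2)")
    half = L // 2
    return v[: 2 * half].reshape(half, 2).max(axis=1)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction)."""
    z = np.asarray(z, dtype=np.float64)
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_loss(
    S: np.ndarray,
    Y: np.ndarray,
    l2_coefficient: float = 0.0,
    weights: Sequence[np.ndarray] = (),
) -> float:
    """Cross-entropy of a probability vector against a one-hot target.

    ``-log`` of the probability assigned to the true class, plus
    ``l2_coefficient * sum(w**2)`` over the given weight arrays.
    """
    S = np.asarray(S, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape != S.shape:
        raise ValueError(f"shape mismatch: S {S.shape} vs Y {Y.shape}")
    one = np.isclose(Y.sum(), 1.0)
    if not (one and np.all((Y == 0) | (Y == 1)) and int((Y == 1).sum()) == 1):
        raise ValueError("Y must be a one-hot vector")
    p = float(S[Y == 1][0])
    loss = -np.log(max(p, 1e-300))
    loss += l2_coefficient * sum(float(np.sum(np.square(w))) for w in weights)
    return float(loss)


@dataclass(frozen=True)
class ClassScores:
    """Pre-softmax scores z and class probabilities S for one abstract."""

    z: np.ndarray
    S: np.ndarray


# --- the model ---------------------------------------------------------------

CHECKPOINT_FORMAT = "venuerec-checkpoint-1"


class CNNModel:
    """Parameters and forward/backward passes of the three-stage network.

    Parameters live in ``self.params`` (numpy float32/float64 arrays):
    ``E`` the (|vocab|+1, k) embedding matrix with row 0 pinned to zero,
    ``convW{t}``/``convb{t}`` the stage kernels (shape (h_t * C_in, r_t))
    and biases, ``W1/b1``, ``W2/b2`` the hidden layers and ``Wout/bout``
    the softmax head. The head weights start at zero so an untrained model
    predicts the uniform distribution.
    """

    def __init__(
        self,
        config: ModelConfig,
        embedding: np.ndarray,
        class_labels: Sequence[str],
        vocab_hash: str = "",
    ):
        if embedding.shape[1] != config.k:
            raise ValueError(f"embedding dim {embedding.shape[1]} != config.k {config.k}")
        if len(class_labels) != config.n_classes:
            raise ValueError(
                f"{len(class_labels)} class labels but config.n_classes={config.n_classes}"
            )
        self.config = config
        self.class_labels = tuple(class_labels)
        self.vocab_hash = vocab_hash
        self.history: list[dict] = []
        rng = np.random.default_rng(config.seed)

        p: dict[str, np.ndarray] = {"E": embedding.astype(np.float64).copy()}
        p["E"][0] = 0.0
        c_in = config.k
        for t, (r, h) in enumerate(config.conv_stages, start=1):
            fan_in = h * c_in
            p[f"convW{t}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, r))
            p[f"convb{t}"] = np.zeros(r)
            c_in = r
        sizes = [config.n_features, *config.hidden_sizes]
        for i in range(2):
            p[f"W{i+1}"] = rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            p[f"b{i+1}"] = np.zeros(sizes[i + 1])
        p["Wout"] = np.zeros((sizes[-1], config.n_classes))
        p["bout"] = np.zeros(config.n_classes)
        self.params = p
        self._adam_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward ----------------------------------------------------------

    @property
    def l2_weight_names(self) -> list[str]:
        """Weight arrays included in the L2 penalty (kernels and dense weights)."""
        names = [f"convW{t}" for t in range(1, len(self.config.conv_stages) + 1)]
        return names + ["W1", "W2", "Wout"]

    def l2_penalty(self) -> float:
        lam = self.config.l2_coefficient
        return lam * sum(float(np.sum(np.square(self.params[n]))) for n in self.l2_weight_names)

    def _forward_batch(self, X: np.ndarray, training: bool, rng: np.random.Generator | None):
        """X: (B, m, k) abstract matrices. Returns (S, cache)."""
        cfg = self.config
        cache: dict = {"stage": []}
        for t, (r, h) in enumerate(cfg.conv_stages, start=1):
            B, L, C = X.shape
            L_out = L - h + 1
            win = np.lib.stride_tricks.sliding_window_view(X, h, axis=1)  # (B, L_out, C, h)
            A = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L_out, h * C)
            Z = A @ self.params[f"convW{t}"] + self.params[f"convb{t}"]
            H = relu(Z)
            half = L_out // 2
            Hp = H[:, : 2 * half].reshape(B, half, 2, r)
            arg = Hp.argmax(axis=2)
            P = np.take_along_axis(Hp, arg[:, :, None, :], axis=2)[:, :, 0, :]
            cache["stage"].append({"A": A, "Z": Z, "arg": arg, "shape": (B, L, C, L_out, half, h, r)})
            X = P
        B = X.shape[0]
        if cfg.global_max_pool:
            cache["gmp_arg"] = X.argmax(axis=1)
            F = X.max(axis=1)
            cache["pre_flatten_shape"] = X.shape
        else:
            cache["pre_flatten_shape"] = X.shape
            F = X.reshape(B, -1)
        cache["F"] = F

        H1 = relu(F @ self.params["W1"] + self.params["b1"])
        if training and cfg.dropout_rate > 0:
            mask1 = (rng.random(H1.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
            H1 = H1 * mask1
            cache["mask1"] = mask1
        H2 = relu(H1 @ self.params["W2"] + self.params["b2"])
        if training and cfg.dropout_rate > 0:
            mask2 = (rng.random(H2.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
            H2 = H2 * mask2
            cache["mask2"] = mask2
        z = H2 @ self.params["Wout"] + self.params["bout"]
        S = softmax(z, axis=1)
        cache.update(H1=H1, H2=H2, z=z, S=S)
        return S, cache

    def embed_ids(self, ids: np.ndarray) -> np.ndarray:
        """Token-id batch (B, m) -> abstract matrices (B, m, k)."""
        return self.params["E"][np.asarray(ids, dtype=np.intp)]

    def forward(self, inputs, training_mode: bool = False,
                rng: np.random.Generator | None = None):
        """Class scores for one abstract or a batch.

        ``inputs`` may be an :class:`~venuerec.embeddings.AbstractMatrix`, a
        single (m, k) matrix, a single length-m id sequence, or a batch of
        either. A single abstract returns :class:`ClassScores`; a batch
        returns the (B, T) probability array. Dropout is active only in
        training mode (which then requires an rng).
        """
        single = False
        if isinstance(inputs, AbstractMatrix):
            X, single = inputs.V[None], True
        else:
            arr = np.asarray(inputs)
            if arr.ndim == 1:  # one id sequence
                X, single = self.embed_ids(arr[None]), True
            elif arr.ndim == 2 and np.issubdtype(arr.dtype, np.integer):
                X = self.embed_ids(arr)
            elif arr.ndim == 2:  # one (m, k) matrix
                X, single = arr[None].astype(np.float64), True
            else:
                X = arr.astype(np.float64)
        m, k = self.config.m, self.config.k
        if X.shape[1:] != (m, k):
            raise ValueError(f"input shape {X.shape[1:]} does not match (m, k)=({m}, {k})")
        if training_mode and rng is None:
            raise ValueError("training_mode=True requires an rng for dropout")
        S, cache = self._forward_batch(X, training_mode, rng)
        if single:
            return ClassScores(z=cache["z"][0].copy(), S=S[0].copy())
        return S

    # -- backward ----------------------------------------------------------

    def _backward_batch(self, X, Y_onehot, cache, sample_weights=None):
        """Gradients of mean weighted cross-entropy + L2 w.r.t. all params."""
        cfg = self.config
        p = self.params
        B = X.shape[0]
        S = cache["S"]
        if sample_weights is None:
            sw = np.full(B, 1.0 / B)
        else:
            sw = np.asarray(sample_weights, dtype=np.float64)
            sw = sw / sw.sum()
        grads: dict[str, np.ndarray] = {}

        dz = (S - Y_onehot) * sw[:, None]
        grads["Wout"] = cache["H2"].T @ dz
        grads["bout"] = dz.sum(axis=0)
        dH2 = dz @ p["Wout"].T
        if "mask2" in cache:
            dH2 = dH2 * cache["mask2"]
        dH2 = dH2 * (cache["H2"] > 0)
        grads["W2"] = cache["H1"].T @ dH2
        grads["b2"] = dH2.sum(axis=0)
        dH1 = dH2 @ p["W2"].T
        if "mask1" in cache:
            dH1 = dH1 * cache["mask1"]
        dH1 = dH1 * (cache["H1"] > 0)
        grads["W1"] = cache["F"].T @ dH1
        grads["b1"] = dH1.sum(axis=0)
        dF = dH1 @ p["W1"].T

        Bp, half3, r3 = cache["pre_flatten_shape"]
        if cfg.global_max_pool:
            dP = np.zeros((Bp, half3, r3))
            np.put_along_axis(dP, cache["gmp_arg"][:, None, :], dF[:, None, :], axis=1)
        else:
            dP = dF.reshape(Bp, half3, r3)

        for t in range(len(cfg.conv_stages), 0, -1):
            st = cache["stage"][t - 1]
            B_, L, C, L_out, half, h, r = st["shape"]
            dHp = np.zeros((B_, half, 2, r))
            np.put_along_axis(dHp, st["arg"][:, :, None, :], dP[:, :, None, :], axis=2)
            dH = np.zeros((B_, L_out, r))
            dH[:, : 2 * half] = dHp.reshape(B_, 2 * half, r)
            dZ = dH * (st["Z"] > 0)
            grads[f"convW{t}"] = st["A"].reshape(-1, h * C).T @ dZ.reshape(-1, r)
            grads[f"convb{t}"] = dZ.sum(axis=(0, 1))
            dA = (dZ @ p[f"convW{t}"].T).reshape(B_, L_out, h, C)
            dX = np.zeros((B_, L, C))
            for j in range(h):
                dX[:, j : j + L_out] += dA[:, :, j]
            dP = dX

        if cfg.trainable_embeddings:
            ids = cache["ids"]
            dE = np.zeros_like(p["E"])
            np.add.at(dE, ids.reshape(-1), dP.reshape(-1, cfg.k))
            dE[0] = 0.0  # padding/OOV row stays zero
            grads["E"] = dE

        lam = cfg.l2_coefficient
        if lam:
            for name in self.l2_weight_names:
                grads[name] = grads[name] + 2.0 * lam * p[name]
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]):
        cfg = self.config
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for name, g in grads.items():
            m, v = self._adam_state.get(name, (np.zeros_like(g), np.zeros_like(g)))
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * np.square(g)
            self._adam_state[name] = (m, v)
            m_hat = m / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            self.params[name] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        self.params["E"][0] = 0.0

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: weights + full config + class labels + vocabulary hash."""
        meta = {
            "format": CHECKPOINT_FORMAT,
            "config": self.config.to_json(),
            "class_labels": list(self.class_labels),
            "vocab_hash": self.vocab_hash,
            "history": self.history,
        }
        arrays = {k: v for k, v in self.params.items()}
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "CNNModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognised checkpoint format: {meta.get('format')!r}")
            config = ModelConfig.from_json(meta["config"])
            model = cls(
                config,
                embedding=data["E"],
                class_labels=meta["class_labels"],
                vocab_hash=meta["vocab_hash"],
            )
            for name in data.files:
                if name != "__meta__":
                    model.params[name] = data[name].copy()
            model.history = meta["history"]
        return model


def vocab_digest(vocabulary: Mapping[str, int]) -> str:
    payload = json.dumps(sorted(vocabulary.items())).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def predict_proba(model: CNNModel, ids: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Class probabilities for a set of encoded abstracts, in memory-bounded chunks."""
    ids = np.asarray(ids)
    if ids.ndim != 2:
        raise ValueError("ids must be a (N, m) integer array")
    chunks = [
        model.forward(ids[i : i + batch_size]) for i in range(0, len(ids), batch_size)
    ]
    return np.vstack(chunks)


def prepare_dataset(
    records,
    vocabulary: Mapping[str, int],
    class_labels: Sequence[str],
    m: int = 350,
) -> tuple[np.ndarray, np.ndarray]:
    """Tokenize + encode records into (ids (N, m) int32, labels (N,) int64)."""
    from .text_prep import encode_sequence, tokenize

    label_index = {lbl: i for i, lbl in enumerate(class_labels)}
    ids = np.zeros((len(records), m), dtype=np.int32)
    y = np.zeros(len(records), dtype=np.int64)
    for i, rec in enumerate(records):
        seq = encode_sequence(tokenize(rec.abstract_text), vocabulary, m=m)
        ids[i] = seq.token_ids
        y[i] = label_index[rec.journal_label]
    return ids, y


def train(
    model: CNNModel,
    train_ids: np.ndarray,
    train_y: np.ndarray,
    val_ids: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
    epochs: int | None = None,
    stop_at_train_acc: float | None = None,
) -> CNNModel:
    """Mini-batch Adam training on the cross-entropy objective.

    Seeded and single-worker: the per-epoch shuffle and the dropout masks
    come from one generator derived from ``config.seed``, so two runs with
    the same seed produce the same parameters. Records per-epoch mean loss
    (including the L2 penalty) and training accuracy in ``model.history``;
    aborts with :class:`TrainingDiverged` if the loss becomes non-finite.
    """
    cfg = model.config
    if len(train_ids) == 0:
        raise ValueError("empty training set")
    if train_y.min() < 0 or train_y.max() >= cfg.n_classes:
        raise ValueError("labels out of range for config.n_classes")
    epochs = cfg.max_epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(train_ids)
    T = cfg.n_classes

    sample_w = None
    if cfg.class_weighting == "inverse_frequency":
        counts = np.bincount(train_y, minlength=T).astype(np.float64)
        w_class = np.where(counts > 0, counts.sum() / np.maximum(counts, 1) / T, 0.0)
        sample_w = w_class[train_y]

    for epoch in range(epochs):
        order = rng.permutation(n)
        total_loss, total_correct, n_batches = 0.0, 0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            ids = train_ids[idx]
            X = model.embed_ids(ids)
            Y = np.eye(T)[train_y[idx]]
            S, cache = model._forward_batch(X, training=True, rng=rng)
            cache["ids"] = ids
            sw = None if sample_w is None else sample_w[idx]
            eps_p = np.maximum(S[np.arange(len(idx)), train_y[idx]], 1e-300)
            if sw is None:
                batch_loss = float(-np.log(eps_p).mean())
            else:
                batch_loss = float(-(np.log(eps_p) * (sw / sw.sum())).sum())
            batch_loss += model.l2_penalty()
            if not np.isfinite(batch_loss):
                raise TrainingDiverged(f"loss became {batch_loss} at epoch {epoch}")
            grads = model._backward_batch(X, Y, cache, sample_weights=sw)
            model._adam_step(grads)
            total_loss += batch_loss
            total_correct += int((S.argmax(axis=1) == train_y[idx]).sum())
            n_batches += 1

        entry = {
            "epoch": epoch,
            "loss": total_loss / n_batches,
            "train_acc": total_correct / n,
        }
        if val_ids is not None and len(val_ids):
            S_val = predict_proba(model, val_ids)
            entry["val_acc"] = float((S_val.argmax(axis=1) == val_y).mean())
        model.history.append(entry)
        if stop_at_train_acc is not None and entry["train_acc"] >= stop_at_train_acc:
            break
    return model
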