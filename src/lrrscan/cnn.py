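"""Convolutional classifier scoring 20-30 aa peptides as LRR units.

The network consumes the 30 x 5 binary peptide matrix and emits an LRR unit
probability score (LPS) in [0, 1].  Architecture: one convolutional layer
with three filter heights (default 4, 5 and 6 rows, 128 filters each, stride
1, spanning all 5 encoding columns, ReLU), one max-pooling layer (width 2,
stride 2, floor), concatenation into a 128 x 38 = 4864-dimensional feature
vector, one fully connected hidden layer (128 units, ReLU, dropout rate 0.5
during training) and a sigmoid output unit trained with binary cross-entropy
(a single sigmoid is mathematically equivalent to a two-unit softmax with
cross-entropy).  Optimisation uses Adam
(lr 1e-4, beta1 0.9, beta2 0.999, eps 1e-8), mini-batches of 128, at most 50
epochs with early stopping on validation loss.

The 5-bit residue codes are a compressed alphabet: detecting a specific
residue (or residue set) is not a linear function of the bits, which makes a
randomly initialised convolutional layer a poor starting basis — gradient
descent then settles on weak aggregate statistics instead of positional
features.  The default initialisation therefore seeds each filter as an
exact-match residue decoder: filter j starts as a template for one residue
code at one row offset (weights ``2*code - 1`` at that row, bias
``-(sum(code) - 0.5)``), so its ReLU output is a clean one-hot indicator of
that residue at that position, plus small Gaussian noise for symmetry
breaking.  The layer thus begins as a redundant one-hot re-encoder that
training reshapes freely; purely random (He) initialisation remains
available via ``ModelConfig.init_scheme``.

The model is implemented directly on numpy: convolutions over full-width
windows reduce to matrix products via an im2col view, so training and
inference are fast on a single CPU.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .encoding import EncodedPeptide, encode_batch


@dataclass(frozen=True)
class ModelConfig:
    n_filters_per_size: int = 128
    filter_heights: tuple[int, ...] = (4, 5, 6)
    stride: int = 1
    pool_width: int = 2
    hidden_units: int = 128
    dropout_rate: float = 0.5
    input_rows: int = 30
    input_cols: int = 5
    init_scheme: str = "decoder"  # "decoder" | "random"

    def __post_init__(self) -> None:
        for h in self.filter_heights:
            if h > self.input_rows:
                raise ValueError(
                    f"filter height {h} exceeds input rows {self.input_rows}"
                )
            if h < 1:
                raise ValueError(f"filter height {h} must be positive")
        if self.init_scheme not in ("decoder", "random"):
            raise ValueError(f"unknown init_scheme {self.init_scheme!r}")

    def pooled_lengths(self) -> tuple[int, ...]:
        return tuple(
            (self.input_rows - h + 1) // self.pool_width for h in self.filter_heights
        )

    @property
    def feature_length(self) -> int:
        """Flattened pooled feature count (128 x 38 = 4864 with defaults)."""
        return self.n_filters_per_size * sum(self.pooled_lengths())


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 50
    batch_size: int = 128
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.beta1, self.beta2, self.epsilon) <= 0:
            raise ValueError("all optimizer rates must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class ConvUnitClassifier:
    """The trainable peptide classifier; scoring is deterministic in eval mode."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.training_history: list[dict[str, float]] = []
        rng = np.random.default_rng(seed)
        c = self.config
        self.params: dict[str, np.ndarray] = {}
        for h in c.filter_heights:
            fan_in = h * c.input_cols
            if c.init_scheme == "decoder":
                W, b = self._decoder_filters(h, rng)
            else:
                W = rng.normal(
                    0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c.n_filters_per_size)
                ).astype(np.float32)
                b = np.zeros(c.n_filters_per_size, dtype=np.float32)
            self.params[f"W{h}"] = W
            self.params[f"b{h}"] = b
        self.params["Wfc"] = rng.normal(
            0.0, np.sqrt(2.0 / c.feature_length),
            size=(c.feature_length, c.hidden_units),
        ).astype(np.float32)
        self.params["bfc"] = np.zeros(c.hidden_units, dtype=np.float32)
        self.params["Wout"] = rng.normal(
            0.0, np.sqrt(2.0 / c.hidden_units), size=(c.hidden_units, 1)
        ).astype(np.float32)
        self.params["bout"] = np.zeros(1, dtype=np.float32)

    def _decoder_filters(
        self, h: int, rng: np.random.Generator, scale: float = 2.0,
        noise: float = 0.05,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Residue-decoder initialisation for one filter height.

        Filter j is an exact-match template for standard residue ``j % 20``
        at row offset ``(j // 20) % h``: ReLU(w.x + b) > 0 iff that row holds
        that residue's code, so the layer starts as a one-hot re-encoder of
        the compressed alphabet.
        """
        from .encoding import ENCODING_TABLE, STANDARD_AA

        c = self.config
        W = rng.normal(0.0, noise, size=(h * c.input_cols, c.n_filters_per_size))
        b = np.zeros(c.n_filters_per_size)
        for j in range(c.n_filters_per_size):
            code = np.array(ENCODING_TABLE[STANDARD_AA[j % 20]], dtype=float)
            o = (j // 20) % h
            W[o * c.input_cols : (o + 1) * c.input_cols, j] += scale * (2 * code - 1)
            b[j] = -scale * (code.sum() - 0.5)
        return W.astype(np.float32), b.astype(np.float32)

    # ---------------------------------------------------------------- forward

    def _im2col(self, X: np.ndarray, h: int) -> np.ndarray:
        # X: (n, rows, cols) -> (n, positions, h*cols) windows, stride 1
        n, rows, cols = X.shape
        view = np.lib.stride_tricks.sliding_window_view(X, (h, cols), axis=(1, 2))
        return view.reshape(n, rows - h + 1, h * cols)

    def features(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Conv + ReLU + max-pool + concat: (n, 30, 5) -> (n, feature_length)."""
        c = self.config
        feats = []
        for h in c.filter_heights:
            win = self._im2col(X, h)
            Z = win @ self.params[f"W{h}"] + self.params[f"b{h}"]
            A = np.maximum(Z, 0.0)
            p_len = (c.input_rows - h + 1) // c.pool_width
            Ar = A[:, : p_len * c.pool_width].reshape(
                X.shape[0], p_len, c.pool_width, c.n_filters_per_size
            )
            arg = Ar.argmax(axis=2)
            pooled = np.take_along_axis(Ar, arg[:, :, None, :], axis=2)[:, :, 0, :]
            feats.append(pooled.reshape(X.shape[0], -1))
            if cache is not None:
                cache[h] = (win, Z, arg)
        return np.concatenate(feats, axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """LPS for a batch of encoded peptides (dropout disabled)."""
        F = self.features(np.asarray(X, dtype=np.float32))
        H = np.maximum(F @ self.params["Wfc"] + self.params["bfc"], 0.0)
        return _sigmoid(
            (H @ self.params["Wout"] + self.params["bout"]).astype(np.float64)
        )[:, 0]

    def score(self, peptide: EncodedPeptide) -> float:
        """LPS of a single encoded peptide."""
        return float(self.predict_proba(peptide.matrix[None].astype(np.float32))[0])

    def score_sequences(self, seqs: list[str], batch_size: int = 4096) -> np.ndarray:
        """Encode and score raw peptide strings in batches."""
        out = np.empty(len(seqs))
        for i in range(0, len(seqs), batch_size):
            out[i : i + batch_size] = self.predict_proba(
                encode_batch(seqs[i : i + batch_size], self.config.input_rows)
            )
        return out

    # --------------------------------------------------------------- backward

    def _backward(
        self,
        X: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator,
    ) -> tuple[float, dict[str, np.ndarray]]:
        c = self.config
        n = X.shape[0]
        cache: dict = {}
        F = self.features(X, cache)
        Zfc = F @ self.params["Wfc"] + self.params["bfc"]
        H = np.maximum(Zfc, 0.0)
        keep = 1.0 - c.dropout_rate
        mask = (rng.random(H.shape) < keep).astype(np.float32) / np.float32(keep)
        Hd = H * mask
        p = _sigmoid((Hd @ self.params["Wout"] + self.params["bout"]).astype(np.float64))[
            :, 0
        ]
        loss = bce_loss(p, y)

        grads: dict[str, np.ndarray] = {}
        dlogit = (((p - y) / n)[:, None]).astype(np.float32)
        grads["Wout"] = Hd.T @ dlogit
        grads["bout"] = dlogit.sum(axis=0)
        dH = (dlogit @ self.params["Wout"].T) * mask
        dZfc = dH * (Zfc > 0)
        grads["Wfc"] = F.T @ dZfc
        grads["bfc"] = dZfc.sum(axis=0)
        dF = dZfc @ self.params["Wfc"].T
        col = 0
        for h in c.filter_heights:
            win, Z, arg = cache[h]
            p_len = (c.input_rows - h + 1) // c.pool_width
            width = p_len * c.n_filters_per_size
            dpool = dF[:, col : col + width].reshape(n, p_len, c.n_filters_per_size)
            col += width
            dA = np.zeros(
                (n, p_len, c.pool_width, c.n_filters_per_size), dtype=np.float32
            )
            np.put_along_axis(dA, arg[:, :, None, :], dpool[:, :, None, :], axis=2)
            dZ = np.zeros_like(Z)
            dZ[:, : p_len * c.pool_width] = dA.reshape(n, p_len * c.pool_width, -1)
            dZ *= Z > 0
            k = win.shape[2]
            grads[f"W{h}"] = (
                win.reshape(-1, k).T @ dZ.reshape(-1, c.n_filters_per_size)
            )
            grads[f"b{h}"] = dZ.sum(axis=(0, 1))
        return loss, grads

    # --------------------------------------------------------------- training

    def train(
        self,
        train_X: np.ndarray,
        train_y: np.ndarray,
        val_X: np.ndarray,
        val_y: np.ndarray,
        tc: TrainingConfig | None = None,
    ) -> "ConvUnitClassifier":
        """Adam/BCE training with early stopping; returns self with best weights.

        The model state after training is the checkpoint with the lowest
        validation loss.  ``training_history`` records per-epoch train and
        validation losses.
        """
        tc = tc or TrainingConfig()
        if len(train_X) == 0 or len(val_X) == 0:
            raise ValueError("training and validation sets must be non-empty")
        if set(np.unique(train_y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary")
        train_X = np.asarray(train_X, dtype=np.float32)
        val_X = np.asarray(val_X, dtype=np.float32)
        train_y = np.asarray(train_y, dtype=np.float64)
        val_y = np.asarray(val_y, dtype=np.float64)

        rng = np.random.default_rng(tc.seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        t = 0
        best_val = np.inf
        best_params = copy.deepcopy(self.params)
        stale = 0
        self.training_history = []
        for epoch in range(tc.epochs):
            order = rng.permutation(len(train_X))
            epoch_loss = 0.0
            for i in range(0, len(order), tc.batch_size):
                idx = order[i : i + tc.batch_size]
                loss, grads = self._backward(train_X[idx], train_y[idx], rng)
                epoch_loss += loss * len(idx)
                t += 1
                for k, g in grads.items():
                    m[k] = tc.beta1 * m[k] + (1 - tc.beta1) * g
                    v[k] = tc.beta2 * v[k] + (1 - tc.beta2) * g * g
                    mhat = m[k] / (1 - tc.beta1**t)
                    vhat = v[k] / (1 - tc.beta2**t)
                    self.params[k] -= tc.learning_rate * mhat / (
                        np.sqrt(vhat) + tc.epsilon
                    )
            val_loss = bce_loss(self.predict_proba(val_X), val_y)
            self.training_history.append(
                {
                    "epoch": epoch + 1,
                    "train_loss": epoch_loss / len(train_X),
                    "val_loss": val_loss,
                }
            )
            if val_loss < best_val:
                best_val = val_loss
                best_params = copy.deepcopy(self.params)
                stale = 0
            else:
                stale += 1
                if stale >= tc.early_stop_patience:
                    break
        self.params = best_params
        return self

    # ------------------------------------------------------------ persistence

    def save(self, path: str | Path) -> None:
        """One-file checkpoint: config JSON + weights (npz)."""
        cfg = asdict(self.config)
        cfg["filter_heights"] = list(cfg["filter_heights"])
        np.savez(
            path,
            __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConvUnitClassifier":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["filter_heights"] = tuple(cfg["filter_heights"])
        model = cls(ModelConfig(**cfg))
        model.params = {k: data[k] for k in data.files if k != "__config__"}
        return model


def train_on_records(
    train_records,
    val_records,
    config: ModelConfig | None = None,
    tc: TrainingConfig | None = None,
) -> ConvUnitClassifier:
    """Convenience wrapper: encode UnitRecords and train a fresh model."""
    tc = tc or TrainingConfig()
    config = config or ModelConfig()

    def encode(records):
        X = encode_batch([r.sequence for r in records], config.input_rows)
        y = np.array([1.0 if r.label == "positive" else 0.0 for r in records])
        return X, y

    model = ConvUnitClassifier(config, seed=tc.seed)
    model.train(*encode(train_records), *encode(val_records), tc)
    return model


class CVEnsembleClassifier:
    """Score-averaging ensemble of the five cross-validation fold models.

    The training protocol runs five-fold cross-validation over the training
    set; each arrangement (fold i held out for early stopping) yields one
    trained model, and the final LPS is the mean of the member scores.
    Averaging damps run-to-run training variance and never scores worse than
    a typical single member.
    """

    def __init__(self, members: list[ConvUnitClassifier]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members
        self.config = members[0].config

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)

    def score(self, peptide: EncodedPeptide) -> float:
        return float(np.mean([m.score(peptide) for m in self.members]))

    def score_sequences(self, seqs: list[str], batch_size: int = 4096) -> np.ndarray:
        return np.mean(
            [m.score_sequences(seqs, batch_size) for m in self.members], axis=0
        )


def train_cv_ensemble(
    split,
    config: ModelConfig | None = None,
    tc: TrainingConfig | None = None,
) -> CVEnsembleClassifier:
    """Train one model per fold arrangement of a SplitDataset.

    Member i trains on all folds but i, early-stops on fold i, and seeds its
    weights/shuffling/dropout from ``tc.seed + i``.
    """
    import dataclasses

    tc = tc or TrainingConfig()
    members = []
    for i, fold in enumerate(split.folds):
        train = [r for j, f in enumerate(split.folds) if j != i for r in f]
        tci = dataclasses.replace(tc, seed=tc.seed + i)
        members.append(train_on_records(train, fold, config, tci))
    return CVEnsembleClassifier(members)
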