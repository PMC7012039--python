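"""The template-prioritization ("rollout") policy network.

Compounds are featurized as ECFP4 fingerprints (Morgan radius 2, folded to
a fixed-length binary vector) and templates as integer class labels over a
:class:`~retrotree.templates.TemplateLibrary`.  The classifier is a single
fully connected layer of 512 ELU units with L2 regularization (0.001),
dropout (0.04) and a softmax output, trained with Adam (initial learning
rate 0.001) on categorical cross-entropy.  The learning rate halves when
the validation loss plateaus for 5 epochs and training stops early after a
10-epoch plateau; top-1/5/10/50 accuracies are monitored per epoch.

The network is implemented directly on NumPy: the matrices involved are
small enough that a hand-rolled forward/backward pass with seeded
initialization and dropout keeps training bitwise reproducible on one
device.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator

from .chem import mol_from_smiles
from .templates import GroupLibrary, TemplateLibrary, TemplateExtractionError

DEFAULT_N_BITS = 2048
DEFAULT_FP_RADIUS = 2

_GENERATORS: dict[tuple[int, int], object] = {}


def _fp_generator(n_bits: int, fp_radius: int):
    key = (n_bits, fp_radius)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=fp_radius, fpSize=n_bits
        )
    return _GENERATORS[key]


def featurize(
    smiles: str, n_bits: int = DEFAULT_N_BITS, fp_radius: int = DEFAULT_FP_RADIUS
) -> np.ndarray:
    """Binary ECFP fingerprint; identical for any SMILES of one molecule."""
    mol = mol_from_smiles(smiles)
    return _fp_generator(n_bits, fp_radius).GetFingerprintAsNumPy(mol).astype(np.float64)


def featurize_many(
    smiles: Iterable[str], n_bits: int = DEFAULT_N_BITS, fp_radius: int = DEFAULT_FP_RADIUS
) -> np.ndarray:
    return np.stack([featurize(s, n_bits, fp_radius) for s in smiles])


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------

def split_indices(
    n: int, fractions: Sequence[float] = (0.90, 0.05, 0.05), seed: int = 42
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded shuffle followed by a floor-rounded 90/5/5-style partition."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    order = np.random.RandomState(seed).permutation(n)
    n_train = int(np.floor(fractions[0] * n))
    n_valid = int(np.floor(fractions[1] * n))
    return order[:n_train], order[n_train : n_train + n_valid], order[n_train + n_valid :]


def split_dataset(
    X: np.ndarray,
    y: np.ndarray,
    fractions: Sequence[float] = (0.90, 0.05, 0.05),
    seed: int = 42,
):
    """Shuffle-and-split into (train, valid, test) (X, y) pairs."""
    train_idx, valid_idx, test_idx = split_indices(len(y), fractions, seed)
    return (
        (X[train_idx], y[train_idx]),
        (X[valid_idx], y[valid_idx]),
        (X[test_idx], y[test_idx]),
    )


def dataset_from_reactions(
    extracted: Sequence[tuple[str, object, object]],
    library: TemplateLibrary,
    n_bits: int = DEFAULT_N_BITS,
    fp_radius: int = DEFAULT_FP_RADIUS,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build (X, y) from extract_templates output against a library.

    Records whose template was dropped by occurrence filtering are excluded,
    so the label space equals the library exactly.  Returns fingerprints,
    labels, and the product SMILES kept.
    """
    from rdkit import Chem

    from .chem import demap

    X_rows, labels, products = [], [], []
    for _, tpl, rxn in extracted:
        digest = tpl.template_hash
        if digest not in library.label_index:
            continue
        smi = Chem.MolToSmiles(demap(rxn.products[0]))
        X_rows.append(featurize(smi, n_bits, fp_radius))
        labels.append(library.label_of(digest))
        products.append(smi)
    if not X_rows:
        raise ValueError("no reaction matches the template library")
    return np.stack(X_rows), np.asarray(labels, dtype=np.int64), products


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training hyper-parameters; defaults follow the standard recipe."""

    learning_rate: float = 0.001
    decay_factor: float = 0.5
    plateau_patience: int = 5
    early_stop_patience: int = 10
    epochs: int = 500
    batch_size: int = 128
    min_learning_rate: float = 1e-6
    l2: float = 0.001
    dropout: float = 0.04
    hidden: int = 512
    seed: int = 0
    topk: tuple[int, ...] = (1, 5, 10, 50)

    def __post_init__(self) -> None:
        if self.plateau_patience <= 0 or self.early_stop_patience <= 0:
            raise ValueError("patience values must be positive")


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class PolicyModel:
    """Fingerprint -> 512 ELU -> softmax over template labels."""

    def __init__(
        self,
        n_bits: int,
        n_labels: int,
        hidden: int = 512,
        l2: float = 0.001,
        dropout: float = 0.04,
        seed: int = 0,
        label_hashes: Sequence[str] | None = None,
    ) -> None:
        self.n_bits = n_bits
        self.n_labels = n_labels
        self.hidden = hidden
        self.l2 = l2
        self.dropout = dropout
        self.seed = seed
        self.label_hashes = list(label_hashes) if label_hashes is not None else None
        rng = np.random.RandomState(seed)
        limit1 = np.sqrt(6.0 / (n_bits + hidden))
        limit2 = np.sqrt(6.0 / (hidden + n_labels))
        self.W1 = rng.uniform(-limit1, limit1, size=(n_bits, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.uniform(-limit2, limit2, size=(hidden, n_labels))
        self.b2 = np.zeros(n_labels)
        self.history_: pd.DataFrame | None = None

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        hidden = _elu(X @ self.W1 + self.b1)
        return _softmax(hidden @ self.W2 + self.b2)

    def predict_smiles(self, smiles: str) -> np.ndarray:
        return self.predict_proba(featurize(smiles, self.n_bits))[0]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "n_bits": self.n_bits,
            "n_labels": self.n_labels,
            "hidden": self.hidden,
            "l2": self.l2,
            "dropout": self.dropout,
            "seed": self.seed,
            "label_hashes": self.label_hashes,
        }
        np.savez(
            path,
            W1=self.W1,
            b1=self.b1,
            W2=self.W2,
            b2=self.b2,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PolicyModel":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        model = cls(
            n_bits=meta["n_bits"],
            n_labels=meta["n_labels"],
            hidden=meta["hidden"],
            l2=meta["l2"],
            dropout=meta["dropout"],
            seed=meta["seed"],
            label_hashes=meta["label_hashes"],
        )
        model.W1, model.b1 = data["W1"], data["b1"]
        model.W2, model.b2 = data["W2"], data["b2"]
        return model


def _topk_hits(probs: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    k = min(k, probs.shape[1])
    top = np.argpartition(-probs, k - 1, axis=1)[:, :k]
    return (top == y[:, None]).any(axis=1)


def topk_accuracy_from_probs(probs: np.ndarray, y: np.ndarray, k: int) -> float:
    return float(_topk_hits(probs, y, k).mean())


def topk_accuracy(model: PolicyModel, dataset: tuple[np.ndarray, np.ndarray], k: int) -> float:
    """Fraction of records whose true label is in the k most probable."""
    if k < 1:
        raise ValueError("k must be >= 1")
    X, y = dataset
    return topk_accuracy_from_probs(model.predict_proba(X), np.asarray(y), k)


def train_policy(
    train: tuple[np.ndarray, np.ndarray],
    valid: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
    model: PolicyModel | None = None,
    label_hashes: Sequence[str] | None = None,
) -> PolicyModel:
    """Train the policy network; history is stored on ``model.history_``.

    The validation loss drives both the plateau learning-rate decay and
    early stopping (best weights are restored on stop).
    """
    config = config or TrainConfig()
    X_train, y_train = np.asarray(train[0], dtype=np.float64), np.asarray(train[1])
    X_valid, y_valid = np.asarray(valid[0], dtype=np.float64), np.asarray(valid[1])
    n_labels = int(max(y_train.max(), y_valid.max() if len(y_valid) else 0)) + 1
    if label_hashes is not None:
        # the output space is the template library, not just the labels seen
        n_labels = max(n_labels, len(label_hashes))
    if model is None:
        model = PolicyModel(
            n_bits=X_train.shape[1],
            n_labels=n_labels,
            hidden=config.hidden,
            l2=config.l2,
            dropout=config.dropout,
            seed=config.seed,
            label_hashes=label_hashes,
        )
    if model.n_labels < n_labels:
        raise ValueError("dataset contains labels outside the model's label space")

    rng = np.random.RandomState(config.seed + 1)
    lr = config.learning_rate
    l2 = config.l2

    params = [model.W1, model.b1, model.W2, model.b2]
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    adam_t = 0

    def valid_metrics() -> dict[str, float]:
        probs = model.predict_proba(X_valid)
        clipped = np.clip(probs[np.arange(len(y_valid)), y_valid], 1e-12, None)
        loss = float(-np.log(clipped).mean())
        out = {"val_loss": loss}
        for k in config.topk:
            out[f"top{k}"] = topk_accuracy_from_probs(probs, y_valid, k)
        return out

    history: list[dict[str, float]] = []
    best_loss = np.inf
    best_weights = [p.copy() for p in params]
    plateau_wait = 0
    stop_wait = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(y_train))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            Xb, yb = X_train[batch], y_train[batch]
            nb = len(batch)

            z1 = Xb @ model.W1 + model.b1
            h = _elu(z1)
            if config.dropout > 0:
                mask = (rng.random_sample(h.shape) >= config.dropout) / (
                    1.0 - config.dropout
                )
                h_drop = h * mask
            else:
                mask = None
                h_drop = h
            probs = _softmax(h_drop @ model.W2 + model.b2)
            clipped = np.clip(probs[np.arange(nb), yb], 1e-12, None)
            loss = -np.log(clipped).mean() + l2 * (
                np.sum(model.W1**2) + np.sum(model.W2**2)
            )
            epoch_loss += loss * nb

            dz2 = probs.copy()
            dz2[np.arange(nb), yb] -= 1.0
            dz2 /= nb
            grad_W2 = h_drop.T @ dz2 + 2.0 * l2 * model.W2
            grad_b2 = dz2.sum(axis=0)
            dh = dz2 @ model.W2.T
            if mask is not None:
                dh *= mask
            dz1 = dh * np.where(z1 > 0, 1.0, np.exp(np.minimum(z1, 0.0)))
            grad_W1 = Xb.T @ dz1 + 2.0 * l2 * model.W1
            grad_b1 = dz1.sum(axis=0)

            adam_t += 1
            for p, g, m, v in zip(
                params, [grad_W1, grad_b1, grad_W2, grad_b2], m_state, v_state
            ):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                m_hat = m / (1 - beta1**adam_t)
                v_hat = v / (1 - beta2**adam_t)
                p -= lr * m_hat / (np.sqrt(v_hat) + eps)

        row = {"epoch": epoch, "loss": epoch_loss / len(order), "lr": lr}
        row.update(valid_metrics())
        history.append(row)

        val_loss = row["val_loss"]
        if val_loss < best_loss - 1e-8:
            best_loss = val_loss
            best_weights = [p.copy() for p in params]
            plateau_wait = 0
            stop_wait = 0
        else:
            plateau_wait += 1
            stop_wait += 1
            if plateau_wait >= config.plateau_patience:
                lr = max(lr * config.decay_factor, config.min_learning_rate)
                plateau_wait = 0
            if stop_wait >= config.early_stop_patience:
                break

    model.W1, model.b1, model.W2, model.b2 = [w.copy() for w in best_weights]
    model.history_ = pd.DataFrame(history)
    return model


def predict_templates(
    model: PolicyModel,
    library: TemplateLibrary,
    smiles: str,
    top_n: int = 50,
) -> list[tuple[int, str, float]]:
    """Rank library templates for a compound by policy probability.

    Returns up to ``min(top_n, L)`` tuples ``(label, template_hash,
    probability)`` with non-increasing probabilities, ties broken by
    ascending label.
    """
    probs = model.predict_smiles(smiles)
    labels = np.arange(len(probs))
    order = np.lexsort((labels, -probs))[: min(top_n, len(library))]
    return [(int(i), library.hashes[int(i)], float(probs[i])) for i in order]
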