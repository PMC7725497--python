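"""Parallel-kernel convolutional hate scorer.

The classifier assigns each tweet a hate score in [0, 1].  Architecture: an
embedding layer, three parallel 1-D convolution branches with kernel sizes
2, 3 and 4 (each followed by a rectifier and global max pooling), branch
concatenation, a rectified hidden dense layer and a single sigmoid output
unit.  Scores at or above 0.5 are labelled hate and further binned into
three hate levels: low [0.50, 0.675), average [0.675, 0.855) and high
[0.855, 1.0] — half-open midpoint boundaries close the gaps left by the
two-decimal bin labels 0.50-0.67 / 0.68-0.85 / 0.86-1.00 so that every
score receives a level.

The network is implemented directly on NumPy with explicit backpropagation
and Adam updates; training is a pure function of (config, data, seed), so a
fixed seed reproduces scores bit for bit.
"""
from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import DEFAULT_STOPWORDS, preprocess_text
from .records import TweetRecord

__all__ = [
    "CNNConfig",
    "HateScore",
    "HateCNN",
    "build_vocab",
    "encode",
    "decode",
    "train",
    "assign_level",
    "classify_score",
    "score_corpus",
]

PAD_INDEX = 0
HATE_THRESHOLD = 0.5
# Upper edges of the low and average bins (midpoints of the 0.67-0.68 and
# 0.85-0.86 gaps in the published two-decimal bin labels).
LOW_UPPER = 0.675
AVERAGE_UPPER = 0.855

LEVELS = ("none", "low", "average", "high")


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters of the hate scorer.

    Kernel sizes default to the three parallel branches (2, 3, 4); the
    remaining sizes are conventional defaults for short-text classification
    and are all overridable.
    """

    vocab_size: int = 10_000
    max_len: int = 50
    embed_dim: int = 100
    kernel_sizes: tuple[int, ...] = (2, 3, 4)
    filters_per_kernel: int = 100
    dense_units: int = 64
    epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.kernel_sizes)
        object.__setattr__(self, "kernel_sizes", ks)
        if not ks:
            raise ValueError("kernel_sizes must be nonempty")
        if any(k < 1 or k > self.max_len for k in ks):
            raise ValueError("each kernel size must be in [1, max_len]")
        if min(self.vocab_size, self.max_len, self.embed_dim,
               self.filters_per_kernel, self.dense_units,
               self.epochs, self.batch_size) < 1:
            raise ValueError("all size hyperparameters must be positive")


def build_vocab(texts: Iterable[Sequence[str]], vocab_size: int) -> dict[str, int]:
    """Index the ``vocab_size`` most frequent tokens from 1.

    Index 0 is reserved for padding; out-of-vocabulary tokens map to the
    dedicated unknown index ``len(vocab) + 1``.  Frequency ties break
    lexicographically so the vocabulary is stable across runs.
    """
    counts: Counter[str] = Counter()
    n_texts = 0
    for tokens in texts:
        n_texts += 1
        counts.update(tokens)
    if n_texts == 0:
        raise ValueError("cannot build a vocabulary from an empty training set")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {tok: i + 1 for i, (tok, _) in enumerate(ranked[:vocab_size])}


def unknown_index(vocab: dict[str, int]) -> int:
    return len(vocab) + 1


def encode(tokens: Sequence[str], vocab: dict[str, int], max_len: int) -> np.ndarray:
    """Map tokens to indices, truncate to ``max_len``, right-pad with 0."""
    unk = unknown_index(vocab)
    ids = [vocab.get(t, unk) for t in tokens[:max_len]]
    ids.extend([PAD_INDEX] * (max_len - len(ids)))
    return np.asarray(ids, dtype=np.int64)


def decode(ids: Sequence[int], vocab: dict[str, int]) -> list[str]:
    """Inverse of :func:`encode` for in-vocabulary, non-pad indices."""
    inv = {i: t for t, i in vocab.items()}
    unk = unknown_index(vocab)
    out = []
    for i in ids:
        if i == PAD_INDEX:
            continue
        out.append(inv.get(int(i), "<unk>") if i != unk else "<unk>")
    return out


def assign_level(score: float) -> str:
    """Bin a hate score into none/low/average/high.

    The bins partition [0, 1]: scores below the 0.5 hate threshold are
    ``none`` (non-hate); [0.5, 0.675) low, [0.675, 0.855) average and
    [0.855, 1.0] high.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"hate score must lie in [0, 1], got {score!r}")
    if score < HATE_THRESHOLD:
        return "none"
    if score < LOW_UPPER:
        return "low"
    if score < AVERAGE_UPPER:
        return "average"
    return "high"


@dataclass(frozen=True)
class HateScore:
    """Score, binary label and hate level for one tweet."""

    score: float
    label: str
    level: str


def classify_score(score: float) -> HateScore:
    level = assign_level(score)
    label = "hate" if score >= HATE_THRESHOLD else "non_hate"
    return HateScore(float(score), label, level)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class HateCNN:
    """Trained hate scorer: vocabulary + network weights.

    Build instances with :func:`train` or :meth:`HateCNN.load`.
    """

    def __init__(self, config: CNNConfig, vocab: dict[str, int],
                 params: dict[str, np.ndarray]):
        self.config = config
        self.vocab = vocab
        self.params = params
        self.loss_trace: list[float] = []

    # -- forward ---------------------------------------------------------

    def _forward(self, X: np.ndarray, keep_cache: bool = False):
        p = self.params
        emb = p["E"][X]                                   # (B, L, d)
        B = X.shape[0]
        pooled_parts, cache = [], []
        for k in self.config.kernel_sizes:
            win = sliding_window_view(emb, k, axis=1)     # (B, P, d, k)
            win = win.transpose(0, 1, 3, 2).reshape(B, -1, k * self.config.embed_dim)
            z = win @ p[f"W_conv{k}"] + p[f"b_conv{k}"]   # (B, P, f)
            a = _relu(z)
            arg = a.argmax(axis=1)                        # (B, f)
            pooled = np.take_along_axis(a, arg[:, None, :], axis=1)[:, 0, :]
            pooled_parts.append(pooled)
            if keep_cache:
                cache.append((win, z, arg))
        h0 = np.concatenate(pooled_parts, axis=1)         # (B, sum f)
        z1 = h0 @ p["W1"] + p["b1"]
        a1 = _relu(z1)
        z2 = a1 @ p["W2"] + p["b2"]
        prob = _sigmoid(z2)[:, 0]
        if keep_cache:
            return prob, (emb, cache, h0, z1, a1)
        return prob

    def scores(self, texts: Sequence[Sequence[str]], batch_size: int = 256) -> np.ndarray:
        """Score a batch of tokenized (classifier-mode) texts."""
        if len(texts) == 0:
            return np.empty(0)
        X = np.stack([encode(t, self.vocab, self.config.max_len) for t in texts])
        out = [self._forward(X[i:i + batch_size])
               for i in range(0, len(X), batch_size)]
        return np.concatenate(out)

    def score(self, tokens: Sequence[str]) -> float:
        return float(self.scores([tokens])[0])

    def classify(self, tokens: Sequence[str]) -> HateScore:
        return classify_score(self.score(tokens))

    # -- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Save config (JSON), vocabulary (TSV) and weights (JSON) to a dir."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(
            json.dumps(asdict(self.config)), encoding="utf-8")
        with open(directory / "vocab.tsv", "w", encoding="utf-8") as fh:
            for tok, idx in sorted(self.vocab.items(), key=lambda kv: kv[1]):
                fh.write(f"{tok}\t{idx}\n")
        weights = {name: arr.tolist() for name, arr in self.params.items()}
        (directory / "weights.json").write_text(json.dumps(weights),
                                                encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "HateCNN":
        directory = Path(directory)
        cfg = json.loads((directory / "config.json").read_text(encoding="utf-8"))
        cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
        config = CNNConfig(**cfg)
        vocab: dict[str, int] = {}
        with open(directory / "vocab.tsv", encoding="utf-8") as fh:
            for line in fh:
                tok, idx = line.rstrip("\n").split("\t")
                vocab[tok] = int(idx)
        weights = json.loads((directory / "weights.json").read_text(encoding="utf-8"))
        params = {name: np.asarray(arr, dtype=np.float64)
                  for name, arr in weights.items()}
        return cls(config, vocab, params)


def _init_params(config: CNNConfig, vocab: dict[str, int],
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    d, f = config.embed_dim, config.filters_per_kernel
    n_rows = len(vocab) + 2                    # pad + tokens + unk
    params = {"E": rng.normal(0.0, 0.1, size=(n_rows, d))}
    params["E"][PAD_INDEX] = 0.0
    for k in config.kernel_sizes:
        fan_in = k * d
        params[f"W_conv{k}"] = rng.normal(0.0, np.sqrt(2.0 / (fan_in + f)),
                                          size=(fan_in, f))
        params[f"b_conv{k}"] = np.zeros(f)
    total_f = f * len(config.kernel_sizes)
    params["W1"] = rng.normal(0.0, np.sqrt(2.0 / (total_f + config.dense_units)),
                              size=(total_f, config.dense_units))
    params["b1"] = np.zeros(config.dense_units)
    params["W2"] = rng.normal(0.0, np.sqrt(2.0 / (config.dense_units + 1)),
                              size=(config.dense_units, 1))
    params["b2"] = np.zeros(1)
    return params


def _backward(model: HateCNN, X: np.ndarray, y: np.ndarray,
              prob: np.ndarray, cache) -> dict[str, np.ndarray]:
    p = model.params
    cfg = model.config
    emb, conv_cache, h0, z1, a1 = cache
    B, L, d = emb.shape
    f = cfg.filters_per_kernel
    grads: dict[str, np.ndarray] = {}

    dz2 = ((prob - y) / B)[:, None]                       # (B, 1)
    grads["W2"] = a1.T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    dz1 = (dz2 @ p["W2"].T) * (z1 > 0)
    grads["W1"] = h0.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    dh0 = dz1 @ p["W1"].T

    demb = np.zeros_like(emb)
    for bi, k in enumerate(cfg.kernel_sizes):
        win, z, arg = conv_cache[bi]
        dpooled = dh0[:, bi * f:(bi + 1) * f]             # (B, f)
        da = np.zeros_like(z)
        np.put_along_axis(da, arg[:, None, :], dpooled[:, None, :], axis=1)
        dz = da * (z > 0)
        P = z.shape[1]
        grads[f"W_conv{k}"] = (
            win.reshape(B * P, -1).T @ dz.reshape(B * P, f))
        grads[f"b_conv{k}"] = dz.sum(axis=(0, 1))
        dwin = (dz @ p[f"W_conv{k}"].T).reshape(B, P, k, d)
        for j in range(k):
            demb[:, j:j + P, :] += dwin[:, :, j, :]

    dE = np.zeros_like(p["E"])
    np.add.at(dE, X.ravel(), demb.reshape(-1, d))
    dE[PAD_INDEX] = 0.0                                   # padding stays frozen
    grads["E"] = dE
    return grads


def train(config: CNNConfig,
          texts: Sequence[Sequence[str]],
          labels: Sequence[int]) -> HateCNN:
    """Train the scorer on tokenized texts with binary hate labels.

    Binary cross-entropy minimized with Adam; deterministic given
    ``config.seed``.  The mean loss per epoch is recorded on the returned
    model's ``loss_trace``.
    """
    labels_arr = np.asarray(labels, dtype=np.float64)
    if len(texts) != len(labels_arr):
        raise ValueError("texts and labels must have equal length")
    n_pos = int(labels_arr.sum())
    if n_pos < 2 or len(labels_arr) - n_pos < 2:
        raise ValueError("training requires at least 2 examples per class")

    vocab = build_vocab(texts, config.vocab_size)
    rng = np.random.default_rng(config.seed)
    model = HateCNN(config, vocab, _init_params(config, vocab, rng))
    X = np.stack([encode(t, vocab, config.max_len) for t in texts])
    y = labels_arr

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(X))
        epoch_losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb, yb = X[idx], y[idx]
            prob, cache = model._forward(Xb, keep_cache=True)
            prob_c = np.clip(prob, 1e-12, 1 - 1e-12)
            loss = -np.mean(yb * np.log(prob_c) + (1 - yb) * np.log(1 - prob_c))
            epoch_losses.append(float(loss))
            grads = _backward(model, Xb, yb, prob, cache)
            t += 1
            for name, g in grads.items():
                adam_m[name] = beta1 * adam_m[name] + (1 - beta1) * g
                adam_v[name] = beta2 * adam_v[name] + (1 - beta2) * g * g
                m_hat = adam_m[name] / (1 - beta1 ** t)
                v_hat = adam_v[name] / (1 - beta2 ** t)
                model.params[name] -= (
                    config.learning_rate * m_hat / (np.sqrt(v_hat) + eps))
            model.params["E"][PAD_INDEX] = 0.0
        model.loss_trace.append(float(np.mean(epoch_losses)))
    return model


def score_corpus(
    model: HateCNN,
    records: Sequence[TweetRecord],
    lemma_table=None,
    stopwords=DEFAULT_STOPWORDS,
) -> list[TweetRecord]:
    """Preprocess (classifier mode) and score records in place."""
    texts = [
        preprocess_text(r.text, "classifier", lemma_table, stopwords).tokens
        for r in records
    ]
    scores = model.scores(texts)
    for rec, s in zip(records, scores):
        hs = classify_score(float(s))
        rec.score, rec.label, rec.level = hs.score, hs.label, hs.level
    return list(records)
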