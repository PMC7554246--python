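"""Embedding-initialised multilayer 1D convolutional classifier.

A lysine-centred 31-mer tokenizes into 30 overlapping bigrams; the
embedding layer maps them to a 30 x d matrix (d = 20 by default).  Three
identical blocks of [1D convolution (128 filters, width 3, rectifier) ->
max pool (2) -> dropout (0.5)] feed two rectified dense layers (128, 64)
and a single logistic output unit giving the ubiquitylation probability.
With valid convolutions the per-block lengths run 30 -> 28 -> 14 -> 12 ->
6 -> 4 -> 2, so the flattened feature vector has 2 x 128 = 256 entries.

Training minimises mean binary cross-entropy with RMSprop (learning rate
0.001, squared-gradient decay 0.9).  Convolution and dense weights start
from Gaussian(0, 0.01); the embedding starts from the transferred
skip-gram matrix and is fine-tuned with the rest unless frozen.  The whole
network — forward, backward and optimiser — is implemented in vectorised
NumPy (float32, im2col convolutions), single-threaded deterministic given
the seeds.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import seq_data
from .embedding import BigramVocabulary, EmbeddingMatrix, build_vocab, tokenize
from .seq_data import FragmentDataset, ProteinRecord, SiteFragment

_BCE_EPS = 1e-7
# RMSprop denominator floor; 1e-8 keeps updates alive under the Gaussian(0, 0.01)
# initialisation, whose early gradients sit near 1e-9
_RMS_EPS = 1e-8


@dataclass
class CNNConfig:
    n_blocks: int = 3
    conv_filters: int = 128
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rate: float = 0.5
    dense_sizes: tuple[int, ...] = (128, 64)
    conv_padding: str = "valid"
    window: int = 31

    def __post_init__(self) -> None:
        if min(self.n_blocks, self.conv_filters, self.kernel_size, self.pool_size) < 1:
            raise ValueError("sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.conv_padding not in ("valid", "same"):
            raise ValueError("conv_padding must be 'valid' or 'same'")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    rms_decay: float = 0.9
    batch_size: int = 500
    epochs: int = 120
    init_sigma: float = 0.01
    seed: int = 0
    freeze_embedding: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("rates and sizes must be positive")
        if not 0.0 < self.rms_decay < 1.0:
            raise ValueError("rms_decay must lie in (0, 1)")


@dataclass
class SitePrediction:
    protein_id: str
    position: int  # 1-based
    score: float
    predicted: bool


@dataclass
class TrainedModel:
    """Network parameters plus configs, vocabulary, and training history."""

    params: dict[str, np.ndarray]
    cnn_config: CNNConfig
    vocab: BigramVocabulary
    train_config: TrainConfig | None = None
    history: list[float] = field(default_factory=list)

    @property
    def embedding_dim(self) -> int:
        return self.params["E"].shape[1]

    @property
    def n_tokens(self) -> int:
        return self.cnn_config.window - self.vocab.n + 1

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params.values())


def layer_lengths(cfg: CNNConfig, n_tokens: int) -> list[int]:
    """Token-axis length after each conv/pool stage (valid padding shrinks)."""
    lengths = [n_tokens]
    L = n_tokens
    for _ in range(cfg.n_blocks):
        if cfg.conv_padding == "valid":
            L = L - cfg.kernel_size + 1
        if L < 1:
            raise ValueError("input too short for the configured conv stack")
        lengths.append(L)
        L = L // cfg.pool_size
        if L < 1:
            raise ValueError("input too short for the configured pool stack")
        lengths.append(L)
    return lengths


def expected_parameter_count(
    cfg: CNNConfig, vocab_size: int, embedding_dim: int
) -> int:
    """Closed-form parameter count for cross-checking the built model."""
    n_tokens = cfg.window - 1  # bigram stream; callers with n != 2 adjust
    total = vocab_size * embedding_dim
    c_in = embedding_dim
    L = n_tokens
    for _ in range(cfg.n_blocks):
        total += cfg.kernel_size * c_in * cfg.conv_filters + cfg.conv_filters
        c_in = cfg.conv_filters
        if cfg.conv_padding == "valid":
            L = L - cfg.kernel_size + 1
        L = L // cfg.pool_size
    flat = L * cfg.conv_filters
    for size in cfg.dense_sizes:
        total += flat * size + size
        flat = size
    total += flat + 1  # logistic output unit
    return total


def build_model(
    cnn: CNNConfig,
    embedding: EmbeddingMatrix,
    seed: int = 0,
    init_sigma: float = 0.01,
) -> TrainedModel:
    """Assemble the untrained network with the embedding transferred verbatim.

    Convolution and dense weights draw from Gaussian(0, ``init_sigma``),
    biases start at zero; the embedding rows are copied exactly from the
    supplied (pretrained or random) matrix.
    """
    vocab = embedding.vocab
    if embedding.matrix.shape[0] != vocab.size:
        raise ValueError(
            f"embedding rows {embedding.matrix.shape[0]} != vocabulary size {vocab.size}"
        )
    n_tokens = cnn.window - vocab.n + 1
    lengths = layer_lengths(cnn, n_tokens)
    rng = np.random.default_rng(seed)
    d = embedding.matrix.shape[1]
    params: dict[str, np.ndarray] = {"E": embedding.matrix.astype(np.float32).copy()}
    c_in = d
    for b in range(cnn.n_blocks):
        params[f"Wc{b}"] = rng.normal(
            0.0, init_sigma, size=(cnn.kernel_size * c_in, cnn.conv_filters)
        ).astype(np.float32)
        params[f"bc{b}"] = np.zeros(cnn.conv_filters, dtype=np.float32)
        c_in = cnn.conv_filters
    flat = lengths[-1] * cnn.conv_filters
    sizes = list(cnn.dense_sizes) + [1]
    for i, size in enumerate(sizes):
        params[f"Wd{i}"] = rng.normal(0.0, init_sigma, size=(flat, size)).astype(
            np.float32
        )
        params[f"bd{i}"] = np.zeros(size, dtype=np.float32)
        flat = size
    return TrainedModel(params=params, cnn_config=cnn, vocab=vocab)


def _conv_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray, k: int):
    B, L, C = X.shape
    Lout = L - k + 1
    patches = sliding_window_view(X, k, axis=1)  # (B, Lout, C, k)
    P2 = np.ascontiguousarray(patches.transpose(0, 1, 3, 2)).reshape(
        B * Lout, k * C
    )
    Z = (P2 @ W + b).reshape(B, Lout, W.shape[1])
    return Z, P2


def _forward(
    model: TrainedModel,
    tokens: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    caches: list | None = None,
) -> np.ndarray:
    """Forward pass over a (B, T) int token batch; returns (B,) scores.

    When ``caches`` is a list, intermediate activations needed for
    backpropagation are appended to it.
    """
    cfg = model.cnn_config
    p = model.params
    k, pool, rate = cfg.kernel_size, cfg.pool_size, cfg.dropout_rate
    X = p["E"][tokens]  # (B, T, d)
    block_caches = []
    for b in range(cfg.n_blocks):
        W, bias = p[f"Wc{b}"], p[f"bc{b}"]
        Z, P2 = _conv_forward(X, W, bias, k)
        A = np.maximum(Z, 0.0)
        B_, Lout, F = A.shape
        Lp = Lout // pool
        At = A[:, : Lp * pool].reshape(B_, Lp, pool, F)
        arg = At.argmax(axis=2)
        pooled = np.take_along_axis(At, arg[:, :, None, :], axis=2)[:, :, 0, :]
        if train_mode and rate > 0.0:
            mask = (rng.random(pooled.shape) >= rate).astype(np.float32)
            out = pooled * mask / (1.0 - rate)
        else:
            mask = None
            out = pooled
        block_caches.append((X, P2, Z, arg, mask, Lout))
        X = out
    Bn = X.shape[0]
    flat = X.reshape(Bn, -1)
    dense_caches = []
    h = flat
    n_dense = len(cfg.dense_sizes)
    for i in range(n_dense):
        z = h @ p[f"Wd{i}"] + p[f"bd{i}"]
        a = np.maximum(z, 0.0)
        dense_caches.append((h, z))
        h = a
    logit = (h @ p[f"Wd{n_dense}"] + p[f"bd{n_dense}"])[:, 0]
    score = 1.0 / (1.0 + np.exp(-logit))
    if caches is not None:
        caches.append((tokens, block_caches, flat, dense_caches, h, X.shape))
    return score


def _backward(
    model: TrainedModel,
    cache,
    score: np.ndarray,
    labels: np.ndarray,
    freeze_embedding: bool,
) -> dict[str, np.ndarray]:
    """Gradients of mean BCE w.r.t. every parameter."""
    cfg = model.cnn_config
    p = model.params
    k, pool, rate = cfg.kernel_size, cfg.pool_size, cfg.dropout_rate
    tokens, block_caches, flat, dense_caches, h_last, conv_out_shape = cache
    B = len(labels)
    grads: dict[str, np.ndarray] = {}

    dlogit = ((score - labels) / B).astype(np.float32)  # sigmoid + BCE
    n_dense = len(cfg.dense_sizes)
    grads[f"Wd{n_dense}"] = h_last.T @ dlogit[:, None]
    grads[f"bd{n_dense}"] = np.array([dlogit.sum()], dtype=np.float32)
    dh = dlogit[:, None] @ p[f"Wd{n_dense}"].T
    for i in range(n_dense - 1, -1, -1):
        h_in, z = dense_caches[i]
        dz = dh * (z > 0)
        grads[f"Wd{i}"] = h_in.T @ dz
        grads[f"bd{i}"] = dz.sum(axis=0)
        dh = dz @ p[f"Wd{i}"].T
    dX = dh.reshape(conv_out_shape)

    for b in range(cfg.n_blocks - 1, -1, -1):
        X_in, P2, Z, arg, mask, Lout = block_caches[b]
        B_, Lp, F = dX.shape
        if mask is not None:
            dX = dX * mask / (1.0 - rate)
        dAt = np.zeros((B_, Lp, pool, F), dtype=np.float32)
        np.put_along_axis(dAt, arg[:, :, None, :], dX[:, :, None, :], axis=2)
        dA = np.zeros((B_, Lout, F), dtype=np.float32)
        dA[:, : Lp * pool] = dAt.reshape(B_, Lp * pool, F)
        dZ = dA * (Z > 0)
        dZ2 = dZ.reshape(B_ * Lout, F)
        grads[f"Wc{b}"] = P2.T @ dZ2
        grads[f"bc{b}"] = dZ.sum(axis=(0, 1))
        dP2 = (dZ2 @ p[f"Wc{b}"].T).reshape(B_, Lout, k, -1)
        C = dP2.shape[3]
        L_in = X_in.shape[1]
        dXin = np.zeros((B_, L_in, C), dtype=np.float32)
        for j in range(k):
            dXin[:, j : j + Lout] += dP2[:, :, j, :]
        dX = dXin

    if not freeze_embedding:
        dE = np.zeros_like(p["E"])
        np.add.at(dE, tokens, dX)
        grads["E"] = dE
    return grads


def bce_loss(labels, scores) -> float:
    """Mean binary cross-entropy; scores clipped to [eps, 1 - eps], eps = 1e-7."""
    labels = np.asarray(labels, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {scores.shape}")
    s = np.clip(scores, _BCE_EPS, 1.0 - _BCE_EPS)
    return float(-np.mean(labels * np.log(s) + (1.0 - labels) * np.log(1.0 - s)))


def tokenize_fragments(
    fragments: list[SiteFragment], vocab: BigramVocabulary, window: int
) -> np.ndarray:
    out = np.empty((len(fragments), window - vocab.n + 1), dtype=np.int32)
    for i, frag in enumerate(fragments):
        if frag.window != window:
            raise ValueError(
                f"fragment {frag.protein_id}:{frag.center_position} has length "
                f"{frag.window}, model expects {window}"
            )
        out[i] = tokenize(frag.sequence, vocab).indices
    return out


def train(
    model: TrainedModel, dataset: FragmentDataset, config: TrainConfig | None = None
) -> TrainedModel:
    """Fine-tune the network in place with RMSprop on mean BCE.

    Dropout is active only here; the embedding updates with the rest unless
    ``config.freeze_embedding``.  ``model.history`` records the mean
    training loss of each epoch.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = TrainConfig()
    if len(dataset) == 0:
        raise ValueError("train: empty dataset")
    labels = dataset.labels().astype(np.float32)
    if labels.min() == labels.max():
        raise ValueError("train: dataset must contain both classes")
    tokens = tokenize_fragments(dataset.fragments, model.vocab, model.cnn_config.window)
    rng = np.random.default_rng(config.seed)
    cache_sq = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta = config.rms_decay
    lr = config.learning_rate
    model.train_config = config
    model.history = []
    n = len(labels)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            caches: list = []
            score = _forward(model, tokens[idx], True, rng, caches)
            y = labels[idx]
            epoch_loss += bce_loss(y, score) * len(idx)
            grads = _backward(model, caches[0], score, y, config.freeze_embedding)
            for name, g in grads.items():
                sq = cache_sq[name]
                sq *= beta
                sq += (1.0 - beta) * g * g
                model.params[name] -= lr * g / (np.sqrt(sq) + _RMS_EPS)
        model.history.append(epoch_loss / n)
    return model


def predict_fragments(
    model: TrainedModel, fragments: list[SiteFragment], batch_size: int = 512
) -> np.ndarray:
    """Score fragments (dropout off); order preserved, batch size immaterial."""
    tokens = tokenize_fragments(fragments, model.vocab, model.cnn_config.window)
    scores = np.empty(len(fragments), dtype=np.float64)
    for start in range(0, len(fragments), batch_size):
        scores[start : start + batch_size] = _forward(
            model, tokens[start : start + batch_size]
        )
    return scores


def predict_protein(
    model: TrainedModel, protein: ProteinRecord, threshold: float = 0.5
) -> list[SitePrediction]:
    """Score every lysine of a protein; ``predicted`` marks score >= threshold."""
    fragments = seq_data.extract_fragments(protein, set(), model.cnn_config.window)
    if not fragments:
        return []
    scores = predict_fragments(model, fragments)
    return [
        SitePrediction(f.protein_id, f.center_position, float(s), bool(s >= threshold))
        for f, s in zip(fragments, scores)
    ]


def save_model(model: TrainedModel, out_dir) -> None:
    """Persist config (JSON), vocabulary (TSV) and weights (NPZ) in a directory."""
    os.makedirs(out_dir, exist_ok=True)
    cfg = {
        "cnn": {**vars(model.cnn_config), "dense_sizes": list(model.cnn_config.dense_sizes)},
        "vocab_n": model.vocab.n,
        "history": model.history,
        "train": vars(model.train_config) if model.train_config else None,
    }
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(cfg, fh, indent=1)
    with open(os.path.join(out_dir, "vocab.tsv"), "w") as fh:
        fh.write("token\tindex\n")
        for i in range(model.vocab.size):
            fh.write(f"{model.vocab.token_of(i)}\t{i}\n")
    np.savez(os.path.join(out_dir, "weights.npz"), **model.params)


def load_model(model_dir) -> TrainedModel:
    with open(os.path.join(model_dir, "config.json")) as fh:
        cfg = json.load(fh)
    cnn_kwargs = dict(cfg["cnn"])
    cnn_kwargs["dense_sizes"] = tuple(cnn_kwargs["dense_sizes"])
    cnn = CNNConfig(**cnn_kwargs)
    vocab = build_vocab(cfg["vocab_n"])
    with np.load(os.path.join(model_dir, "weights.npz")) as npz:
        params = {k: npz[k] for k in npz.files}
    train_cfg = TrainConfig(**cfg["train"]) if cfg.get("train") else None
    return TrainedModel(
        params=params,
        cnn_config=cnn,
        vocab=vocab,
        train_config=train_cfg,
        history=list(cfg.get("history", [])),
    )
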