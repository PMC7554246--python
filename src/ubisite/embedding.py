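"""Bigram tokenization and skip-gram pretraining of residue-pair embeddings.

Protein sequences are decomposed into overlapping n-grams (default n = 2,
giving 20^2 = 400 bigrams over the standard amino-acid alphabet, plus one
reserved pad token for any gram touching the pseudo-residue X).  A
skip-gram model with negative sampling is trained on the token streams of
whole proteins: each token predicts its neighbours within a +/-
``context_window`` positions.  The trained input-side (hidden-layer) weight
matrix is the embedding transferred into the classifier.

Training is plain NumPy, mini-batched and fully deterministic given the
config seed.  Because any two grams that ever co-occur share gradient
signal, tokens with similar sequence context end up with nearby vectors,
which is exactly the property the downstream classifier inherits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .seq_data import AA_ALPHABET, PAD_SYMBOL, ProteinRecord


@dataclass
class BigramVocabulary:
    """Ordered n-gram vocabulary over the 20 standard residues + pad token."""

    n: int
    tokens: list[str]
    index: dict[str, int]
    pad_token: str

    @property
    def pad_index(self) -> int:
        return len(self.tokens)

    @property
    def size(self) -> int:
        """Total row count including the reserved pad index."""
        return len(self.tokens) + 1

    def token_of(self, idx: int) -> str:
        return self.pad_token if idx == self.pad_index else self.tokens[idx]


@dataclass
class TokenSequence:
    indices: np.ndarray  # int32, vocabulary indices
    source_length: int
    pad_index: int

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class SkipGramConfig:
    embedding_dim: int = 20
    context_window: int = 2
    negative_samples: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    batch_size: int = 1024
    seed: int = 0
    center: bool = True

    def __post_init__(self) -> None:
        if self.embedding_dim < 1 or self.epochs < 1 or self.negative_samples < 1:
            raise ValueError("embedding_dim, epochs, negative_samples must be >= 1")
        if self.context_window < 1:
            raise ValueError("context_window must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class EmbeddingMatrix:
    """|vocabulary| x dim real matrix; row order follows the vocabulary."""

    matrix: np.ndarray
    vocab: BigramVocabulary
    provenance: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def build_vocab(n: int = 2) -> BigramVocabulary:
    """Lexicographically ordered n-grams over the 20 residues, plus a pad token."""
    if n not in (1, 2, 3):
        raise ValueError(f"n-gram length must be 1, 2 or 3, got {n}")
    tokens = ["".join(p) for p in product(AA_ALPHABET, repeat=n)]
    index = {t: i for i, t in enumerate(tokens)}
    return BigramVocabulary(n=n, tokens=tokens, index=index, pad_token=PAD_SYMBOL * n)


def tokenize(sequence: str, vocab: BigramVocabulary) -> TokenSequence:
    """All L - n + 1 overlapping n-grams in order; X-containing grams -> pad token."""
    n = vocab.n
    L = len(sequence)
    pad = vocab.pad_index
    if L < n:
        return TokenSequence(np.empty(0, dtype=np.int32), L, pad)
    idx = np.empty(L - n + 1, dtype=np.int32)
    get = vocab.index.get
    for i in range(L - n + 1):
        idx[i] = get(sequence[i : i + n], pad)
    return TokenSequence(idx, L, pad)


def detokenize(tokens: TokenSequence, vocab: BigramVocabulary) -> str:
    """Overlap-merge an X-free token sequence back into a residue string."""
    if len(tokens) == 0:
        return ""
    parts = [vocab.token_of(int(tokens.indices[0]))]
    for i in tokens.indices[1:]:
        parts.append(vocab.token_of(int(i))[-1])
    return "".join(parts)


def skipgram_pairs(tokens: TokenSequence, context_window: int = 2) -> np.ndarray:
    """(center, context) index pairs within +/- context_window; pad tokens skipped.

    Returns an (m, 2) int32 array.  For an X-free token stream of length
    L > 2w the pair count has the closed form 2 w L - w (w + 1).
    """
    if context_window < 1:
        raise ValueError("context_window must be >= 1")
    idx = tokens.indices
    L = len(idx)
    if L == 0:
        return np.empty((0, 2), dtype=np.int32)
    chunks = []
    for d in range(1, context_window + 1):
        if d >= L:
            break
        left, right = idx[:-d], idx[d:]
        chunks.append(np.stack([left, right], axis=1))   # context d to the right
        chunks.append(np.stack([right, left], axis=1))   # context d to the left
    if not chunks:
        return np.empty((0, 2), dtype=np.int32)
    pairs = np.concatenate(chunks, axis=0)
    keep = (pairs[:, 0] != tokens.pad_index) & (pairs[:, 1] != tokens.pad_index)
    return pairs[keep]


def corpus_pairs(
    proteins: list[ProteinRecord],
    vocab: BigramVocabulary,
    context_window: int = 2,
) -> np.ndarray:
    """All training pairs over a protein corpus."""
    chunks = []
    for prot in proteins:
        p = skipgram_pairs(tokenize(prot.sequence, vocab), context_window)
        if len(p):
            chunks.append(p)
    if not chunks:
        return np.empty((0, 2), dtype=np.int32)
    return np.concatenate(chunks, axis=0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def train_skipgram(
    proteins: list[ProteinRecord],
    vocab: BigramVocabulary,
    config: SkipGramConfig | None = None,
) -> EmbeddingMatrix:
    """Skip-gram with negative sampling over a whole-protein corpus.

    Negative contexts are drawn from the unigram distribution raised to the
    3/4 power.  The learning rate decays linearly over the run.  Returns
    the input-side weight matrix (the "hidden layer" of the two-layer
    word2vec network), one row per vocabulary token including the pad row.

    By default the trained rows are mean-centred before return
    (``config.center``): skip-gram vectors share a large common component
    that encodes corpus frequency rather than token identity, and on
    near-uniform corpora this component dwarfs the informative structure.
    Removing it is standard word-vector post-processing and leaves the
    pairwise geometry intact.
    """
    if config is None:
        config = SkipGramConfig()
    if not proteins:
        raise ValueError("train_skipgram: empty corpus")
    pairs = corpus_pairs(proteins, vocab, config.context_window)
    if len(pairs) == 0:
        raise ValueError("train_skipgram: corpus yields zero usable pairs")

    V, d = vocab.size, config.embedding_dim
    rng = np.random.default_rng(config.seed)
    w_in = ((rng.random((V, d)) - 0.5) / d).astype(np.float64)
    w_out = np.zeros((V, d), dtype=np.float64)

    # unigram^0.75 noise distribution over non-pad tokens
    counts = np.bincount(pairs[:, 0], minlength=V).astype(np.float64)
    noise = counts**0.75
    noise[vocab.pad_index] = 0.0
    noise_cdf = np.cumsum(noise / noise.sum())

    k = config.negative_samples
    total_batches = config.epochs * max(1, (len(pairs) + config.batch_size - 1) // config.batch_size)
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(pairs))
        for start in range(0, len(pairs), config.batch_size):
            batch = pairs[order[start : start + config.batch_size]]
            c, o = batch[:, 0], batch[:, 1]
            B = len(c)
            lr = config.learning_rate * max(1e-4, 1.0 - step / total_batches)
            step += 1

            neg = np.searchsorted(noise_cdf, rng.random((B, k))).astype(np.int32)
            v = w_in[c]  # (B, d)
            u_pos = w_out[o]  # (B, d)
            u_neg = w_out[neg]  # (B, k, d)

            g_pos = _sigmoid(np.einsum("bd,bd->b", v, u_pos)) - 1.0  # (B,)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, u_neg))  # (B, k)

            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            grad_u_pos = g_pos[:, None] * v
            grad_u_neg = g_neg[:, :, None] * v[:, None, :]

            np.add.at(w_in, c, -lr * grad_v)
            np.add.at(w_out, o, -lr * grad_u_pos)
            np.add.at(w_out, neg.ravel(), -lr * grad_u_neg.reshape(B * k, d))

    if config.center:
        trained = counts > 0
        w_in[trained] -= w_in[trained].mean(axis=0)
    digest = hashlib.sha1(
        "".join(p.sequence for p in proteins).encode()
    ).hexdigest()[:12]
    return EmbeddingMatrix(
        matrix=w_in,
        vocab=vocab,
        provenance={
            "corpus_digest": digest,
            "n_proteins": len(proteins),
            "n_pairs": int(len(pairs)),
            "config": vars(config).copy(),
        },
    )


def random_embedding(
    vocab: BigramVocabulary, dim: int = 20, sigma: float = 0.01, seed: int = 0
) -> EmbeddingMatrix:
    """Gaussian(0, sigma) embedding — the random-initialisation baseline."""
    rng = np.random.default_rng(seed)
    return EmbeddingMatrix(
        matrix=rng.normal(0.0, sigma, size=(vocab.size, dim)),
        vocab=vocab,
        provenance={"random_init": True, "sigma": sigma, "seed": seed},
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def nearest_neighbor(emb: EmbeddingMatrix, token: str) -> str:
    """Cosine nearest vocabulary token (pad row excluded)."""
    i = emb.vocab.index[token]
    M = emb.matrix[: len(emb.vocab.tokens)]
    norms = np.linalg.norm(M, axis=1)
    sims = M @ M[i] / np.where(norms > 0, norms * norms[i], np.inf)
    sims[i] = -np.inf
    return emb.vocab.tokens[int(np.argmax(sims))]


def save_embedding_tsv(emb: EmbeddingMatrix, path) -> None:
    with open(path, "w") as fh:
        dim = emb.dim
        fh.write("token\t" + "\t".join(f"v{j}" for j in range(dim)) + "\n")
        for i in range(emb.vocab.size):
            vec = "\t".join(repr(float(x)) for x in emb.matrix[i])
            fh.write(f"{emb.vocab.token_of(i)}\t{vec}\n")


def load_embedding_tsv(path) -> EmbeddingMatrix:
    rows = []
    tokens = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    n = len(tokens[0])
    vocab = build_vocab(n)
    expected = vocab.tokens + [vocab.pad_token]
    if tokens != expected:
        raise ValueError(f"{path}: token order does not match the canonical vocabulary")
    return EmbeddingMatrix(np.array(rows), vocab, {"loaded_from": str(path)})
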