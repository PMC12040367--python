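"""Skip-gram with negative sampling (SGNS), trained from scratch.

For a centre unit u and an observed context unit v, the per-pair loss is

    L(u, v) = -log sigma(w_u . c_v) - sum_{j=1..k} log sigma(-w_u . c_nj)

with k noise units n_j drawn from the unigram distribution raised to the
3/4 power.  Optimisation is plain SGD with a linearly decaying learning
rate, word2vec-style dynamic windows (the effective window at each
position is uniform on 1..w), and frequent-unit subsampling (a unit with
corpus frequency f is discarded with probability 1 - sqrt(t/f), applied
independently per epoch).

Training is single-threaded and fully deterministic given the seed; the
batched SGD accumulates gradients over a minibatch of pairs before
applying them, which is the only deviation from strictly sequential
word2vec updates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .phrases import PhraseVocabulary, apply_phrases


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # log sigma(x) = -log(1 + exp(-x)), computed stably
    return -np.logaddexp(0.0, -x)


@dataclass
class SGNSParams:
    dim: int = 100
    window: int = 5
    negatives: int = 5
    subsample: float = 1e-3
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    batch_size: int = 2048
    update_clip: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("dim", "window", "negatives", "epochs", "batch_size"):
            if getattr(self, name) < 0 or (
                name in ("dim", "window", "batch_size") and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.subsample < 0:
            raise ValueError("learning_rate must be > 0 and subsample >= 0")


@dataclass
class DocumentVector:
    values: np.ndarray
    n_in_vocab: int

    @property
    def all_oov(self) -> bool:
        return self.n_in_vocab == 0


@dataclass
class EmbeddingModel:
    vocabulary: PhraseVocabulary
    input_vectors: np.ndarray   # (V, d)
    output_vectors: np.ndarray  # (V, d)
    params: SGNSParams
    loss_history: list[float] = field(default_factory=list)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.vocabulary.to_tsv(d / "vocabulary.tsv")
        np.save(d / "input_vectors.npy", self.input_vectors)
        np.save(d / "output_vectors.npy", self.output_vectors)
        manifest = asdict(self.params)
        manifest["loss_history"] = self.loss_history
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def initial_vectors(
    vocab_size: int, dim: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded initialisation: small uniform input vectors, zero outputs."""
    rng = np.random.default_rng(seed)
    w_in = ((rng.random((vocab_size, dim)) - 0.5) / dim).astype(np.float64)
    w_out = np.zeros((vocab_size, dim), dtype=np.float64)
    return w_in, w_out


def pair_loss(
    w_u: np.ndarray, c_v: np.ndarray, c_neg: np.ndarray
) -> float:
    """SGNS loss for one (centre, context) pair with fixed noise vectors."""
    pos = float(_log_sigmoid(np.array([w_u @ c_v]))[0])
    neg = float(_log_sigmoid(-(c_neg @ w_u)).sum())
    return -(pos + neg)


def pair_gradients(
    w_u: np.ndarray, c_v: np.ndarray, c_neg: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`pair_loss` w.r.t. (w_u, c_v, c_neg)."""
    s_pos = float(_sigmoid(np.array([w_u @ c_v]))[0])
    s_neg = _sigmoid(c_neg @ w_u)  # (k,)
    g_u = (s_pos - 1.0) * c_v + s_neg @ c_neg
    g_v = (s_pos - 1.0) * w_u
    g_neg = s_neg[:, None] * w_u[None, :]
    return g_u, g_v, g_neg


def _encode_corpus(
    corpus: Sequence[Sequence[str]], vocab: PhraseVocabulary
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten documents to unit-id and document-id arrays (OOV dropped)."""
    ids: list[int] = []
    doc_ids: list[int] = []
    u2i = vocab.unit_to_index
    for d, doc in enumerate(corpus):
        for tok in doc:
            j = u2i.get(tok)
            if j is not None:
                ids.append(j)
                doc_ids.append(d)
    return np.asarray(ids, dtype=np.int64), np.asarray(doc_ids, dtype=np.int64)


def _noise_cdf(vocab: PhraseVocabulary) -> np.ndarray:
    counts = np.zeros(vocab.size)
    for u, c in vocab.unit_counts.items():
        counts[vocab.unit_to_index[u]] = c
    p = counts ** 0.75
    p /= p.sum()
    return np.cumsum(p)


def _keep_probs(vocab: PhraseVocabulary, t: float) -> np.ndarray:
    total = max(vocab.total_tokens, 1)
    keep = np.ones(vocab.size)
    if t <= 0:
        return keep
    for u, c in vocab.unit_counts.items():
        f = c / total
        if f > t:
            keep[vocab.unit_to_index[u]] = np.sqrt(t / f)
    return keep


def _epoch_pairs(
    ids: np.ndarray,
    doc_ids: np.ndarray,
    keep: np.ndarray,
    window: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the stream and enumerate (centre, context) id pairs."""
    mask = rng.random(ids.shape[0]) < keep[ids]
    kept = ids[mask]
    kdoc = doc_ids[mask]
    if kept.shape[0] < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    radius = rng.integers(1, window + 1, size=kept.shape[0])
    centres = []
    contexts = []
    for off in range(1, window + 1):
        same_doc = kdoc[:-off] == kdoc[off:]
        left = same_doc & (radius[:-off] >= off)
        if left.any():
            centres.append(kept[:-off][left])
            contexts.append(kept[off:][left])
        right = same_doc & (radius[off:] >= off)
        if right.any():
            centres.append(kept[off:][right])
            contexts.append(kept[:-off][right])
    if not centres:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    c = np.concatenate(centres)
    x = np.concatenate(contexts)
    order = rng.permutation(c.shape[0])
    return c[order], x[order]


def train_sgns(
    corpus: Sequence[Sequence[str]],
    vocabulary: PhraseVocabulary,
    params: SGNSParams | None = None,
) -> EmbeddingModel:
    """Train input/output vectors on a unit corpus; seeded and single-worker."""
    params = params or SGNSParams()
    params.validate()
    if vocabulary.size < 2:
        raise ValueError("degenerate vocabulary: fewer than 2 distinct units")

    rng = np.random.default_rng(params.seed)
    w_in, w_out = initial_vectors(vocabulary.size, params.dim, params.seed)
    if params.epochs == 0:
        return EmbeddingModel(vocabulary, w_in, w_out, params, [])

    ids, doc_ids = _encode_corpus(corpus, vocabulary)
    if np.unique(ids).shape[0] < 2:
        raise ValueError("degenerate vocabulary: fewer than 2 distinct units")
    cdf = _noise_cdf(vocabulary)
    keep = _keep_probs(vocabulary, params.subsample)

    total_updates = 0  # set from the first epoch's actual pair count
    done = 0
    lr0, lr_min = params.learning_rate, params.min_learning_rate
    k = params.negatives
    clip = params.update_clip
    losses: list[float] = []

    for _ in range(params.epochs):
        centres, contexts = _epoch_pairs(
            ids, doc_ids, keep, params.window, rng
        )
        n_pairs = centres.shape[0]
        if total_updates == 0:
            total_updates = max(1, n_pairs * params.epochs)
        epoch_loss = 0.0
        for lo in range(0, n_pairs, params.batch_size):
            c = centres[lo: lo + params.batch_size]
            v = contexts[lo: lo + params.batch_size]
            b = c.shape[0]
            lr = max(lr_min, lr0 * (1.0 - done / total_updates))
            done += b

            x = w_in[c]            # (b, d)
            pos = w_out[v]         # (b, d)
            score_pos = np.einsum("bd,bd->b", x, pos)
            s_pos = _sigmoid(score_pos)
            if k > 0:
                neg_ids = np.searchsorted(cdf, rng.random((b, k)))
                neg = w_out[neg_ids]  # (b, k, d)
                score_neg = np.einsum("bkd,bd->bk", neg, x)
                s_neg = _sigmoid(score_neg)
                epoch_loss += float(
                    -(_log_sigmoid(score_pos).sum()
                      + _log_sigmoid(-score_neg).sum())
                )
                g_x = (s_pos - 1.0)[:, None] * pos + np.einsum(
                    "bk,bkd->bd", s_neg, neg
                )
                g_neg = s_neg[:, :, None] * x[:, None, :]
            else:
                epoch_loss += float(-_log_sigmoid(score_pos).sum())
                g_x = (s_pos - 1.0)[:, None] * pos
            g_pos = (s_pos - 1.0)[:, None] * x

            # elementwise clip keeps accumulated updates on very
            # frequent units from destabilising the batched SGD
            np.add.at(w_in, c, np.clip(-lr * g_x, -clip, clip))
            np.add.at(w_out, v, np.clip(-lr * g_pos, -clip, clip))
            if k > 0:
                np.add.at(
                    w_out,
                    neg_ids.ravel(),
                    np.clip(-lr * g_neg, -clip, clip).reshape(
                        -1, w_in.shape[1]
                    ),
                )
        losses.append(epoch_loss / max(n_pairs, 1))

    return EmbeddingModel(vocabulary, w_in, w_out, params, losses)


def embed_document(
    model: EmbeddingModel,
    tokens: Sequence[str],
    weighting: str = "uniform",
    merge_phrases: bool = True,
) -> DocumentVector:
    """Aggregate a document into one vector.

    Default is the unweighted mean of input vectors over in-vocabulary
    units after phrase re-merging; ``weighting="inverse_frequency"``
    down-weights frequent units by 1/log(2 + corpus count).  Documents
    with no in-vocabulary unit map to the zero vector with the OOV flag
    (``n_in_vocab == 0``) set.
    """
    units = apply_phrases(model.vocabulary, tokens) if merge_phrases else list(tokens)
    u2i = model.vocabulary.unit_to_index
    idx = [u2i[u] for u in units if u in u2i]
    d = model.input_vectors.shape[1]
    if not idx:
        return DocumentVector(values=np.zeros(d), n_in_vocab=0)
    vecs = model.input_vectors[idx]
    if weighting == "uniform":
        values = vecs.mean(axis=0)
    elif weighting == "inverse_frequency":
        counts = np.array(
            [model.vocabulary.unit_counts.get(u, 1) for u in units if u in u2i],
            dtype=float,
        )
        w = 1.0 / np.log(2.0 + counts)
        values = (w[:, None] * vecs).sum(axis=0) / w.sum()
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    return DocumentVector(values=values, n_in_vocab=len(idx))
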