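"""node2vec-style node embeddings of a patient similarity network.

Two biased second-order random-walk runs are performed per network — one
breadth-favouring (return parameter p=1, in-out parameter q=4) and one
depth-favouring (p=4, q=1) — each followed by skip-gram training with
negative sampling on the walk corpus.  The two d=128 embeddings are
concatenated, so every node carries 256 embedding features by default.

The skip-gram trainer is a mini-batch SGD implementation in numpy,
deterministic for a fixed seed: all scatter updates are exact segment sums,
there are no asynchronous workers.  Walk defaults (10 walks per node of 80
nodes each, window 10, one training pass) follow the node2vec reference
tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import PatientSimilarityNetwork, TopoFeatureSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    d: int = 128
    runs: tuple[tuple[float, float], ...] = ((1.0, 4.0), (4.0, 1.0))
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 10
    epochs: int = 1
    negative: int = 5
    learning_rate: float = 0.025
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValidationError("embedding dimension d must be >= 1")
        for p, q in self.runs:
            if p <= 0 or q <= 0:
                raise ValidationError("walk parameters p and q must be positive")
        if self.walk_length < 1 or self.walks_per_node < 1:
            raise ValidationError("walk counts must be positive")


def biased_random_walks(psn: PatientSimilarityNetwork, p: float, q: float,
                        walks_per_node: int = 10, walk_length: int = 80,
                        rng_seed: int = 0) -> list[list[str]]:
    """Second-order biased walks over the weighted network.

    From current node ``v`` (previous node ``t``) the unnormalized
    probability of stepping to ``x`` is ``w(v,x)`` times 1/p if ``x == t``,
    1 if ``x`` is a neighbour of ``t``, and 1/q otherwise.  Each node starts
    ``walks_per_node`` walks of ``walk_length`` nodes; an isolated start node
    yields a length-1 walk (logged, not an error).  All walks of one call
    advance in lock-step, which keeps the sampling fully vectorized and
    reproducible from the seed.
    """
    if p <= 0 or q <= 0:
        raise ValidationError("p and q must be positive")
    rng = np.random.default_rng(rng_seed)
    w = psn.w
    n = psn.n_patients
    ids = psn.patient_ids
    adj = w > 0
    row_sums = w.sum(axis=1)
    isolated = row_sums == 0
    if isolated.any():
        logger.info("%d isolated node(s): length-1 walks", isolated.sum())

    starts = np.concatenate([rng.permutation(n) for _ in range(walks_per_node)])
    active = ~isolated[starts]
    trail = np.full((len(starts), walk_length), -1, dtype=np.int64)
    trail[:, 0] = starts
    cur = starts[active].copy()
    prev = np.full(len(cur), -1, dtype=np.int64)
    rows = np.flatnonzero(active)
    for step in range(1, walk_length):
        probs = w[cur].copy()
        has_prev = prev >= 0
        if has_prev.any():
            hp = np.flatnonzero(has_prev)
            bias = np.where(adj[prev[hp]], 1.0, 1.0 / q)
            bias[np.arange(len(hp)), prev[hp]] = 1.0 / p
            probs[hp] *= bias
        totals = probs.sum(axis=1)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(len(cur)) * totals
        nxt = (cum >= u[:, None]).argmax(axis=1)
        trail[rows, step] = nxt
        prev, cur = cur, nxt.astype(np.int64)
    walks: list[list[str]] = []
    for row in trail:
        walks.append([ids[i] for i in row if i >= 0])
    return walks


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _scatter_sub(target: np.ndarray, idx: np.ndarray, grad: np.ndarray,
                 lr: float) -> None:
    """target[idx] -= lr * grad with exact (deterministic) duplicate handling.

    Duplicates are aggregated through a sparse one-hot product, which is both
    reproducible and far cheaper than element-wise scatter for the dense
    vocabularies of patient networks.
    """
    from scipy import sparse

    B = len(idx)
    onehot = sparse.csr_matrix(
        (np.ones(B, dtype=grad.dtype), (idx, np.arange(B))),
        shape=(target.shape[0], B))
    target -= lr * (onehot @ grad)


def _skipgram_pairs(corpus_enc: list[np.ndarray],
                    window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    by_len: dict[int, list[np.ndarray]] = {}
    for enc in corpus_enc:
        if len(enc) > 1:
            by_len.setdefault(len(enc), []).append(enc)
    for length, group in by_len.items():
        block = np.vstack(group)
        for off in range(1, min(window, length - 1) + 1):
            a = block[:, :-off].ravel()
            b = block[:, off:].ravel()
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    if not centers:
        raise ValidationError("empty training corpus")
    return np.concatenate(centers), np.concatenate(contexts)


def train_embedding(corpus: list[list[str]], d: int, window: int = 10,
                    rng_seed: int = 0, epochs: int = 1, negative: int = 5,
                    learning_rate: float = 0.025,
                    nodes: list[str] | None = None,
                    batch_size: int = 2048) -> tuple[list[str], np.ndarray]:
    """Skip-gram with negative sampling on a walk corpus.

    Returns ``(vocabulary, matrix)`` with one d-dimensional row per
    vocabulary node (sorted ids, or the order of ``nodes`` when given).
    Negative samples follow the unigram^0.75 noise distribution; the
    learning rate decays linearly over the run.  Deterministic for a fixed
    seed.  Raises if a requested node never appears in the corpus.
    """
    seen: dict[str, int] = {}
    for walk in corpus:
        for tok in walk:
            seen[tok] = seen.get(tok, 0) + 1
    if nodes is not None:
        missing = [v for v in nodes if v not in seen]
        if missing:
            raise ValidationError(f"node {missing[0]!r} absent from walk corpus")
        vocab = list(nodes)
    else:
        vocab = sorted(seen)
    index = {v: i for i, v in enumerate(vocab)}
    V = len(vocab)

    corpus_enc = [np.array([index[t] for t in walk if t in index],
                           dtype=np.int64) for walk in corpus]
    centers, contexts = _skipgram_pairs(corpus_enc, window)

    counts = np.zeros(V)
    for v, cnt in seen.items():
        if v in index:
            counts[index[v]] = cnt
    noise = counts ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(rng_seed)
    w_in = ((rng.random((V, d)) - 0.5) / d).astype(np.float32)
    w_out = np.zeros((V, d), dtype=np.float32)

    from scipy import sparse

    # cap the batch so each node aggregates only a handful of duplicate
    # updates per step; larger ratios make the effective step size explode
    batch_size = int(max(32, min(batch_size, 8 * V)))
    n_pairs = len(centers)
    total_batches = max(1, epochs * int(np.ceil(n_pairs / batch_size)))
    batch_no = 0
    for _epoch in range(epochs):
        perm = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            sel = perm[lo:lo + batch_size]
            lr = np.float32(learning_rate
                            * max(1e-4, 1.0 - batch_no / total_batches))
            batch_no += 1
            C, O = centers[sel], contexts[sel]
            B = len(sel)
            N = rng.choice(V, size=(B, negative), p=noise)
            vin = w_in[C]
            vpos = w_out[O]
            gpos = _sigmoid(np.einsum("bd,bd->b", vin, vpos)) - np.float32(1)
            vneg = w_out[N]
            gneg = _sigmoid(np.einsum("bd,bkd->bk", vin, vneg))
            grad_in = gpos[:, None] * vpos + np.einsum("bk,bkd->bd", gneg, vneg)
            _scatter_sub(w_in, C, grad_in, lr)
            _scatter_sub(w_out, O, gpos[:, None] * vin, lr)
            # aggregate the negative-context updates without materializing
            # the (B * negative, d) gradient
            agg = sparse.csr_matrix(
                (gneg.ravel(),
                 (N.ravel(), np.repeat(np.arange(B), negative))),
                shape=(V, B))
            w_out -= lr * (agg @ vin)
    return vocab, w_in.astype(float)


def node2vec_features(psn: PatientSimilarityNetwork,
                      config: EmbeddingConfig | None = None) -> TopoFeatureSet:
    """Concatenated embeddings of the configured walk runs (2*d columns)."""
    config = config or EmbeddingConfig()
    blocks, names = [], []
    for run_idx, (p, q) in enumerate(config.runs):
        walks = biased_random_walks(
            psn, p, q, config.walks_per_node, config.walk_length,
            rng_seed=config.rng_seed + run_idx)
        _, mat = train_embedding(
            walks, config.d, config.window, rng_seed=config.rng_seed + run_idx,
            epochs=config.epochs, negative=config.negative,
            learning_rate=config.learning_rate, nodes=list(psn.patient_ids))
        blocks.append(mat)
        names.extend(f"n2v_r{run_idx + 1}_{j}" for j in range(config.d))
    values = np.hstack(blocks)
    return TopoFeatureSet(list(psn.patient_ids), names, values,
                          family="embedding")
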