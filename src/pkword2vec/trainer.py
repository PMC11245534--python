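"""The prior-knowledge-regularized skip-gram trainer.

The model keeps two matrices per vocabulary: center vectors ``v`` and
context vectors ``u``.  The loss has two parts:

* the classic skip-gram negative-sampling (SGNS) term, summed over observed
  (center, context) pairs within a window of size ``m`` with ``K`` negative
  words drawn from the smoothed unigram distribution:
  ``-log sigma(u_ctx . v) - sum_k log sigma(-u_k . v)``;

* a prior-knowledge term: each time a center word ``t`` with prior
  knowledge is processed, one word ``j`` is sampled from its candidate
  distribution ``p_tj`` and the penalty
  ``gamma(t) * Psi = gamma(t) * ([1 - cos(u_t, u_j)] + [1 - cos(v_t, v_j)])``
  pulls ``t`` toward ``j`` in both vector spaces.  ``gamma(t) = tau /
  rel_freq(t)`` discounts frequent words, so corpus evidence dominates
  where it is plentiful.  With ``context_regularization=False`` only the
  center-vector cosine term is kept (the ablation without context-vector
  regularization).

The total objective is ``Loss_SGNS + alpha * Loss_PK``; ``alpha = 0``
recovers plain SGNS exactly.  Optimization is single-threaded mini-batch
SGD with a linearly decaying learning rate; batches are internally
vectorized with numpy but the update order is fully deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from .corpus import NegativeSamplingTable, Vocabulary, negative_table
from .prior import PriorSource
from .vectors import WordVectors

__all__ = [
    "TrainConfig",
    "EmbeddingPair",
    "TrainingExample",
    "sigmoid",
    "sgns_pair_loss",
    "gamma",
    "psi",
    "pk_step_loss",
    "total_loss",
    "gradients",
    "train",
]

_SIG_EPS = 1e-12
_NORM_EPS = 1e-9


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    window
        Context window half-width ``m``.
    negatives
        Negative samples ``K`` per (center, context) pair.
    alpha
        Weight of the prior-knowledge loss; 0 is the SGNS baseline.
    tau
        Frequency-discount threshold in ``gamma = tau / rel_freq``.
    dim
        Embedding dimension ``d``.
    epochs, batch_size, learning_rate
        SGD schedule; the learning rate decays linearly to
        ``min_lr_factor * learning_rate`` over all batches.
    context_regularization
        Include the context-vector cosine term in ``Psi``.
    ns_exponent
        Unigram smoothing exponent of the negative-sampling table.
    update_every
        Occurrences per SGD update within a batch.  The batch is the
        data-grouping and loss-accounting unit; parameter updates happen at
        this finer grain so the learning rate keeps its classic
        per-example scale (a whole-batch update would make only a handful
        of steps per epoch on a small corpus and cannot converge).
    """

    window: int = 5
    negatives: int = 5
    alpha: float = 0.0
    tau: float = 1e-5
    dim: int = 45
    epochs: int = 10
    batch_size: int = 10_000
    learning_rate: float = 0.025
    seed: int = 0
    context_regularization: bool = True
    ns_exponent: float = 0.75
    min_lr_factor: float = 1e-4
    update_every: int = 8

    def __post_init__(self) -> None:
        if min(self.window, self.negatives, self.dim, self.epochs,
               self.batch_size) < 1:
            raise ValueError("window, negatives, dim, epochs, batch_size "
                             "must be positive")
        if self.tau <= 0 or self.learning_rate <= 0:
            raise ValueError("tau and learning_rate must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")

    def with_(self, **kwargs) -> "TrainConfig":
        return replace(self, **kwargs)


@dataclass
class EmbeddingPair:
    """Trainable matrices of one model: center rows ``v``, context rows ``u``."""

    center: np.ndarray
    context: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        self.context = np.asarray(self.context, dtype=np.float64)
        if self.center.shape != self.context.shape:
            raise ValueError("center/context shape mismatch")

    @property
    def dim(self) -> int:
        return self.center.shape[1]

    def copy(self) -> "EmbeddingPair":
        return EmbeddingPair(self.center.copy(), self.context.copy())

    def word_vectors(self, vocab: Vocabulary, which: str = "center") -> WordVectors:
        matrix = self.center if which == "center" else self.context
        return WordVectors(vocab.words, matrix)

    @classmethod
    def init(cls, n_words: int, dim: int,
             rng: np.random.Generator) -> "EmbeddingPair":
        # word2vec convention: small uniform center rows, zero context rows
        center = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n_words, dim))
        return cls(center, np.zeros((n_words, dim)))


class TrainingExample(NamedTuple):
    """One center-word occurrence: its window contexts, the negatives drawn
    for each (center, context) pair, and the sampled prior word (or None)."""

    center: int
    contexts: tuple[int, ...]
    negatives: np.ndarray  # shape (len(contexts), K)
    prior: int | None


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    with np.errstate(over="ignore"):  # exp overflow -> sigma = 0 exactly
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return np.log(np.clip(sigmoid(x), _SIG_EPS, 1.0 - _SIG_EPS))


def sgns_pair_loss(u_ctx: np.ndarray, v_ctr: np.ndarray,
                   negs: np.ndarray) -> float:
    """SGNS loss of one (center, context) pair with its negative vectors:
    ``-log sigma(u_ctx . v) - sum_k log sigma(-u_k . v)``."""
    u_ctx = np.asarray(u_ctx, dtype=np.float64)
    v_ctr = np.asarray(v_ctr, dtype=np.float64)
    negs = np.atleast_2d(np.asarray(negs, dtype=np.float64))
    pos = -_log_sigmoid(np.array([u_ctx @ v_ctr]))[0]
    neg = -_log_sigmoid(-(negs @ v_ctr)).sum()
    return float(pos + neg)


def gamma(word_id: int, vocab: Vocabulary, tau: float) -> float:
    """Frequency discount ``tau / rel_freq(word)`` of the prior penalty."""
    return float(tau / vocab.rel_freq[word_id])


def psi(u_t: np.ndarray, u_j: np.ndarray, v_t: np.ndarray, v_j: np.ndarray,
        context_regularization: bool = True) -> float:
    """Prior-knowledge penalty ``[1 - cos(u_t,u_j)] + [1 - cos(v_t,v_j)]``;
    without context regularization only the center term remains."""
    from .vectors import cosine

    value = 1.0 - cosine(v_t, v_j)
    if context_regularization:
        value += 1.0 - cosine(u_t, u_j)
    return float(value)


def pk_step_loss(word_id: int, prior_id: int | None, pair: EmbeddingPair,
                 vocab: Vocabulary, config: TrainConfig) -> float:
    """One occurrence's prior-knowledge loss ``gamma(t) * Psi``; zero when
    the word has no prior knowledge."""
    if prior_id is None:
        return 0.0
    return gamma(word_id, vocab, config.tau) * psi(
        pair.context[word_id], pair.context[prior_id],
        pair.center[word_id], pair.center[prior_id],
        config.context_regularization,
    )


# ---------------------------------------------------------------------------
# vectorized batch core (shared by total_loss / gradients / train)
# ---------------------------------------------------------------------------


def _cosine_terms(A: np.ndarray, B: np.ndarray, w: np.ndarray):
    """Loss and gradients of ``w * (1 - cos(a, b))`` row-wise.

    Rows where either vector is (numerically) zero contribute nothing to
    loss or gradient: the cosine is undefined there, which only happens
    transiently for still-zero context rows at the very start of training.
    """
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    valid = (na > _NORM_EPS) & (nb > _NORM_EPS)
    n = A.shape[0]
    loss = np.zeros(n)
    gA = np.zeros_like(A)
    gB = np.zeros_like(B)
    if not valid.any():
        return loss, gA, gB
    Av, Bv = A[valid], B[valid]
    nav, nbv = na[valid, None], nb[valid, None]
    wv = w[valid, None]
    dot = np.einsum("nd,nd->n", Av, Bv)[:, None]
    cos = dot / (nav * nbv)
    loss[valid] = (w[valid]) * (1.0 - cos[:, 0])
    # d[1-cos]/dA = -(B/(|A||B|) - cos * A/|A|^2)
    gA[valid] = -wv * (Bv / (nav * nbv) - cos * Av / nav**2)
    gB[valid] = -wv * (Av / (nav * nbv) - cos * Bv / nbv**2)
    return loss, gA, gB


def _batch_arrays(batch: Sequence[TrainingExample], vocab: Vocabulary,
                  config: TrainConfig):
    """Flatten examples into pair-level and occurrence-level arrays."""
    pc, px, ng = [], [], []
    pt, pj, pw = [], [], []
    for ex in batch:
        negs = np.atleast_2d(np.asarray(ex.negatives, dtype=np.int64))
        for c, ctx in enumerate(ex.contexts):
            pc.append(ex.center)
            px.append(ctx)
            ng.append(negs[c])
        if ex.prior is not None:
            pt.append(ex.center)
            pj.append(ex.prior)
            pw.append(config.alpha * gamma(ex.center, vocab, config.tau))
    pair_center = np.array(pc, dtype=np.int64)
    pair_ctx = np.array(px, dtype=np.int64)
    negatives = (np.array(ng, dtype=np.int64) if ng
                 else np.zeros((0, config.negatives), dtype=np.int64))
    return (pair_center, pair_ctx, negatives,
            np.array(pt, dtype=np.int64), np.array(pj, dtype=np.int64),
            np.array(pw, dtype=np.float64))


def _core(pair_center, pair_ctx, negatives, pk_t, pk_j, pk_w,
          center, context, context_reg, want_grads=True):
    """Loss and (optionally) gradient matrices for one flattened batch.

    ``pk_w`` already carries ``alpha * gamma(t)`` per prior pair, so the
    returned ``loss_pk`` is the weighted prior loss as it enters the total
    objective.
    """
    d = center.shape[1]
    grad_c = np.zeros_like(center) if want_grads else None
    grad_x = np.zeros_like(context) if want_grads else None

    loss_sgns = 0.0
    if pair_center.size:
        V = center[pair_center]                      # (n, d)
        U = context[pair_ctx]                        # (n, d)
        UN = context[negatives]                      # (n, K, d)
        s_pos = np.einsum("nd,nd->n", U, V)
        s_neg = np.einsum("nkd,nd->nk", UN, V)
        loss_sgns = float(-_log_sigmoid(s_pos).sum()
                          - _log_sigmoid(-s_neg).sum())
        if want_grads:
            g_pos = sigmoid(s_pos) - 1.0             # (n,)
            g_neg = sigmoid(s_neg)                   # (n, K)
            gV = g_pos[:, None] * U + np.einsum("nk,nkd->nd", g_neg, UN)
            np.add.at(grad_c, pair_center, gV)
            np.add.at(grad_x, pair_ctx, g_pos[:, None] * V)
            np.add.at(grad_x, negatives.ravel(),
                      (g_neg[:, :, None] * V[:, None, :]).reshape(-1, d))

    loss_pk = 0.0
    if pk_t.size:
        lv, gvt, gvj = _cosine_terms(center[pk_t], center[pk_j], pk_w)
        loss_pk += float(lv.sum())
        if want_grads:
            np.add.at(grad_c, pk_t, gvt)
            np.add.at(grad_c, pk_j, gvj)
        if context_reg:
            lu, gut, guj = _cosine_terms(context[pk_t], context[pk_j], pk_w)
            loss_pk += float(lu.sum())
            if want_grads:
                np.add.at(grad_x, pk_t, gut)
                np.add.at(grad_x, pk_j, guj)

    return loss_sgns, loss_pk, grad_c, grad_x


def total_loss(batch: Sequence[TrainingExample], pair: EmbeddingPair,
               vocab: Vocabulary, config: TrainConfig) -> float:
    """Batch objective ``Loss_SGNS + alpha * Loss_PK``."""
    arrays = _batch_arrays(batch, vocab, config)
    loss_sgns, loss_pk, _, _ = _core(
        *arrays, pair.center, pair.context,
        config.context_regularization, want_grads=False)
    return loss_sgns + loss_pk


def gradients(batch: Sequence[TrainingExample], pair: EmbeddingPair,
              vocab: Vocabulary, config: TrainConfig
              ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`total_loss` w.r.t. both matrices.

    Returns dense ``(grad_center, grad_context)`` matrices; rows not touched
    by the batch are zero.
    """
    arrays = _batch_arrays(batch, vocab, config)
    _, _, grad_c, grad_x = _core(
        *arrays, pair.center, pair.context,
        config.context_regularization, want_grads=True)
    return grad_c, grad_x


def _apply_micro(center, context, lr, pc, px, negs, pk_t, pk_j, pk_w,
                 context_reg) -> tuple[float, float]:
    """One in-place SGD step on a micro-batch; returns (sgns, pk) losses
    evaluated at the pre-update parameters.

    Numerically identical to ``params -= lr * gradients(...)`` for the same
    flattened arrays, but without allocating full gradient matrices.
    """
    d = center.shape[1]
    loss_sgns = loss_pk = 0.0
    # gradients are all evaluated at the pre-update parameters, then applied
    if pk_t.size:
        lv, gvt, gvj = _cosine_terms(center[pk_t], center[pk_j], pk_w)
        loss_pk += float(lv.sum())
        if context_reg:
            lu, gut, guj = _cosine_terms(context[pk_t], context[pk_j], pk_w)
            loss_pk += float(lu.sum())
    if pc.size:
        V = center[pc]
        U = context[px]
        UN = context[negs]
        s_pos = np.einsum("nd,nd->n", U, V)
        s_neg = np.einsum("nkd,nd->nk", UN, V)
        loss_sgns = float(-_log_sigmoid(s_pos).sum()
                          - _log_sigmoid(-s_neg).sum())
        g_pos = sigmoid(s_pos) - 1.0
        g_neg = sigmoid(s_neg)
        gV = g_pos[:, None] * U + np.einsum("nk,nkd->nd", g_neg, UN)
        np.add.at(center, pc, -lr * gV)
        np.add.at(context, px, (-lr * g_pos[:, None]) * V)
        np.add.at(context, negs.ravel(),
                  (-lr * g_neg[:, :, None] * V[:, None, :]).reshape(-1, d))
    if pk_t.size:
        np.add.at(center, pk_t, -lr * gvt)
        np.add.at(center, pk_j, -lr * gvj)
        if context_reg:
            np.add.at(context, pk_t, -lr * gut)
            np.add.at(context, pk_j, -lr * guj)
    return loss_sgns, loss_pk


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _epoch_pairs(doc_ids: list[np.ndarray], order: np.ndarray, window: int):
    """Pair arrays for one epoch in document ``order``.

    Returns (centers_by_occ, occ_of_pair, pair_center, pair_ctx) where
    occurrence indices follow the shuffled stream order and pairs are sorted
    by occurrence (stable), so batches of occurrences map to contiguous
    pair slices.
    """
    centers, occs, pcs, pxs = [], [], [], []
    base = 0
    for di in order:
        ids = doc_ids[di]
        L = len(ids)
        if L == 0:
            continue
        centers.append(ids)
        pos = np.arange(L)
        for off in range(1, window + 1):
            if off >= L:
                break
            left, right = pos[:-off], pos[off:]
            # (center at left, ctx at right) and the mirror
            occs.append(base + left); pcs.append(ids[left]); pxs.append(ids[right])
            occs.append(base + right); pcs.append(ids[right]); pxs.append(ids[left])
        base += L
    if not centers:
        raise ValueError("no in-vocabulary tokens in corpus")
    centers_by_occ = np.concatenate(centers)
    if occs:
        occ = np.concatenate(occs)
        pc = np.concatenate(pcs)
        px = np.concatenate(pxs)
        srt = np.argsort(occ, kind="stable")
        occ, pc, px = occ[srt], pc[srt], px[srt]
    else:
        occ = np.zeros(0, dtype=np.int64)
        pc = px = occ
    return centers_by_occ, occ, pc, px


def _sample_negatives(pair_center, pair_ctx, K, table: NegativeSamplingTable,
                      rng: np.random.Generator, max_tries: int = 20):
    """Draw K negatives per pair, resampling collisions with the pair's own
    center or context word."""
    n = len(pair_center)
    negs = table.sample(rng, (n, K))
    for _ in range(max_tries):
        bad = (negs == pair_center[:, None]) | (negs == pair_ctx[:, None])
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        negs[bad] = table.sample(rng, n_bad)
    return negs


def _sample_priors(centers_by_occ: np.ndarray, priors: Sequence[PriorSource],
                   rng: np.random.Generator) -> np.ndarray:
    """One candidate id per occurrence (-1 where no prior knowledge).

    Uniform variates are drawn once per occurrence in stream order, so the
    result is independent of batching.
    """
    n = len(centers_by_occ)
    out = np.full(n, -1, dtype=np.int64)
    if not priors:
        return out
    u = rng.random(n)
    lookup: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for src in priors:
        for t, (ids, _cos, p) in src.candidates.items():
            lookup.setdefault(t, (ids, np.cumsum(p)))
    for t in np.unique(centers_by_occ):
        entry = lookup.get(int(t))
        if entry is None:
            continue
        ids, cdf = entry
        where = np.flatnonzero(centers_by_occ == t)
        j = np.searchsorted(cdf, u[where], side="right")
        out[where] = ids[np.minimum(j, len(ids) - 1)]
    return out


def train(
    docs: Sequence[Sequence[str]],
    vocab: Vocabulary,
    priors: Sequence[PriorSource] = (),
    config: TrainConfig = TrainConfig(),
    table: NegativeSamplingTable | None = None,
) -> tuple[EmbeddingPair, list[dict[str, float]]]:
    """Train the model and return the embeddings plus a per-epoch loss trace.

    Each epoch shuffles documents, then streams center-word occurrences: a
    window pair is emitted for every context position, ``K`` negatives are
    drawn per pair from the unigram table, and one prior word is sampled per
    occurrence.  Updates are applied per batch of ``batch_size``
    occurrences.  Separate RNG streams drive initialization, shuffling,
    negative sampling and prior sampling, so the ``alpha = 0`` run is
    bit-identical to a run with no prior sources at all.

    The trace records per epoch the summed SGNS loss, the weighted prior
    loss ``alpha * Loss_PK``, and their mean per (center, context) pair.
    """
    if table is None:
        table = negative_table(vocab, config.ns_exponent)
    doc_ids = [vocab.ids(doc) for doc in docs]
    n_tokens = int(sum(len(ids) for ids in doc_ids))
    if n_tokens == 0:
        raise ValueError("no in-vocabulary tokens in corpus")

    ss = np.random.SeedSequence(config.seed)
    init_rng, shuffle_rng, neg_rng, prior_rng = (
        np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(4))
    pair = EmbeddingPair.init(len(vocab), config.dim, init_rng)

    gamma_vec = config.tau / vocab.rel_freq
    micro = config.update_every
    total_updates = config.epochs * max(1, -(-n_tokens // micro))
    done = 0
    use_pk = config.alpha > 0 and len(priors) > 0
    empty_i = np.zeros(0, dtype=np.int64)
    empty_f = np.zeros(0)

    trace: list[dict[str, float]] = []
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(doc_ids))
        centers_by_occ, occ, pc_all, px_all = _epoch_pairs(
            doc_ids, order, config.window)
        prior_j = _sample_priors(centers_by_occ, priors, prior_rng)
        n_occ = len(centers_by_occ)
        ep_sgns = ep_pk = 0.0
        for b0 in range(0, n_occ, config.batch_size):
            b1 = min(b0 + config.batch_size, n_occ)
            lo, hi = np.searchsorted(occ, [b0, b1])
            # negatives for the whole batch, then updates per micro-batch
            negs_all = _sample_negatives(pc_all[lo:hi], px_all[lo:hi],
                                         config.negatives, table, neg_rng)
            for m0 in range(b0, b1, micro):
                m1 = min(m0 + micro, b1)
                ml, mh = np.searchsorted(occ, [m0, m1])
                if use_pk:
                    occ_slice = np.arange(m0, m1)
                    covered = occ_slice[prior_j[m0:m1] >= 0]
                    pk_t = centers_by_occ[covered]
                    pk_jj = prior_j[covered]
                    pk_w = config.alpha * gamma_vec[pk_t]
                else:
                    pk_t, pk_jj, pk_w = empty_i, empty_i, empty_f
                lr = config.learning_rate * max(
                    config.min_lr_factor, 1.0 - done / total_updates)
                loss_sgns, loss_pk = _apply_micro(
                    pair.center, pair.context, lr,
                    pc_all[ml:mh], px_all[ml:mh], negs_all[ml - lo : mh - lo],
                    pk_t, pk_jj, pk_w, config.context_regularization)
                done += 1
                ep_sgns += loss_sgns
                ep_pk += loss_pk
            if not np.isfinite(ep_sgns + ep_pk):
                raise RuntimeError(
                    f"non-finite loss at epoch {_epoch}, batch {b0}: "
                    f"sgns={ep_sgns}, pk={ep_pk}")
        n_pairs = len(pc_all)
        trace.append({
            "epoch": float(_epoch),
            "loss_sgns": ep_sgns,
            "loss_pk_weighted": ep_pk,
            "mean_pair_loss": (ep_sgns + ep_pk) / max(1, n_pairs),
        })
    return pair, trace
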