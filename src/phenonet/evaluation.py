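"""Token-score aggregation, cross-entropy loss, and strict/partial NER + RE metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

logger = logging.getLogger(__name__)

#: BIO classes, in canonical column order for probability matrices.
CLASSES = ("B", "I", "O")

#: Floor applied to probabilities inside logs (triggering it is logged).
LOG_EPS = 1e-12

#: Inclusive score threshold for positive NER/RE hits.
SCORE_THRESHOLD = 0.5


@dataclass
class TokenPredictionBatch:
    """True labels and per-class probabilities for the tokens of N sentences.

    ``y`` holds one label string per token per sentence; ``p`` one row per
    token with columns ordered as :data:`CLASSES`.
    """

    y: list[list[str]]
    p: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.y) != len(self.p):
            raise ValueError("y and p must have one entry per sentence")
        for labels, probs in zip(self.y, self.p):
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (len(labels), len(CLASSES)):
                raise ValueError("probability matrix shape mismatch")
            if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("per-token probabilities must sum to 1")
            for lab in labels:
                if lab not in CLASSES:
                    raise ValueError(f"invalid class label {lab!r}")


@dataclass(frozen=True)
class SpanPrediction:
    """A maximal consecutive B/I token run with its max-aggregated score."""

    category: str
    token_start: int  # first token index of the run
    token_end: int  # one past the last token index
    score: float
    start: int = -1  # character offsets, when known
    end: int = -1


@dataclass
class MetricResult:
    mode: str
    cor: int
    par: int
    n_pred: int
    n_gold: int

    @property
    def precision(self) -> float:
        if self.n_pred == 0:
            return 0.0
        credit = self.cor + (0.5 * self.par if self.mode == "partial" else 0.0)
        return credit / self.n_pred

    @property
    def recall(self) -> float:
        if self.n_gold == 0:
            return 0.0
        credit = self.cor + (0.5 * self.par if self.mode == "partial" else 0.0)
        return credit / self.n_gold

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def cross_entropy_loss(batch: TokenPredictionBatch) -> float:
    """Mean negative log-likelihood over sentences.

    ``L = -(1/N) * sum_i sum_t sum_c delta(y_it, c) * log p_itc`` where the
    Kronecker delta picks the probability of the true class.  Probabilities
    are floored at :data:`LOG_EPS` (logged when triggered).
    """
    n = len(batch.y)
    if n == 0:
        raise ValueError("empty batch")
    total = 0.0
    floored = 0
    for labels, probs in zip(batch.y, batch.p):
        probs = np.asarray(probs, dtype=float)
        for t, lab in enumerate(labels):
            p_true = probs[t, CLASSES.index(lab)]
            if p_true < LOG_EPS:
                p_true = LOG_EPS
                floored += 1
            total -= np.log(p_true)
    if floored:
        logger.warning("floored %d zero probabilities at eps=%g", floored, LOG_EPS)
    return total / n


def aggregate_spans(
    token_scores: list[dict[str, float]],
    category: str = "STRAIN",
    threshold: float = SCORE_THRESHOLD,
) -> list[SpanPrediction]:
    """Merge consecutive B/I tokens into span predictions with max aggregation.

    ``token_scores`` holds one dict per token mapping each class in
    :data:`CLASSES` to its probability.  A token belongs to an entity run when
    its argmax class is B or I; the run's score is the maximum of its tokens'
    winning scores, and runs scoring below ``threshold`` (inclusive
    comparison: kept when ``score >= threshold``) are dropped.
    """
    spans: list[SpanPrediction] = []
    run_start = None
    run_score = 0.0
    for i, scores in enumerate(token_scores):
        best = max(CLASSES, key=lambda c: scores.get(c, 0.0))
        if best in ("B", "I"):
            if run_start is None:
                run_start = i
                run_score = scores[best]
            else:
                run_score = max(run_score, scores[best])
        else:
            if run_start is not None:
                spans.append(SpanPrediction(category, run_start, i, run_score))
                run_start = None
    if run_start is not None:
        spans.append(SpanPrediction(category, run_start, len(token_scores), run_score))
    return [s for s in spans if s.score >= threshold]


# ---------------------------------------------------------------------------
# NER span metrics
# ---------------------------------------------------------------------------


def _match_counts(
    pred: list[tuple[int, int]], gold: list[tuple[int, int]]
) -> tuple[int, int]:
    """(COR, PAR) for one sentence under one-to-one matching.

    Exact-extent matches are paired first; the remaining spans are paired by
    a maximum bipartite matching on the overlap relation, so the returned
    counts equal the brute-force optimum over all one-to-one matchings
    (maximal COR, then maximal PAR).
    """
    pred_left = list(range(len(pred)))
    gold_left = list(range(len(gold)))
    cor = 0
    for i in list(pred_left):
        for j in gold_left:
            if pred[i] == gold[j]:
                cor += 1
                pred_left.remove(i)
                gold_left.remove(j)
                break
    if not pred_left or not gold_left:
        return cor, 0
    rows, cols = [], []
    for a, i in enumerate(pred_left):
        for b, j in enumerate(gold_left):
            if pred[i][0] < gold[j][1] and pred[i][1] > gold[j][0]:
                rows.append(a)
                cols.append(b)
    if not rows:
        return cor, 0
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(pred_left), len(gold_left))
    )
    matching = maximum_bipartite_matching(graph, perm_type="column")
    par = int((matching >= 0).sum())
    return cor, par


def ner_metrics(
    pred_spans: list[list[tuple[int, int]]],
    gold_spans: list[list[tuple[int, int]]],
    mode: str = "strict",
) -> MetricResult:
    """Strict or partial precision/recall/F1 over per-sentence span extents.

    Strict credit is exact-extent matches (COR); partial mode additionally
    grants half credit to overlapping non-exact one-to-one matches (PAR).
    Denominators are the total predicted (precision) and gold (recall) span
    counts.
    """
    if mode not in ("strict", "partial"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(pred_spans) != len(gold_spans):
        raise ValueError("prediction and gold sentence counts differ")
    cor = par = n_pred = n_gold = 0
    for pred, gold in zip(pred_spans, gold_spans):
        c, p = _match_counts(list(pred), list(gold))
        cor += c
        par += p
        n_pred += len(pred)
        n_gold += len(gold)
    return MetricResult(mode=mode, cor=cor, par=par, n_pred=n_pred, n_gold=n_gold)


def re_metrics(
    predicted, true, threshold: float = SCORE_THRESHOLD
) -> MetricResult:
    """Binary precision/recall/F1 for relation extraction.

    ``predicted`` may be binary labels or scores (thresholded at
    ``>= threshold``); the positive class is "relation present".
    """
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=int)
    if predicted.shape != true.shape:
        raise ValueError("length mismatch between predictions and labels")
    pos = predicted >= threshold
    tp = int(np.sum(pos & (true == 1)))
    n_pred = int(pos.sum())
    n_gold = int((true == 1).sum())
    return MetricResult(mode="strict", cor=tp, par=0, n_pred=n_pred, n_gold=n_gold)
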