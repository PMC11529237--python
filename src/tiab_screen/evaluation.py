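"""Performance measurement: AUC, bootstrap confidence intervals, and the
growing-training-set (learning-curve) protocol.

The AUC here is the Mann-Whitney pair statistic — the probability that a
randomly chosen include is ranked above a randomly chosen exclude, ties
counting one half — computed via midranks so it is exact and O(n log n).

The learning curve shuffles the labeled corpus once, allocates documents to
``n_batches`` batches with include counts balanced to within one, and at
step k trains on batches 1..k (so training sets are nested) while testing on
the remainder.  The complete chain — singleton removal, elastic-net
selection, grid-search tuning, prediction — is re-run from scratch at every
step on the training part only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .classifiers import ClassifierSpec, predict_inclusion_probability, tune_and_fit
from .corpus_io import Corpus, Label
from .features import (
    LeakageGuard,
    build_dtm,
    drop_rare_terms,
    elastic_net_select,
    labels_to_binary,
)
from .text_processing import TextPipelineConfig, process_corpus

logger = logging.getLogger(__name__)

__all__ = [
    "AUCResult",
    "LearningCurvePoint",
    "auc",
    "bootstrap_auc_ci",
    "allocate_batches",
    "learning_curve",
]


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    level: float
    seed: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("percentile interval must bracket the point estimate")


def _as_binary(truth: Sequence[Label] | np.ndarray) -> np.ndarray:
    if isinstance(truth, np.ndarray) and truth.dtype != object:
        return truth.astype(np.int64)
    return labels_to_binary(list(truth))


def auc(probabilities: Sequence[float], truth: Sequence[Label] | np.ndarray) -> float:
    """Mann-Whitney AUC: P(score(include) > score(exclude)) + 0.5 P(tie)."""
    y = _as_binary(truth)
    p = np.asarray(probabilities, dtype=np.float64)
    if p.shape[0] != y.shape[0]:
        raise ValueError("probabilities and truth differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes in the truth vector")
    ranks = rankdata(p)  # midranks handle ties exactly
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_auc_ci(
    probabilities: Sequence[float],
    truth: Sequence[Label] | np.ndarray,
    n_bootstrap: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> AUCResult:
    """Percentile bootstrap CI for the AUC, resampling documents.

    Replicates that lose one class entirely are redrawn.
    """
    if n_bootstrap < 100:
        raise ValueError("n_bootstrap must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    y = _as_binary(truth)
    p = np.asarray(probabilities, dtype=np.float64)
    point = auc(p, y)
    rng = np.random.default_rng(seed)
    n = y.size
    replicates = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
        replicates[b] = auc(p[idx], y[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(replicates, [alpha, 1.0 - alpha])
    return AUCResult(
        auc=point,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        n_bootstrap=n_bootstrap,
        level=level,
        seed=seed,
    )


def allocate_batches(
    labels: Sequence[Label] | np.ndarray, n_batches: int, seed: int
) -> list[np.ndarray]:
    """Shuffle once and allocate document positions to batches.

    Stratified: within each class, documents are dealt round-robin over the
    shuffled order, so per-batch include counts differ by at most one
    (largest-remainder behaviour) and batch sizes differ by at most one.
    """
    y = _as_binary(labels)
    rng = np.random.default_rng(seed)
    batches: list[list[int]] = [[] for _ in range(n_batches)]
    for cls, reverse in ((1, False), (0, True)):
        members = np.flatnonzero(y == cls)
        rng.shuffle(members)
        for i, pos in enumerate(members):
            # deal the two classes in opposite batch orders so the +1
            # remainders land on different batches and sizes stay balanced
            b = (n_batches - 1 - i % n_batches) if reverse else (i % n_batches)
            batches[b].append(int(pos))
    return [np.sort(np.array(b, dtype=np.int64)) for b in batches]


@dataclass(frozen=True)
class LearningCurvePoint:
    fraction: float
    n_train: int
    n_includes_train: int
    method: str
    result: AUCResult


def run_chain(
    train_bags,
    train_labels: np.ndarray,
    test_bags,
    spec: ClassifierSpec,
    *,
    mixing_weight: float = 0.5,
    min_total_count: int = 2,
    guard: LeakageGuard | None = None,
    selection_kwargs: dict | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Full train-only chain: DTM -> singleton filter -> elastic net ->
    tune_and_fit -> project test -> predict.  Returns (test probabilities,
    selected vocabulary)."""
    dtm_train = drop_rare_terms(build_dtm(train_bags), min_total_count)
    selection = elastic_net_select(
        dtm_train,
        train_labels,
        mixing_weight=mixing_weight,
        seed=spec.seed,
        **(selection_kwargs or {}),
    )
    if guard is not None:
        guard.register_selection(dtm_train.doc_ids)
    if not selection.kept_terms:
        # fall back to the post-singleton vocabulary when the net shrinks
        # everything away (tiny corpora); logged, never silent
        logger.warning("elastic net kept no terms; using post-singleton vocabulary")
        kept = dtm_train.vocabulary
    else:
        kept = selection.kept_terms
    model = tune_and_fit(spec, dtm_train.select_columns(kept), train_labels)
    dtm_test = build_dtm(test_bags, vocabulary=kept)
    return predict_inclusion_probability(model, dtm_test), kept


def learning_curve(
    corpus: Corpus,
    specs: Sequence[ClassifierSpec],
    text_config: TextPipelineConfig | None = None,
    n_batches: int = 10,
    seed: int = 0,
    *,
    n_bootstrap: int = 2000,
    level: float = 0.95,
    mixing_weight: float = 0.5,
    selection_kwargs: dict | None = None,
    guard: LeakageGuard | None = None,
) -> list[LearningCurvePoint]:
    """Growing-training-set evaluation over fractions 1/n_batches .. (n-1)/n."""
    labels = corpus.labels()
    if any(lab is Label.UNSCREENED for lab in labels):
        raise ValueError("learning_curve requires a fully labeled corpus")
    y = labels_to_binary(labels)
    n_includes = int(y.sum())
    if n_includes < n_batches:
        raise ValueError(
            f"need at least {n_batches} includes to place one per batch; "
            f"corpus has {n_includes} includes in {len(corpus)} documents"
        )
    text_config = text_config or TextPipelineConfig()
    bags = process_corpus(corpus.records, text_config)
    batches = allocate_batches(y, n_batches, seed)
    guard = guard if guard is not None else LeakageGuard()

    points: list[LearningCurvePoint] = []
    train_pos: np.ndarray = np.array([], dtype=np.int64)
    for k in range(1, n_batches):
        train_pos = np.sort(np.concatenate([train_pos, batches[k - 1]]))
        test_pos = np.sort(np.concatenate(batches[k:]))
        train_bags = [bags[i] for i in train_pos]
        test_bags = [bags[i] for i in test_pos]
        y_train, y_test = y[train_pos], y[test_pos]
        for spec in specs:
            probs, _ = run_chain(
                train_bags,
                y_train,
                test_bags,
                spec,
                mixing_weight=mixing_weight,
                guard=guard,
                selection_kwargs=selection_kwargs,
            )
            guard.check_test_partition(corpus.ids[i] for i in test_pos)
            result = bootstrap_auc_ci(
                probs, y_test, n_bootstrap=n_bootstrap, level=level, seed=seed + k
            )
            points.append(
                LearningCurvePoint(
                    fraction=k / n_batches,
                    n_train=len(train_pos),
                    n_includes_train=int(y_train.sum()),
                    method=spec.method,
                    result=result,
                )
            )
            logger.info(
                "learning curve %s step %d/%d: n_train=%d AUC=%.4f",
                spec.method, k, n_batches, len(train_pos), result.auc,
            )
    return points
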