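"""Cross-validated cutoff selection and the screening decision rule.

Missing a relevant citation at title-abstract stage cannot be repaired
later, so the cutoff is chosen to be conservative: within each
cross-validation fold the candidate cutoff is the *smallest* predicted
inclusion probability among that fold's human-included citations (so
applying it back to the fold captures every include), and the K fold
cutoffs are then aggregated — by minimum (default, safest), median, or
mean.  Feature selection is re-run inside every fold on the K-1 training
folds only, extending the train-only rule to the nested split.

The decision rule is inclusive: a citation is forwarded to full-text
screening when its probability is *at least* the cutoff.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import ClassifierSpec
from .corpus_io import Label
from .features import LeakageGuard, labels_to_binary

logger = logging.getLogger(__name__)

__all__ = [
    "AGGREGATION_RULES",
    "CutoffResult",
    "ScreeningOutcome",
    "fold_cutoff_from_probs",
    "cv_fold_cutoffs",
    "aggregate_cutoffs",
    "select_cutoff",
    "screen",
    "confusion_rates",
]

AGGREGATION_RULES = ("min", "median", "mean")


@dataclass(frozen=True)
class CutoffResult:
    fold_cutoffs: tuple[float, ...]
    n_folds: int
    aggregation_rule: str
    cutoff: float
    n_folds_skipped: int = 0

    def __post_init__(self) -> None:
        expected = aggregate_cutoffs(self.fold_cutoffs, self.aggregation_rule)
        if abs(expected - self.cutoff) > 1e-12:
            raise ValueError("cutoff must equal the aggregation rule applied to fold_cutoffs")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "fold_cutoffs": list(self.fold_cutoffs),
                    "n_folds": self.n_folds,
                    "aggregation_rule": self.aggregation_rule,
                    "cutoff": self.cutoff,
                    "n_folds_skipped": self.n_folds_skipped,
                },
                indent=2,
            )
            + "\n"
        )


def fold_cutoff_from_probs(
    probabilities: Sequence[float], is_gold_include: Sequence[bool]
) -> float:
    """Smallest predicted inclusion probability among a fold's gold includes."""
    include_probs = [p for p, inc in zip(probabilities, is_gold_include) if inc]
    if not include_probs:
        raise ValueError("fold contains no gold include")
    return float(min(include_probs))


def cv_fold_cutoffs(
    bags: Sequence,
    labels: Sequence[Label] | np.ndarray,
    spec: ClassifierSpec,
    n_folds: int = 5,
    seed: int = 0,
    *,
    mixing_weight: float = 0.5,
    min_total_count: int = 2,
    guard: LeakageGuard | None = None,
    selection_kwargs: dict | None = None,
) -> tuple[list[float], int]:
    """Per-fold smallest to-be-included probability over gold includes.

    *bags* are the TRAINING documents' token bags.  Per fold: re-run feature
    selection and model fitting on the other K-1 folds, predict the held
    fold, and record the minimum probability among its gold includes.  Folds
    without a gold include are skipped with a warning.  Returns
    (fold_cutoffs, n_folds_skipped).
    """
    from .evaluation import run_chain  # local import to avoid a module cycle

    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = labels if isinstance(labels, np.ndarray) else labels_to_binary(labels)
    if int(y.sum()) == 0:
        raise ValueError("no gold includes in the training data; cannot define a cutoff")
    if len(y) != len(bags):
        raise ValueError("labels length does not match number of documents")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cutoffs: list[float] = []
    skipped = 0
    for fold_no, (fit_idx, held_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        held_includes = held_idx[y[held_idx] == 1]
        if held_includes.size == 0:
            logger.warning("fold %d holds no gold include; skipped", fold_no)
            skipped += 1
            continue
        probs, _ = run_chain(
            [bags[i] for i in fit_idx],
            y[fit_idx],
            [bags[i] for i in held_idx],
            spec,
            mixing_weight=mixing_weight,
            min_total_count=min_total_count,
            guard=guard,
            selection_kwargs=selection_kwargs,
        )
        cutoffs.append(fold_cutoff_from_probs(probs, y[held_idx] == 1))
        logger.info("fold %d cutoff: %.4f", fold_no, cutoffs[-1])
    return cutoffs, skipped


def aggregate_cutoffs(fold_cutoffs: Sequence[float], rule: str) -> float:
    """Aggregate K fold cutoffs with min (safest), median, or mean."""
    if rule not in AGGREGATION_RULES:
        raise ValueError(f"rule must be one of {AGGREGATION_RULES}, got {rule!r}")
    values = list(fold_cutoffs)
    if not values:
        raise ValueError("fold_cutoffs must not be empty")
    if rule == "min":
        return float(min(values))
    if rule == "median":
        return float(statistics.median(values))
    return float(statistics.fmean(values))


def select_cutoff(
    bags: Sequence,
    labels: Sequence[Label] | np.ndarray,
    spec: ClassifierSpec,
    n_folds: int = 5,
    rule: str = "min",
    seed: int = 0,
    **chain_kwargs,
) -> CutoffResult:
    """Run the full cross-validated cutoff procedure on the training set."""
    cutoffs, skipped = cv_fold_cutoffs(
        bags, labels, spec, n_folds=n_folds, seed=seed, **chain_kwargs
    )
    return CutoffResult(
        fold_cutoffs=tuple(cutoffs),
        n_folds=n_folds,
        aggregation_rule=rule,
        cutoff=aggregate_cutoffs(cutoffs, rule),
        n_folds_skipped=skipped,
    )


def screen(probabilities: Sequence[float], cutoff: float) -> np.ndarray:
    """Decision per document: include iff probability >= cutoff (inclusive)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    p = np.asarray(probabilities, dtype=np.float64)
    decisions = np.empty(p.shape, dtype=object)
    flagged = p >= cutoff
    decisions[flagged] = Label.INCLUDE
    decisions[~flagged] = Label.EXCLUDE
    return decisions


@dataclass(frozen=True)
class ScreeningOutcome:
    """Confusion counts and rates of a screening decision vector."""

    tp: int
    fp: int
    tn: int
    fn: int
    true_positive_rate: float | None
    true_negative_rate: float | None

    @property
    def n_flagged(self) -> int:
        return self.tp + self.fp

    @property
    def decisions_total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_rates(
    decisions: Sequence[Label] | np.ndarray, truth: Sequence[Label] | np.ndarray
) -> ScreeningOutcome:
    """Confusion counts, true-positive and true-negative rates.

    With single-class truth the undefined rate is reported as ``None``
    rather than fabricated.
    """
    d = np.asarray([x is Label.INCLUDE or x == Label.INCLUDE for x in decisions])
    t = np.asarray([x is Label.INCLUDE or x == Label.INCLUDE for x in truth])
    if d.shape != t.shape:
        raise ValueError("decisions and truth differ in length")
    if any(x is Label.UNSCREENED for x in truth):
        raise ValueError("truth must be fully labeled")
    tp = int(np.sum(d & t))
    fp = int(np.sum(d & ~t))
    tn = int(np.sum(~d & ~t))
    fn = int(np.sum(~d & t))
    tpr = tp / (tp + fn) if (tp + fn) else None
    tnr = tn / (tn + fp) if (tn + fp) else None
    return ScreeningOutcome(
        tp=tp, fp=fp, tn=tn, fn=fn,
        true_positive_rate=tpr, true_negative_rate=tnr,
    )
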