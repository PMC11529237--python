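"""Document-term matrix assembly and train-only variable selection.

Two-stage selection in the p > n regime: (1) drop terms whose corpus-wide
total count is 1 — a single appearance cannot contribute a second,
discriminating occurrence; (2) fit an l1+l2-penalized (elastic-net) logistic
regression with the penalty strength chosen by internal cross-validation and
keep the terms with nonzero coefficients.

Selection must only ever see training rows.  The :class:`LeakageGuard`
records the id set each selection was computed on and raises if any of those
ids later shows up in a test partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .corpus_io import Label
from .text_processing import TokenBag

logger = logging.getLogger(__name__)

__all__ = [
    "DocumentTermMatrix",
    "SelectionResult",
    "LeakageGuard",
    "LeakageError",
    "build_dtm",
    "drop_rare_terms",
    "elastic_net_select",
    "labels_to_binary",
]


@dataclass(frozen=True)
class DocumentTermMatrix:
    """docs x stems count matrix (rows follow doc_ids, columns vocabulary)."""

    doc_ids: tuple[str, ...]
    vocabulary: tuple[str, ...]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise ValueError("duplicate doc_ids in document-term matrix")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("duplicate vocabulary entries")
        if self.counts.shape != (len(self.doc_ids), len(self.vocabulary)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.doc_ids)} docs x {len(self.vocabulary)} terms"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n(self) -> int:
        """Number of documents (rows)."""
        return len(self.doc_ids)

    @property
    def p(self) -> int:
        """Number of terms (columns); typically p > n before selection."""
        return len(self.vocabulary)

    def select_columns(self, terms: Sequence[str]) -> "DocumentTermMatrix":
        """Project onto *terms* (each must exist in the vocabulary)."""
        index = {t: j for j, t in enumerate(self.vocabulary)}
        missing = [t for t in terms if t not in index]
        if missing:
            raise KeyError(f"terms not in vocabulary: {missing[:5]}")
        cols = [index[t] for t in terms]
        return DocumentTermMatrix(
            doc_ids=self.doc_ids,
            vocabulary=tuple(terms),
            counts=sp.csr_matrix(self.counts[:, cols]),
        )

    def select_rows(self, row_idx: Sequence[int]) -> "DocumentTermMatrix":
        return DocumentTermMatrix(
            doc_ids=tuple(self.doc_ids[i] for i in row_idx),
            vocabulary=self.vocabulary,
            counts=sp.csr_matrix(self.counts[row_idx, :]),
        )

    def toarray(self) -> np.ndarray:
        return self.counts.toarray()

    def save(self, prefix: str | Path) -> None:
        """Persist as MTX plus sidecar text files for ids and vocabulary."""
        prefix = Path(prefix)
        mmwrite(str(prefix.with_suffix(".mtx")), self.counts)
        prefix.with_suffix(".docs.txt").write_text("\n".join(self.doc_ids) + "\n")
        prefix.with_suffix(".vocab.txt").write_text("\n".join(self.vocabulary) + "\n")

    @classmethod
    def load(cls, prefix: str | Path) -> "DocumentTermMatrix":
        prefix = Path(prefix)
        counts = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
        doc_ids = tuple(prefix.with_suffix(".docs.txt").read_text().split())
        vocab = tuple(prefix.with_suffix(".vocab.txt").read_text().split())
        return cls(doc_ids=doc_ids, vocabulary=vocab, counts=counts)


def build_dtm(
    bags: Sequence[TokenBag], vocabulary: Sequence[str] | None = None
) -> DocumentTermMatrix:
    """Tabulate token bags into a count matrix.

    With an explicit *vocabulary* (e.g. the training vocabulary), bag terms
    outside it are dropped and absent terms yield zero — the projection used
    for test documents.  Without one, the vocabulary is the sorted union of
    bag keys.
    """
    doc_ids = tuple(b.doc_id for b in bags)
    if len(set(doc_ids)) != len(doc_ids):
        raise ValueError("duplicate doc_ids among token bags")
    if vocabulary is None:
        vocab = tuple(sorted(set().union(*(b.counts.keys() for b in bags)) if bags else set()))
    else:
        vocab = tuple(vocabulary)
    index = {t: j for j, t in enumerate(vocab)}
    rows, cols, data = [], [], []
    for i, bag in enumerate(bags):
        for term, count in bag.counts.items():
            j = index.get(term)
            if j is not None:
                rows.append(i)
                cols.append(j)
                data.append(count)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(doc_ids), len(vocab)), dtype=np.int64
    )
    return DocumentTermMatrix(doc_ids=doc_ids, vocabulary=vocab, counts=counts)


def drop_rare_terms(dtm: DocumentTermMatrix, min_total_count: int = 2) -> DocumentTermMatrix:
    """Keep columns with corpus-wide total count >= *min_total_count*.

    The default of 2 removes exactly the terms that appeared only once.
    """
    if min_total_count < 1:
        raise ValueError("min_total_count must be >= 1")
    totals = np.asarray(dtm.counts.sum(axis=0)).ravel()
    keep = [t for t, tot in zip(dtm.vocabulary, totals) if tot >= min_total_count]
    logger.info("singleton filter: %d -> %d terms", dtm.p, len(keep))
    return dtm.select_columns(keep)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the elastic-net stage.

    ``penalty_strength`` is the regularization strength lambda (inverse of
    scikit-learn's C); larger means more shrinkage.
    """

    kept_terms: tuple[str, ...]
    n_singletons_removed: int
    mixing_weight: float
    penalty_strength: float
    nonzero_coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.kept_terms) != set(self.nonzero_coefficients):
            raise ValueError("kept_terms must equal keys of nonzero_coefficients")

    def save(self, path: str | Path) -> None:
        lines = ["term,coefficient"]
        lines += [f"{t},{self.nonzero_coefficients[t]:.10g}" for t in self.kept_terms]
        Path(path).write_text("\n".join(lines) + "\n")


def labels_to_binary(labels: Sequence[Label]) -> np.ndarray:
    """Map include/exclude labels to 1/0; unscreened labels are an error."""
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab is Label.INCLUDE:
            out[i] = 1
        elif lab is Label.EXCLUDE:
            out[i] = 0
        else:
            raise ValueError(f"unscreened label at position {i}")
    return out


def elastic_net_select(
    dtm: DocumentTermMatrix,
    labels: Sequence[Label] | np.ndarray,
    mixing_weight: float = 0.5,
    seed: int = 0,
    *,
    n_penalties: int = 10,
    internal_folds: int = 5,
    standardize: bool = True,
    max_iter: int = 2000,
    penalty_override: float | None = None,
) -> SelectionResult:
    """Elastic-net logistic regression on TRAINING rows only.

    The penalty strength is chosen over a log-spaced path by stratified
    internal cross-validation maximizing held-out log-likelihood; terms with
    nonzero coefficients at the chosen penalty are the selected features.
    Columns are scaled to unit second moment before penalization by default
    (the glmnet convention; coefficients are reported on the count scale);
    ``standardize=False`` penalizes raw counts instead.
    """
    if not 0.0 <= mixing_weight <= 1.0:
        raise ValueError("mixing_weight must be in [0, 1]")
    if dtm.p == 0:
        raise ValueError("empty vocabulary: nothing to select from")
    y = labels if isinstance(labels, np.ndarray) else labels_to_binary(labels)
    if len(y) != dtm.n:
        raise ValueError("labels length does not match number of documents")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present for selection")

    X = dtm.counts.astype(np.float64)
    col_mean = np.asarray(X.mean(axis=0)).ravel()
    col_meansq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    col_var = np.maximum(col_meansq - col_mean**2, 0.0)
    # zero-variance columns are collinear with the intercept: their
    # coefficients are unidentifiable and are fixed at zero up front
    identifiable = np.flatnonzero(col_var > 0)
    X = sp.csr_matrix(X[:, identifiable])
    if identifiable.size == 0:
        raise ValueError("all columns are constant; nothing selectable")
    if standardize:
        # scale columns to unit std without centering, keeping the matrix
        # sparse — the intercept absorbs the mean shift
        scale = np.sqrt(col_var[identifiable])
        X = sp.csr_matrix(X.multiply(1.0 / scale))

    if penalty_override is not None:
        # fixed penalty strength lambda (no internal CV); C = 1/lambda
        if penalty_override <= 0:
            raise ValueError("penalty_override must be positive")
        model = LogisticRegression(
            C=1.0 / penalty_override,
            solver="saga",
            l1_ratio=mixing_weight,
            max_iter=max_iter,
            random_state=seed,
            tol=1e-3,
        )
        model.fit(X, y)
        chosen_penalty = float(penalty_override)
    else:
        n_minority = int(np.min(np.bincount(y)))
        cv = min(internal_folds, n_minority)
        if cv < 2:
            raise ValueError(
                f"minority class has {n_minority} member(s); at least 2 are "
                "needed for internal cross-validation"
            )
        model = LogisticRegressionCV(
            Cs=n_penalties,
            cv=cv,
            solver="saga",
            l1_ratios=(mixing_weight,),
            scoring="neg_log_loss",
            max_iter=max_iter,
            random_state=seed,
            n_jobs=1,
            tol=1e-3,
            use_legacy_attributes=False,
        )
        model.fit(X, y)
        chosen_penalty = 1.0 / float(np.atleast_1d(model.C_)[0])
    fitted = model.coef_.ravel()
    if standardize:
        fitted = fitted / scale
    coefs = np.zeros(dtm.p)
    coefs[identifiable] = fitted
    nonzero = {
        term: float(c) for term, c in zip(dtm.vocabulary, coefs) if c != 0.0
    }
    result = SelectionResult(
        kept_terms=tuple(t for t in dtm.vocabulary if t in nonzero),
        n_singletons_removed=0,
        mixing_weight=mixing_weight,
        penalty_strength=chosen_penalty,
        nonzero_coefficients=nonzero,
    )
    logger.info(
        "elastic net kept %d/%d terms (C=%.4g, l1_ratio=%.2f)",
        len(result.kept_terms), dtm.p, result.penalty_strength, mixing_weight,
    )
    return result


class LeakageError(RuntimeError):
    """A row used for feature selection reappeared in a test partition."""


class LeakageGuard:
    """Records which ids each feature selection saw and polices test splits."""

    def __init__(self) -> None:
        self._selection_ids: list[frozenset[str]] = []

    def register_selection(self, ids: Iterable[str]) -> None:
        self._selection_ids.append(frozenset(ids))

    @property
    def selection_id_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(self._selection_ids)

    def check_test_partition(self, test_ids: Iterable[str]) -> None:
        """Raise :class:`LeakageError` if any selection overlapped *test_ids*."""
        test = frozenset(test_ids)
        for i, sel in enumerate(self._selection_ids):
            overlap = sel & test
            if overlap:
                raise LeakageError(
                    f"selection #{i} used {len(overlap)} ids that are in the "
                    f"test partition (e.g. {sorted(overlap)[:3]}); variable "
                    "selection must only see training rows"
                )
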