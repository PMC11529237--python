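"""Reading, validating and writing citation export tables.

Screening tools export one CSV row per citation (title, abstract and, for
screened rows, a human include/exclude decision).  Export schemas vary
between tools, so column names and label spellings are supplied as a
:class:`Dialect` instead of being hard-coded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Label",
    "CitationRecord",
    "Corpus",
    "Dialect",
    "read_citations",
    "write_citations",
    "filter_screenable",
    "split_train_test",
    "write_decisions",
]


class Label(str, Enum):
    """Screening state of a citation."""

    INCLUDE = "include"
    EXCLUDE = "exclude"
    UNSCREENED = "unscreened"


#: default spellings accepted for each label (all matched case-insensitively)
DEFAULT_LABEL_SYNONYMS: dict[str, Label] = {
    "include": Label.INCLUDE,
    "included": Label.INCLUDE,
    "1": Label.INCLUDE,
    "true": Label.INCLUDE,
    "yes": Label.INCLUDE,
    "exclude": Label.EXCLUDE,
    "excluded": Label.EXCLUDE,
    "0": Label.EXCLUDE,
    "false": Label.EXCLUDE,
    "no": Label.EXCLUDE,
    "unscreened": Label.UNSCREENED,
    "maybe": Label.UNSCREENED,
    "": Label.UNSCREENED,
}


@dataclass(frozen=True)
class CitationRecord:
    """One citation: identifier, title, abstract and screening label."""

    id: str
    title: str
    abstract: str
    label: Label = Label.UNSCREENED
    screenable: bool = True

    def __post_init__(self) -> None:
        if not self.abstract.strip() and self.screenable:
            object.__setattr__(self, "screenable", False)

    @property
    def text(self) -> str:
        """Title and abstract joined into the single text field used downstream."""
        return f"{self.title} {self.abstract}".strip()


@dataclass(frozen=True)
class Corpus:
    """Ordered collection of citation records with stable order.

    All downstream splits reference ids/positions of this order; the source
    file is never re-read.
    """

    records: tuple[CitationRecord, ...]
    provenance: str = "<memory>"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
        if dupes:
            raise ValueError(f"duplicate citation ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> CitationRecord:
        return self.records[i]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def labels(self) -> tuple[Label, ...]:
        return tuple(r.label for r in self.records)

    def subset(self, keep_ids: Iterable[str]) -> "Corpus":
        keep = set(keep_ids)
        unknown = keep - set(self.ids)
        if unknown:
            raise KeyError(f"ids not in corpus: {sorted(unknown)}")
        return Corpus(
            records=tuple(r for r in self.records if r.id in keep),
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping and label-synonym table for one export flavour."""

    name: str = "default"
    id_column: str = "id"
    title_column: str = "title"
    abstract_column: str = "abstract"
    label_column: str | None = "label"
    #: optional boolean column marking records that must not be screened
    unscreenable_column: str | None = None
    label_synonyms: Mapping[str, Label] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_SYNONYMS)
    )
    delimiter: str = ","


def _parse_label(raw: object, synonyms: Mapping[str, Label], row: int) -> Label:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return Label.UNSCREENED
    key = str(raw).strip().lower()
    if key not in synonyms:
        raise ValueError(f"unparseable label value {raw!r} in row {row}")
    return synonyms[key]


def read_citations(path: str | Path, dialect: Dialect | None = None) -> Corpus:
    """Read a citation CSV into a :class:`Corpus`.

    Raises :class:`KeyError` naming any mapped column absent from the file,
    :class:`ValueError` for duplicate ids or unparseable label strings.  A
    missing/unmapped label column yields all-unscreened records.
    """
    dialect = dialect or Dialect()
    path = Path(path)
    frame = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)

    for role, col in (("id", dialect.id_column), ("title", dialect.title_column),
                      ("abstract", dialect.abstract_column)):
        if col not in frame.columns:
            raise KeyError(f"mapped {role} column {col!r} not found in {path}")

    has_labels = dialect.label_column is not None and dialect.label_column in frame.columns
    synonyms = {k.lower(): v for k, v in dialect.label_synonyms.items()}

    records = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=1):
        row_d = dict(zip(frame.columns, row))
        label = (
            _parse_label(row_d[dialect.label_column], synonyms, row_no)
            if has_labels
            else Label.UNSCREENED
        )
        screenable = True
        if dialect.unscreenable_column and dialect.unscreenable_column in frame.columns:
            screenable = str(row_d[dialect.unscreenable_column]).strip().lower() not in (
                "1", "true", "yes",
            )
        records.append(
            CitationRecord(
                id=str(row_d[dialect.id_column]).strip(),
                title=str(row_d[dialect.title_column]),
                abstract=str(row_d[dialect.abstract_column]),
                label=label,
                screenable=screenable,
            )
        )
    corpus = Corpus(records=tuple(records), provenance=f"{path}#{dialect.name}")
    logger.info("read %d citations from %s", len(corpus), path)
    return corpus


def write_citations(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the default dialect (round-trips with read_citations)."""
    frame = pd.DataFrame(
        {
            "id": [r.id for r in corpus],
            "title": [r.title for r in corpus],
            "abstract": [r.abstract for r in corpus],
            "label": [r.label.value for r in corpus],
        }
    )
    frame.to_csv(path, index=False)


def filter_screenable(corpus: Corpus) -> Corpus:
    """Drop records without usable abstract text; order preserved, idempotent."""
    kept = tuple(r for r in corpus if r.screenable)
    removed = len(corpus) - len(kept)
    if removed:
        logger.info("removed %d unscreenable citations (no abstract)", removed)
    return Corpus(records=kept, provenance=corpus.provenance)


def split_train_test(corpus: Corpus, train_ids: Iterable[str]) -> tuple[Corpus, Corpus]:
    """Partition a corpus into (train, test) by id.

    Every training record must carry a human include/exclude decision;
    unknown ids and unscreened training labels are errors.
    """
    train_set = set(train_ids)
    unknown = train_set - set(corpus.ids)
    if unknown:
        raise KeyError(f"train ids not in corpus: {sorted(unknown)}")
    train_records, test_records = [], []
    for rec in corpus:
        if rec.id in train_set:
            if rec.label is Label.UNSCREENED:
                raise ValueError(f"training citation {rec.id!r} has no screening label")
            train_records.append(rec)
        else:
            test_records.append(rec)
    return (
        Corpus(records=tuple(train_records), provenance=corpus.provenance),
        Corpus(records=tuple(test_records), provenance=corpus.provenance),
    )


def write_decisions(
    path: str | Path,
    ids: Sequence[str],
    probabilities: Sequence[float],
    decisions: Sequence[Label],
) -> None:
    """Write the per-citation decision table (id, probability, decision)."""
    pd.DataFrame(
        {
            "id": list(ids),
            "probability": list(probabilities),
            "decision": [d.value for d in decisions],
        }
    ).to_csv(path, index=False)


def write_run_metadata(path: str | Path, metadata: Mapping[str, object]) -> None:
    Path(path).write_text(json.dumps(metadata, indent=2, default=str) + "\n")
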