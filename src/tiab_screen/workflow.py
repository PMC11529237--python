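"""Human-in-the-loop workflow accounting.

In the traditional workflow two reviewers read every abstract.  In the
semi-automated workflow the training set is still double-read, the test set
is read once by a human while the model screens it, and a second human reads
only the abstracts where machine and human disagree.  Reads therefore total
``2*n_train + n_test + n_disagreement`` against ``2*n_total`` traditionally,
and the saving in minutes is the read difference times the per-abstract
reading time (default one minute).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .corpus_io import Label

__all__ = ["WorkloadReport", "disagreements", "workload_report"]


def disagreements(
    ml_decisions: dict[str, Label], human_decisions: dict[str, Label]
) -> tuple[int, list[str]]:
    """Ids where machine and human decisions differ, plus their count."""
    if set(ml_decisions) != set(human_decisions):
        only_ml = sorted(set(ml_decisions) - set(human_decisions))[:3]
        only_h = sorted(set(human_decisions) - set(ml_decisions))[:3]
        raise ValueError(
            f"decision id sets differ (only ML: {only_ml}, only human: {only_h})"
        )
    ids = [i for i in ml_decisions if ml_decisions[i] != human_decisions[i]]
    return len(ids), ids


@dataclass(frozen=True)
class WorkloadReport:
    """Abstract-read counts and minutes saved, traditional vs semi-automated."""

    n_total: int
    n_train: int
    n_test: int
    n_disagreement: int
    minutes_per_abstract: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_total", "n_train", "n_test", "n_disagreement"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_total != self.n_train + self.n_test:
            raise ValueError(
                f"n_total ({self.n_total}) != n_train ({self.n_train}) + "
                f"n_test ({self.n_test})"
            )
        if self.n_disagreement > self.n_test:
            raise ValueError(
                f"n_disagreement ({self.n_disagreement}) exceeds n_test ({self.n_test})"
            )
        if self.minutes_per_abstract <= 0:
            raise ValueError("minutes_per_abstract must be positive")

    @property
    def reads_traditional(self) -> int:
        return 2 * self.n_total

    @property
    def reads_ml(self) -> int:
        return 2 * self.n_train + self.n_test + self.n_disagreement

    @property
    def reads_saved(self) -> int:
        return self.reads_traditional - self.reads_ml

    @property
    def minutes_saved(self) -> float:
        return self.reads_saved * self.minutes_per_abstract

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_disagreement": self.n_disagreement,
            "reads_traditional": self.reads_traditional,
            "reads_ml": self.reads_ml,
            "reads_saved": self.reads_saved,
            "minutes_per_abstract": self.minutes_per_abstract,
            "minutes_saved": self.minutes_saved,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def summary(self) -> str:
        return (
            f"Traditional double screening: {self.reads_traditional} abstract reads\n"
            f"Semi-automated workflow:      {self.reads_ml} abstract reads\n"
            f"  ({self.n_train} citations double-read for training, "
            f"{self.n_test} single-read, {self.n_disagreement} disagreement re-reads)\n"
            f"Reads saved: {self.reads_saved} "
            f"({self.minutes_saved:g} minutes at "
            f"{self.minutes_per_abstract:g} min/abstract)"
        )


def workload_report(
    n_total: int,
    n_train: int,
    n_test: int,
    n_disagreement: int,
    minutes_per_abstract: float = 1.0,
) -> WorkloadReport:
    """Build a :class:`WorkloadReport`; inconsistent counts raise ValueError."""
    return WorkloadReport(
        n_total=n_total,
        n_train=n_train,
        n_test=n_test,
        n_disagreement=n_disagreement,
        minutes_per_abstract=minutes_per_abstract,
    )
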