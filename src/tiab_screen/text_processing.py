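"""Title+abstract text -> counted bags of filtered word stems.

Stage order is fixed: lowercase -> tokenize/strip -> lemmatize -> stem ->
dictionary filter.  Lemmatization runs before stemming so that inflection
families merge at the lemma and then collapse to one stem, which shrinks the
vocabulary in the p > n regime.  The dictionary filter removes stems of fill
words and any stem with no counterpart in a reference English wordlist
(which kills web artifacts such as ``https`` and, with a curated list,
uninformative proper nouns).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

from ._lemmatizer import default_lemmatize
from ._porter import porter_stem
from .corpus_io import CitationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TextPipelineConfig",
    "TokenBag",
    "normalize",
    "lemmatize_tokens",
    "stem_tokens",
    "dictionary_filter",
    "process_document",
    "process_corpus",
    "load_wordlist",
    "default_stopwords",
    "default_wordlist",
]

# tokens are maximal runs of letters; hyphens/slashes/digits/punctuation separate
_TOKEN_RE = re.compile(r"[a-z]+")

Lemmatizer = Callable[[str], str]
Stemmer = Callable[[str], str]


def load_wordlist(path: str | Path) -> frozenset[str]:
    """Load a one-word-per-line plain-text wordlist, lowercased."""
    words = {
        line.strip().lower()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(words)


def _packaged_list(name: str) -> frozenset[str]:
    text = resources.files("tiab_screen").joinpath("data", name).read_text("utf-8")
    return frozenset(
        w.strip().lower() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


def default_stopwords() -> frozenset[str]:
    """Packaged English fill-word list (replaceable via config)."""
    return _packaged_list("stopwords_en.txt")


def default_wordlist() -> frozenset[str]:
    """Packaged starter English reference wordlist (replaceable via config)."""
    return _packaged_list("wordlist_en.txt")


@dataclass(frozen=True)
class TextPipelineConfig:
    """Configuration of the text chain; serialized with every run."""

    lowercase: bool = True
    lemmatize: bool = True
    stem: bool = True
    stopword_list: frozenset[str] = field(default_factory=default_stopwords)
    reference_wordlist: frozenset[str] = field(default_factory=default_wordlist)
    min_token_length: int = 2
    lemmatizer: Lemmatizer = default_lemmatize
    stemmer: Stemmer = porter_stem

    def __post_init__(self) -> None:
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")
        object.__setattr__(
            self, "stopword_list", frozenset(w.lower() for w in self.stopword_list)
        )
        object.__setattr__(
            self,
            "reference_wordlist",
            frozenset(w.lower() for w in self.reference_wordlist),
        )

    # wordlist and stopwords are compared stem-to-stem, so both sets are
    # pushed through the active lemma/stem chain once, lazily, per config
    def _reduce(self, word: str) -> str:
        w = self.lemmatizer(word) if self.lemmatize else word
        return self.stemmer(w) if self.stem else w

    @property
    def stopword_stems(self) -> frozenset[str]:
        cached = getattr(self, "_stopword_stems", None)
        if cached is None:
            cached = frozenset(self._reduce(w) for w in self.stopword_list)
            object.__setattr__(self, "_stopword_stems", cached)
        return cached

    @property
    def wordlist_stems(self) -> frozenset[str]:
        cached = getattr(self, "_wordlist_stems", None)
        if cached is None:
            cached = frozenset(self._reduce(w) for w in self.reference_wordlist)
            object.__setattr__(self, "_wordlist_stems", cached)
        return cached

    def to_metadata(self) -> dict:
        return {
            "lowercase": self.lowercase,
            "lemmatize": self.lemmatize,
            "stem": self.stem,
            "n_stopwords": len(self.stopword_list),
            "n_reference_words": len(self.reference_wordlist),
            "min_token_length": self.min_token_length,
            "lemmatizer": getattr(self.lemmatizer, "__name__", repr(self.lemmatizer)),
            "stemmer": getattr(self.stemmer, "__name__", repr(self.stemmer)),
        }


@dataclass(frozen=True)
class TokenBag:
    """Stem counts for one document; all counts >= 1, keys lowercase letters."""

    doc_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for stem, n in self.counts.items():
            if n < 1:
                raise ValueError(f"count for {stem!r} must be >= 1, got {n}")
            if not stem.isalpha() or stem != stem.lower():
                raise ValueError(f"invalid stem key {stem!r}")

    def total(self) -> int:
        return sum(self.counts.values())


def normalize(raw: str, min_token_length: int = 1) -> list[str]:
    """Lowercase and tokenize: only alphabetic runs survive.

    Digits, punctuation, hyphens, slashes and whitespace all act as token
    separators and are dropped.
    """
    if not raw:
        return []
    return [t for t in _TOKEN_RE.findall(raw.lower()) if len(t) >= min_token_length]


def lemmatize_tokens(tokens: Sequence[str], lemmatizer: Lemmatizer = default_lemmatize) -> list[str]:
    """Map each token to its lemma; unknown words pass through unchanged."""
    return [lemmatizer(t) for t in tokens]


def stem_tokens(tokens: Sequence[str], stemmer: Stemmer = porter_stem) -> list[str]:
    """Map each token to its Porter stem."""
    return [stemmer(t) for t in tokens]


def dictionary_filter(stems: Sequence[str], config: TextPipelineConfig) -> list[str]:
    """Drop fill-word stems and stems absent from the reference wordlist."""
    if not config.reference_wordlist:
        raise ValueError("reference_wordlist must not be empty")
    stop = config.stopword_stems
    vocab = config.wordlist_stems
    return [s for s in stems if s not in stop and s in vocab]


def process_text(text: str, config: TextPipelineConfig) -> list[str]:
    tokens = normalize(text if config.lowercase else text, config.min_token_length)
    if config.lemmatize:
        tokens = lemmatize_tokens(tokens, config.lemmatizer)
    if config.stem:
        tokens = stem_tokens(tokens, config.stemmer)
    return dictionary_filter(tokens, config)


def process_document(record: CitationRecord, config: TextPipelineConfig) -> TokenBag:
    """Run the full chain on one citation's title+abstract.

    Deterministic for a fixed config; a document with no surviving token
    yields an empty bag (logged).
    """
    surviving = process_text(record.text, config)
    counts: dict[str, int] = {}
    for stem in surviving:
        counts[stem] = counts.get(stem, 0) + 1
    if not counts:
        logger.warning("document %s has no tokens after filtering", record.id)
    return TokenBag(doc_id=record.id, counts=counts)


def process_corpus(records: Iterable[CitationRecord], config: TextPipelineConfig) -> list[TokenBag]:
    return [process_document(r, config) for r in records]
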