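"""Synthetic labeled citation corpora for end-to-end testing.

Real screening exports cannot be redistributed, so this module generates
corpora with the statistical structure the pipeline assumes: heavy class
imbalance (a few percent includes), short title+abstract documents, a p > n
vocabulary, and a sparse set of "signal" terms enriched in included
documents.  The generative model is a two-distribution multinomial mixture:
background term probabilities follow a Zipf-like decay, and in include
documents the signal terms' probabilities are multiplied by
``exp(signal_log_odds)`` and renormalized.

Generated words are pronounceable consonant-vowel syllable strings, and the
generator emits a matching reference wordlist so the dictionary filter is
exercised rather than bypassed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_io import CitationRecord, Corpus, Label
from .features import DocumentTermMatrix, build_dtm
from .text_processing import TokenBag

__all__ = [
    "SyntheticCorpusConfig",
    "generate_corpus",
    "generate_vocabulary",
    "write_corpus_artifacts",
    "worked_example_corpus",
    "worked_example_config",
]

_CONSONANTS = "bdfgklmnprtv"
_VOWELS_SYL = "aeiou"
# words the default lemmatizer special-cases; never emit them
_FORBIDDEN = {"data"}


def generate_vocabulary(size: int) -> list[str]:
    """Deterministic pronounceable three-syllable words (CV CV CV)."""
    from ._porter import porter_stem

    syllables = [c + v for c, v in itertools.product(_CONSONANTS, _VOWELS_SYL)]
    words = []
    for combo in itertools.product(syllables, repeat=3):
        word = "".join(combo)
        if word in _FORBIDDEN:
            continue
        # only emit words whose stem is a Porter fixed point, so that
        # re-stemming pipeline output is the identity on synthetic corpora
        stem = porter_stem(word)
        if porter_stem(stem) != stem:
            continue
        words.append(word)
        if len(words) == size:
            return words
    raise ValueError(f"cannot build a vocabulary of size {size}")


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    n_docs: int = 2000
    inclusion_rate: float = 0.05
    vocab_size_background: int = 500
    n_signal_terms: int = 30
    signal_log_odds: float = 1.5
    doc_length_mean: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1 or self.vocab_size_background < 1:
            raise ValueError("all sizes must be positive")
        if not 0.0 < self.inclusion_rate < 1.0:
            raise ValueError("inclusion_rate must be in (0, 1)")
        if self.n_signal_terms > self.vocab_size_background:
            raise ValueError("n_signal_terms cannot exceed vocab_size_background")
        if self.signal_log_odds < 0:
            raise ValueError("signal_log_odds must be >= 0")
        if self.doc_length_mean <= 0:
            raise ValueError("doc_length_mean must be positive")


def generate_corpus(config: SyntheticCorpusConfig) -> tuple[Corpus, dict]:
    """Draw a labeled corpus; returns (corpus, generator truth record).

    Labels are independent Bernoulli(inclusion_rate); document lengths are
    Poisson(doc_length_mean) floored at 4 tokens so every abstract is
    non-empty.  The truth record carries the config, the gold labels, the
    signal terms and the full vocabulary (which doubles as the matching
    reference wordlist).
    """
    rng = np.random.default_rng(config.seed)
    vocab = generate_vocabulary(config.vocab_size_background)
    signal_terms = vocab[: config.n_signal_terms]

    ranks = np.arange(1, config.vocab_size_background + 1, dtype=np.float64)
    background = 1.0 / (ranks + 2.0)  # Zipf-like decay with a flat head
    background /= background.sum()

    boosted = background.copy()
    boosted[: config.n_signal_terms] *= np.exp(config.signal_log_odds)
    boosted /= boosted.sum()

    labels = rng.random(config.n_docs) < config.inclusion_rate
    records = []
    for i in range(config.n_docs):
        length = max(4, int(rng.poisson(config.doc_length_mean)))
        probs = boosted if labels[i] else background
        tokens = rng.choice(vocab, size=length, p=probs)
        title = " ".join(tokens[:3]).capitalize()
        abstract = " ".join(tokens[3:]).capitalize() + "."
        records.append(
            CitationRecord(
                id=f"syn{i:05d}",
                title=title,
                abstract=abstract,
                label=Label.INCLUDE if labels[i] else Label.EXCLUDE,
            )
        )
    corpus = Corpus(records=tuple(records), provenance=f"synthetic(seed={config.seed})")
    truth = {
        "config": {
            "n_docs": config.n_docs,
            "inclusion_rate": config.inclusion_rate,
            "vocab_size_background": config.vocab_size_background,
            "n_signal_terms": config.n_signal_terms,
            "signal_log_odds": config.signal_log_odds,
            "doc_length_mean": config.doc_length_mean,
            "seed": config.seed,
        },
        "labels": {r.id: r.label.value for r in records},
        "signal_terms": signal_terms,
        "wordlist": vocab,
    }
    return corpus, truth


def write_corpus_artifacts(corpus: Corpus, truth: dict, out_dir: str | Path) -> None:
    """Write citations.csv, truth.json and wordlist.txt for a generated corpus."""
    from .corpus_io import write_citations

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_citations(corpus, out / "citations.csv")
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    (out / "wordlist.txt").write_text("\n".join(truth["wordlist"]) + "\n")


# ---------------------------------------------------------------------------
# Worked example: 8 documents hand-traced through the full text chain
# (lowercase -> tokenize -> lemmatize -> Porter stem -> dictionary filter).
# The expected stem counts below were derived by hand and are frozen; they
# serve as an exact regression oracle for the text pipeline.
# ---------------------------------------------------------------------------

_EXAMPLE_WORDLIST = frozenset(
    {
        "analyze", "analysis", "program", "infection", "trial", "random",
        "screen", "patient", "outcome", "study", "risk",
    }
)
_EXAMPLE_STOPWORDS = frozenset({"and", "the", "of", "a", "in", "was", "were", "this", "for"})

_EXAMPLE_DOCS = [
    ("d1", "Analyzing programs", "Analyze programs and screening patients.", Label.INCLUDE),
    ("d2", "Randomized trial", "A randomized trial of infection outcomes in patients.", Label.EXCLUDE),
    ("d3", "Study of studies", "The study was studying study outcomes.", Label.EXCLUDE),
    ("d4", "Infection risk", "Infections and infection risks in trials.", Label.INCLUDE),
    ("d5", "1234 !!", "???", Label.EXCLUDE),
    ("d6", "The and of", "And the of the a in.", Label.EXCLUDE),
    ("d7", "Screening https links", "Visit https://example.org for RCTs 2023.", Label.EXCLUDE),
    ("d8", "Patient risk program", "Programming risk analyses for patients and programmers.", Label.EXCLUDE),
]

# hand-traced surviving stem counts per document
_EXAMPLE_BAGS = {
    "d1": {"analyz": 2, "program": 2, "screen": 1, "patient": 1},
    "d2": {"random": 2, "trial": 2, "infect": 1, "outcom": 1, "patient": 1},
    "d3": {"studi": 5, "outcom": 1},
    "d4": {"infect": 3, "risk": 2, "trial": 1},
    "d5": {},
    "d6": {},
    "d7": {"screen": 1},  # https/link/visit/example/org/rct all fail the dictionary
    "d8": {"patient": 2, "risk": 2, "program": 2, "analysi": 1},
    # note d8: "programmers" lemmatizes to "programmer", Porter-stems to
    # "programm" (canonical behaviour), which matches no wordlist stem and
    # is therefore filtered out
}


def worked_example_config():
    """Text config matching the hand trace (default lemmatizer + Porter)."""
    from .text_processing import TextPipelineConfig

    return TextPipelineConfig(
        stopword_list=_EXAMPLE_STOPWORDS,
        reference_wordlist=_EXAMPLE_WORDLIST,
    )


def worked_example_corpus() -> tuple[Corpus, DocumentTermMatrix]:
    """Fixed 8-document corpus plus its hand-computed document-term matrix."""
    records = tuple(
        CitationRecord(id=i, title=t, abstract=a, label=lab)
        for i, t, a, lab in _EXAMPLE_DOCS
    )
    corpus = Corpus(records=records, provenance="worked-example")
    bags = [TokenBag(doc_id=i, counts=dict(_EXAMPLE_BAGS[i])) for i, *_ in _EXAMPLE_DOCS]
    expected = build_dtm(bags)
    return corpus, expected
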