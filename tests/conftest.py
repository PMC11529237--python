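import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

from tiab_screen.classifiers import ClassifierSpec
from tiab_screen.corpus_io import CitationRecord, Corpus, Label
from tiab_screen.synthetic_corpus import SyntheticCorpusConfig, generate_corpus
from tiab_screen.text_processing import TextPipelineConfig, process_corpus


@pytest.fixture(autouse=True)
def _quiet_solver_warnings():
    # saga on tiny toy problems may stop at max_iter; irrelevant to the assertions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@pytest.fixture(scope="session")
def small_synthetic():
    """400-doc strong-signal corpus with its matching wordlist and bags."""
    config = SyntheticCorpusConfig(
        n_docs=400,
        inclusion_rate=0.15,
        vocab_size_background=150,
        n_signal_terms=15,
        signal_log_odds=2.0,
        doc_length_mean=40.0,
        seed=7,
    )
    corpus, truth = generate_corpus(config)
    text_config = TextPipelineConfig(
        reference_wordlist=frozenset(truth["wordlist"])
    )
    bags = process_corpus(corpus.records, text_config)
    y = np.array([1 if r.label is Label.INCLUDE else 0 for r in corpus])
    return {"corpus": corpus, "truth": truth, "bags": bags, "y": y,
            "text_config": text_config}


@pytest.fixture(scope="session")
def fast_rf_spec():
    """Single-point random-forest grid for quick chain runs."""
    return ClassifierSpec(
        method="random_forest",
        hyperparameter_grid={"n_estimators": [100], "max_features_factor": [1.0]},
        seed=3,
    )


@pytest.fixture
def tiny_corpus():
    return Corpus(
        records=(
            CitationRecord("a", "Trial of screening", "A randomized trial.", Label.INCLUDE),
            CitationRecord("b", "Cohort study", "A cohort study of patients.", Label.EXCLUDE),
            CitationRecord("c", "No abstract here", "", Label.EXCLUDE),
        )
    )
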