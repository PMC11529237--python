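import numpy as np
import pytest

from tiab_screen.corpus_io import Label
from tiab_screen.thresholding import (
    CutoffResult,
    aggregate_cutoffs,
    confusion_rates,
    cv_fold_cutoffs,
    fold_cutoff_from_probs,
    screen,
    select_cutoff,
)


class TestFoldCutoff:
    def test_minimum_over_gold_includes(self):
        probs = [0.3, 0.7, 0.1, 0.9]
        gold = [True, True, False, False]
        assert fold_cutoff_from_probs(probs, gold) == 0.3

    def test_oracle_classifier_yields_one(self):
        # a classifier emitting the gold label as probability
        gold = [True, False, True, False]
        probs = [1.0 if g else 0.0 for g in gold]
        assert fold_cutoff_from_probs(probs, gold) == 1.0

    def test_no_includes_rejected(self):
        with pytest.raises(ValueError):
            fold_cutoff_from_probs([0.5], [False])


class TestAggregate:
    @pytest.mark.parametrize(
        "rule,expected", [("min", 0.2), ("mean", 0.5), ("median", 0.4)]
    )
    def test_rules(self, rule, expected):
        assert aggregate_cutoffs([0.2, 0.4, 0.9], rule) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cutoffs([], "min")

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cutoffs([0.5], "max")

    def test_min_never_exceeds_mean_or_median(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cuts = rng.random(int(rng.integers(1, 9))).tolist()
            assert aggregate_cutoffs(cuts, "min") <= aggregate_cutoffs(cuts, "mean")
            assert aggregate_cutoffs(cuts, "min") <= aggregate_cutoffs(cuts, "median")


class TestCutoffResult:
    def test_cutoff_must_match_rule(self):
        with pytest.raises(ValueError):
            CutoffResult(
                fold_cutoffs=(0.2, 0.4), n_folds=2,
                aggregation_rule="min", cutoff=0.4,
            )

    def test_round_trip_json(self, tmp_path):
        import json

        r = CutoffResult(
            fold_cutoffs=(0.2, 0.4, 0.6), n_folds=3,
            aggregation_rule="median", cutoff=0.4,
        )
        r.save(tmp_path / "c.json")
        data = json.loads((tmp_path / "c.json").read_text())
        assert data["cutoff"] == 0.4
        assert data["fold_cutoffs"] == [0.2, 0.4, 0.6]


class TestScreen:
    def test_probability_equal_to_cutoff_is_included(self):
        decisions = screen([0.219, 0.218], 0.219)
        assert decisions[0] == Label.INCLUDE
        assert decisions[1] == Label.EXCLUDE

    def test_cutoff_zero_includes_everything(self):
        assert all(d is Label.INCLUDE for d in screen([0.0, 0.5, 1.0], 0.0))

    def test_cutoff_above_max_includes_nothing(self):
        assert all(d is Label.EXCLUDE for d in screen([0.1, 0.8], 0.81))

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        probs = rng.random(200)
        flagged = [
            sum(d is Label.INCLUDE for d in screen(probs, c))
            for c in np.linspace(1, 0, 11)
        ]
        assert flagged == sorted(flagged)


class TestConfusionRates:
    def test_worked_illustration_arithmetic(self):
        # 133 gold includes all captured; 1491 flagged of 2672 total
        truth = [Label.INCLUDE] * 133 + [Label.EXCLUDE] * 2539
        decisions = (
            [Label.INCLUDE] * 133
            + [Label.INCLUDE] * (1491 - 133)
            + [Label.EXCLUDE] * (2539 - (1491 - 133))
        )
        out = confusion_rates(decisions, truth)
        assert out.true_positive_rate == 1.0
        assert out.tn == 1181
        assert round(out.true_negative_rate, 3) == 0.465

    def test_perfect_decisions(self):
        truth = [Label.INCLUDE, Label.EXCLUDE, Label.EXCLUDE]
        out = confusion_rates(truth, truth)
        assert out.true_positive_rate == 1.0
        assert out.true_negative_rate == 1.0

    def test_nothing_flagged(self):
        truth = [Label.INCLUDE, Label.EXCLUDE]
        out = confusion_rates([Label.EXCLUDE, Label.EXCLUDE], truth)
        assert out.true_positive_rate == 0.0
        assert out.true_negative_rate == 1.0

    def test_single_class_truth_flags_undefined_rate(self):
        truth = [Label.EXCLUDE, Label.EXCLUDE]
        out = confusion_rates([Label.EXCLUDE, Label.INCLUDE], truth)
        assert out.true_positive_rate is None
        assert out.true_negative_rate == 0.5

    def test_confusion_identities(self):
        rng = np.random.default_rng(3)
        truth = [Label.INCLUDE if b else Label.EXCLUDE for b in rng.random(100) < 0.3]
        decisions = [Label.INCLUDE if b else Label.EXCLUDE for b in rng.random(100) < 0.5]
        out = confusion_rates(decisions, truth)
        gold_inc = sum(t is Label.INCLUDE for t in truth)
        assert out.tp + out.fn == gold_inc
        assert out.tn + out.fp == 100 - gold_inc
        assert out.n_flagged == sum(d is Label.INCLUDE for d in decisions)


class TestCvFoldCutoffs:
    @pytest.fixture(scope="class")
    def fold_run(self, small_synthetic, fast_rf_spec):
        bags = small_synthetic["bags"]
        y = small_synthetic["y"]
        cutoffs, skipped = cv_fold_cutoffs(
            bags, y, fast_rf_spec, n_folds=3, seed=0,
            selection_kwargs={"n_penalties": 4, "internal_folds": 3},
        )
        return cutoffs, skipped

    def test_one_cutoff_per_fold(self, fold_run):
        cutoffs, skipped = fold_run
        assert len(cutoffs) == 3
        assert skipped == 0

    def test_cutoffs_are_probabilities(self, fold_run):
        cutoffs, _ = fold_run
        assert all(0.0 <= c <= 1.0 for c in cutoffs)

    def test_zero_includes_rejected(self, small_synthetic, fast_rf_spec):
        bags = small_synthetic["bags"][:20]
        with pytest.raises(ValueError, match="include"):
            cv_fold_cutoffs(bags, np.zeros(20, dtype=int), fast_rf_spec, seed=0)

    def test_construction_property_each_fold_captures_all_includes(
        self, small_synthetic, fast_rf_spec
    ):
        # applying each fold's own cutoff back to that fold flags every
        # gold include, by definition of the fold cutoff
        from sklearn.model_selection import StratifiedKFold

        from tiab_screen.evaluation import run_chain

        bags = small_synthetic["bags"]
        y = small_synthetic["y"]
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=0)
        for fit_idx, held_idx in skf.split(np.zeros(len(y)), y):
            probs, _ = run_chain(
                [bags[i] for i in fit_idx], y[fit_idx],
                [bags[i] for i in held_idx], fast_rf_spec,
                selection_kwargs={"n_penalties": 4, "internal_folds": 3},
            )
            cut = fold_cutoff_from_probs(probs, y[held_idx] == 1)
            decisions = screen(probs, cut)
            out = confusion_rates(decisions, [
                Label.INCLUDE if v else Label.EXCLUDE for v in y[held_idx] == 1
            ])
            assert out.true_positive_rate == 1.0


def test_min_rule_dominates_on_held_out_data(small_synthetic, fast_rf_spec):
    # min-aggregated cutoff is the most conservative: held-out tpr under
    # "min" is >= tpr under "mean" and "median"
    from tiab_screen.evaluation import run_chain

    bags = small_synthetic["bags"]
    y = small_synthetic["y"]
    rng = np.random.default_rng(5)
    perm = rng.permutation(len(y))
    tr, te = perm[:280], perm[280:]
    sel_kwargs = {"n_penalties": 4, "internal_folds": 3}

    cutoffs, _ = cv_fold_cutoffs(
        [bags[i] for i in tr], y[tr], fast_rf_spec, n_folds=3, seed=2,
        selection_kwargs=sel_kwargs,
    )
    probs, _ = run_chain(
        [bags[i] for i in tr], y[tr], [bags[i] for i in te], fast_rf_spec,
        selection_kwargs=sel_kwargs,
    )
    truth = [Label.INCLUDE if v else Label.EXCLUDE for v in y[te] == 1]
    tprs = {}
    for rule in ("min", "mean", "median"):
        cut = aggregate_cutoffs(cutoffs, rule)
        tprs[rule] = confusion_rates(screen(probs, cut), truth).true_positive_rate
    assert tprs["min"] >= tprs["mean"]
    assert tprs["min"] >= tprs["median"]


def test_select_cutoff_end_to_end(small_synthetic, fast_rf_spec):
    bags = small_synthetic["bags"][:200]
    y = small_synthetic["y"][:200]
    result = select_cutoff(
        bags, y, fast_rf_spec, n_folds=2, rule="min", seed=1,
        selection_kwargs={"n_penalties": 3, "internal_folds": 2},
    )
    assert result.aggregation_rule == "min"
    assert result.cutoff == min(result.fold_cutoffs)
    assert 0.0 <= result.cutoff <= 1.0
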