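import math
import random

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from picoscreen.errors import AccountingError
from picoscreen.evaluation import (
    ChiSquareResult,
    ConfusionSummary,
    chi_square_2xk,
    compare_models,
    compute_metrics,
    confusion_from_decisions,
    exclusion_reason_concordance,
    load_gold,
    percent_string,
)
from picoscreen.screening import ScreeningDecision


def _dec(rid, verdict, reason=None, stage="title_abstract"):
    return ScreeningDecision(rid, stage, verdict, exclusion_reason=reason)


class TestConfusion:
    def test_perfect_agreement(self):
        gold = {f"i{i}": "include" for i in range(10)}
        gold.update({f"e{i}": "exclude" for i in range(90)})
        decisions = [_dec(r, v, "r" if v == "exclude" else None) for r, v in gold.items()]
        c = confusion_from_decisions(decisions, gold)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 90, 0, 0)

    def test_single_false_negative(self):
        gold = {"a": "include", "b": "exclude"}
        decisions = [_dec("a", "exclude", "r"), _dec("b", "exclude", "r")]
        c = confusion_from_decisions(decisions, gold)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 1, 0, 1)

    def test_against_brute_force_recount(self):
        rng = random.Random(17)
        gold = {f"r{i}": rng.choice(["include", "exclude"]) for i in range(200)}
        decisions = [
            _dec(r, v, None if v == "include" else "why")
            for r, v in ((r, rng.choice(["include", "exclude"])) for r in gold)
        ]
        c = confusion_from_decisions(decisions, gold)
        # independent pairwise recount
        tp = sum(1 for d in decisions if gold[d.record_id] == "include" and d.decision == "include")
        tn = sum(1 for d in decisions if gold[d.record_id] == "exclude" and d.decision == "exclude")
        fp = sum(1 for d in decisions if gold[d.record_id] == "exclude" and d.decision == "include")
        fn = sum(1 for d in decisions if gold[d.record_id] == "include" and d.decision == "exclude")
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.total == 200

    def test_missing_gold_id(self):
        with pytest.raises(AccountingError) as exc:
            confusion_from_decisions([_dec("ghost", "include")], {"a": "include"})
        assert exc.value.record_ids == ["ghost"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionSummary(tp=-1, tn=0, fp=0, fn=0)


class TestMetrics:
    @pytest.mark.parametrize("wrong,expected", [(7, "99.38"), (12, "98.94"), (13, "98.85")])
    def test_accuracy_from_misclassification_counts(self, wrong, expected):
        c = ConfusionSummary(tp=113, tn=1133 - 113 - wrong, fp=wrong, fn=0)
        metrics = compute_metrics(c)
        assert metrics.as_percent_strings()["accuracy"] == expected

    def test_perfect_is_100(self):
        metrics = compute_metrics(ConfusionSummary(10, 90, 0, 0))
        assert metrics.as_percent_strings() == {
            "accuracy": "100.00", "precision": "100.00", "recall": "100.00",
        }

    def test_hand_arithmetic(self):
        metrics = compute_metrics(ConfusionSummary(tp=8, fp=2, fn=2, tn=88))
        pct = metrics.as_percent_strings()
        assert pct == {"accuracy": "96.00", "precision": "80.00", "recall": "80.00"}

    def test_undefined_denominators_flagged(self):
        metrics = compute_metrics(ConfusionSummary(tp=0, tn=5, fp=0, fn=0))
        assert metrics.precision is None and metrics.recall is None
        assert metrics.accuracy == 1.0

    def test_empty_total_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionSummary(0, 0, 0, 0))

    def test_accuracy_one_iff_no_errors(self):
        assert compute_metrics(ConfusionSummary(5, 5, 0, 0)).accuracy == 1.0
        assert compute_metrics(ConfusionSummary(5, 5, 1, 0)).accuracy < 1.0

    def test_recall_monotone_in_fn(self):
        # tp+fn fixed at 10
        recalls = [compute_metrics(ConfusionSummary(10 - fn, 50, 0, fn)).recall
                   for fn in range(10)]
        assert recalls == sorted(recalls, reverse=True)

    def test_percent_half_up(self):
        assert percent_string(1, 16) == "6.25"
        assert percent_string(1005, 100000) == "1.01"  # 1.005 rounds up, not half-even
        assert percent_string(1126, 1133) == "99.38"


class TestConcordance:
    def test_hand_count(self):
        gold_reasons = {"a": "reason x", "b": "reason x", "c": "reason y", "d": "reason z"}
        decisions = [
            _dec("a", "exclude", "reason x"),
            _dec("b", "exclude", "Reason   X"),  # matches after normalization
            _dec("c", "exclude", "reason y"),
            _dec("d", "exclude", "wrong reason"),
        ]
        result = exclusion_reason_concordance(decisions, gold_reasons)
        assert (result.matched, result.compared) == (3, 4)
        assert result.rate == 0.75

    def test_all_match(self):
        decisions = [_dec("a", "exclude", "r")]
        assert exclusion_reason_concordance(decisions, {"a": "r"}).rate == 1.0

    def test_no_co_excluded_flagged(self):
        result = exclusion_reason_concordance([_dec("a", "include")], {"b": "r"})
        assert result.rate is None and result.compared == 0

    def test_tool_exclude_gold_include_not_compared(self):
        result = exclusion_reason_concordance([_dec("a", "exclude", "r")], {})
        assert result.compared == 0


class TestChiSquare:
    def test_identical_columns_zero(self):
        result = chi_square_2xk([[10, 10], [5, 5]])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_hand_pearson(self):
        result = chi_square_2xk([[20, 5], [10, 15]])
        assert result.statistic == pytest.approx(25 / 3, abs=1e-9)  # 8.3333…
        assert result.df == 1

    def test_2x3_vs_independent_formula(self):
        table = [[12.0, 30.0, 18.0], [8.0, 10.0, 22.0]]
        # textbook oracle: direct sum over expected counts
        row = [sum(r) for r in table]
        col = [table[0][j] + table[1][j] for j in range(3)]
        grand = sum(row)
        expected_stat = sum(
            (table[i][j] - row[i] * col[j] / grand) ** 2 / (row[i] * col[j] / grand)
            for i in range(2)
            for j in range(3)
        )
        result = chi_square_2xk(table)
        assert result.statistic == pytest.approx(expected_stat, abs=1e-9)
        assert result.df == 2
        # cross-check against scipy's uncorrected Pearson test
        stat, p, df, _ = chi2_contingency(np.array(table), correction=False)
        assert result.statistic == pytest.approx(stat, abs=1e-9)
        assert result.p_value == pytest.approx(p, abs=1e-12)
        assert result.df == df

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="zero marginal"):
            chi_square_2xk([[0, 0], [5, 5]])

    def test_bad_shape(self):
        with pytest.raises(ValueError):
            chi_square_2xk([[1, 2, 3]])
        with pytest.raises(ValueError):
            chi_square_2xk([[1], [2]])


def _decision_set(gold, flip_ids=(), reason="r"):
    decisions = []
    for rid, verdict in gold.items():
        v = verdict
        if rid in flip_ids:
            v = "include" if verdict == "exclude" else "exclude"
        decisions.append(_dec(rid, v, reason if v == "exclude" else None))
    return decisions


class TestCompareModels:
    GOLD = {f"i{i}": "include" for i in range(20)} | {f"e{i}": "exclude" for i in range(80)}
    REASONS = {f"e{i}": "r" for i in range(80)}

    def test_identical_sets_zero_chi(self):
        sets = {name: _decision_set(self.GOLD, flip_ids={"i0"}) for name in "abc"}
        report = compare_models(sets, self.GOLD, self.REASONS)
        metric_strings = {
            name: b.metrics.as_percent_strings() for name, b in report.backends.items()
        }
        assert len(set(map(str, metric_strings.values()))) == 1
        assert report.recall_chi2.statistic == pytest.approx(0.0, abs=1e-12)

    def test_perfect_sets_degenerate_chi(self):
        sets = {name: _decision_set(self.GOLD) for name in "ab"}
        report = compare_models(sets, self.GOLD, self.REASONS)
        assert report.recall_chi2.degenerate
        assert report.recall_chi2 == ChiSquareResult(0.0, 1, 1.0, degenerate=True)

    def test_recall_chi_matches_manual_table(self):
        sets = {
            "a": _decision_set(self.GOLD, flip_ids={"i0", "i1"}),  # fn=2
            "b": _decision_set(self.GOLD, flip_ids={"i0"}),  # fn=1
            "c": _decision_set(self.GOLD),  # fn=0
        }
        report = compare_models(sets, self.GOLD, self.REASONS)
        manual = chi_square_2xk([[18, 19, 20], [2, 1, 0]])
        assert report.recall_chi2.statistic == pytest.approx(manual.statistic, abs=1e-12)
        assert report.recall_chi2.p_value == pytest.approx(manual.p_value, abs=1e-12)

    def test_coverage_mismatch(self):
        full = _decision_set(self.GOLD)
        partial = full[:-1]
        with pytest.raises(AccountingError):
            compare_models({"a": full, "b": partial}, self.GOLD, self.REASONS)

    def test_report_serializes(self):
        sets = {"a": _decision_set(self.GOLD, flip_ids={"e0"})}
        sets["b"] = _decision_set(self.GOLD)
        report = compare_models(sets, self.GOLD, self.REASONS)
        payload = report.to_dict()
        assert set(payload["backends"]) == {"a", "b"}
        assert "Accuracy" in report.render_text()


class TestGoldIO:
    def test_load_gold(self, tmp_path):
        path = tmp_path / "gold.csv"
        path.write_text(
            "record_id,decision,reason\na,include,\nb,exclude,some reason\n",
            encoding="utf-8",
        )
        gold, reasons = load_gold(path)
        assert gold == {"a": "include", "b": "exclude"}
        assert reasons == {"b": "some reason"}


def test_noise_recovery_small():
    """Mock noise ε produces accuracy within 3 binomial SEs of 1−ε (small n here;
    the full n=1000 check lives in the acceptance suite)."""
    import picoscreen.screening as scr
    from picoscreen.criteria_prompt import default_criteria
    from picoscreen.llm_backend import BackendParams, MockBackend
    from picoscreen.synthetic_corpus import CorpusProfile, generate_corpus

    criteria, taxonomy = default_criteria()
    records, labels = generate_corpus(CorpusProfile(n_records=400, prevalence=0.1, seed=5))
    tasks = scr.default_task_suite(criteria, taxonomy, "title_abstract")
    eps = 0.05
    decisions = scr.screen_records(
        records, tasks, MockBackend(noise=eps, seed=9), BackendParams(), criteria
    )
    gold = {l.record_id: l.decision for l in labels}
    c = confusion_from_decisions(decisions, gold)
    accuracy = (c.tp + c.tn) / c.total
    se = math.sqrt(eps * (1 - eps) / 400)
    assert abs(accuracy - (1 - eps)) <= 3 * se
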