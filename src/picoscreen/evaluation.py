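"""Scoring against a gold standard: confusion metrics, exclusion-reason
concordance, Pearson chi-square model comparison, and report rendering.

The positive class is gold "include". Percentages are rendered half-up at
two decimals. Undefined denominators are flagged (``None``), never silently
reported as zero.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal, localcontext
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import chi2 as _chi2_dist

from .errors import AccountingError
from .screening import ScreeningDecision


@dataclass
class ConfusionSummary:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    accuracy: float
    precision: float | None  # None = undefined (tp+fp == 0)
    recall: float | None  # None = undefined (tp+fn == 0)

    def as_percent_strings(self) -> dict[str, str | None]:
        return {
            "accuracy": format_fraction_percent(self.accuracy),
            "precision": None if self.precision is None else format_fraction_percent(self.precision),
            "recall": None if self.recall is None else format_fraction_percent(self.recall),
        }


@dataclass
class ConcordanceResult:
    matched: int
    compared: int
    rate: float | None  # None = undefined (no co-excluded records)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    degenerate: bool = False  # zero-marginal table treated as "no difference"


def percent_string(numerator: int, denominator: int) -> str:
    """Exact percentage of an integer ratio, half-up at 2 decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    with localcontext() as ctx:
        ctx.prec = 50
        value = Decimal(100 * numerator) / Decimal(denominator)
    return str(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_fraction_percent(fraction: float) -> str:
    with localcontext() as ctx:
        ctx.prec = 50
        value = Decimal(repr(fraction)) * 100
    return str(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# confusion + metrics


def confusion_from_decisions(
    decisions: Iterable[ScreeningDecision], gold: Mapping[str, str]
) -> ConfusionSummary:
    """Count TP/TN/FP/FN with gold "include" as the positive class."""
    decisions = list(decisions)
    missing = sorted({d.record_id for d in decisions} - set(gold))
    if missing:
        raise AccountingError(
            f"decision record ids missing from gold standard: {missing}", record_ids=missing
        )
    tp = tn = fp = fn = 0
    for d in decisions:
        actual_positive = gold[d.record_id] == "include"
        predicted_positive = d.decision == "include"
        if actual_positive and predicted_positive:
            tp += 1
        elif not actual_positive and not predicted_positive:
            tn += 1
        elif not actual_positive and predicted_positive:
            fp += 1
        else:
            fn += 1
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(c: ConfusionSummary) -> MetricSet:
    """Accuracy=(TP+TN)/total, Precision=TP/(TP+FP), Recall=TP/(TP+FN)."""
    if c.total == 0:
        raise ValueError("cannot compute metrics over an empty confusion summary")
    return MetricSet(
        accuracy=(c.tp + c.tn) / c.total,
        precision=None if c.tp + c.fp == 0 else c.tp / (c.tp + c.fp),
        recall=None if c.tp + c.fn == 0 else c.tp / (c.tp + c.fn),
    )


# ---------------------------------------------------------------------------
# exclusion-reason concordance


def _normalize_reason(reason: str) -> str:
    return " ".join(reason.casefold().split())


def exclusion_reason_concordance(
    decisions: Iterable[ScreeningDecision], gold_reasons: Mapping[str, str]
) -> ConcordanceResult:
    """Among records excluded by BOTH tool and gold, the fraction whose
    normalized reason labels agree."""
    compared = matched = 0
    for d in decisions:
        if d.decision != "exclude":
            continue
        gold_reason = gold_reasons.get(d.record_id)
        if gold_reason is None:
            continue  # gold did not exclude this record
        compared += 1
        if _normalize_reason(d.exclusion_reason or "") == _normalize_reason(gold_reason):
            matched += 1
    rate = matched / compared if compared else None
    return ConcordanceResult(matched=matched, compared=compared, rate=rate)


# ---------------------------------------------------------------------------
# chi-square


def chi_square_2xk(table: list[list[float]]) -> ChiSquareResult:
    """Pearson chi-square for a 2×k contingency table; df = k−1."""
    if len(table) != 2:
        raise ValueError("table must have exactly 2 rows")
    k = len(table[0])
    if k < 2 or len(table[1]) != k:
        raise ValueError("table must be 2×k with k >= 2")
    row_totals = [sum(row) for row in table]
    col_totals = [table[0][j] + table[1][j] for j in range(k)]
    grand = sum(row_totals)
    if any(t <= 0 for t in row_totals + col_totals):
        raise ValueError("zero marginal: every row and column total must be positive")
    statistic = 0.0
    for i in range(2):
        for j in range(k):
            expected = row_totals[i] * col_totals[j] / grand
            statistic += (table[i][j] - expected) ** 2 / expected
    df = k - 1
    return ChiSquareResult(
        statistic=statistic, df=df, p_value=float(_chi2_dist.sf(statistic, df))
    )


# ---------------------------------------------------------------------------
# multi-backend comparison report


@dataclass
class BackendEval:
    confusion: ConfusionSummary
    metrics: MetricSet
    concordance: ConcordanceResult


@dataclass
class EvalReport:
    stage: str
    n_records: int
    backends: dict[str, BackendEval] = field(default_factory=dict)
    recall_chi2: ChiSquareResult | None = None
    concordance_chi2: ChiSquareResult | None = None
    alpha: float = 0.05

    def to_dict(self) -> dict:
        def chi(c: ChiSquareResult | None) -> dict | None:
            if c is None:
                return None
            return {
                "statistic": c.statistic,
                "df": c.df,
                "p_value": c.p_value,
                "degenerate": c.degenerate,
                "significant": (not c.degenerate) and c.p_value < self.alpha,
            }

        return {
            "stage": self.stage,
            "n_records": self.n_records,
            "alpha": self.alpha,
            "backends": {
                name: {
                    "confusion": vars(b.confusion),
                    "metrics": b.metrics.as_percent_strings(),
                    "concordance": {
                        "matched": b.concordance.matched,
                        "compared": b.concordance.compared,
                        "rate": b.concordance.rate,
                    },
                }
                for name, b in self.backends.items()
            },
            "recall_chi2": chi(self.recall_chi2),
            "concordance_chi2": chi(self.concordance_chi2),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=False, indent=1)

    def render_text(self) -> str:
        lines = [f"Stage: {self.stage}   n={self.n_records}   alpha={self.alpha}"]
        header = f"{'Model':<16}{'Accuracy':>10}{'Recall':>10}{'Precision':>11}{'Concordance':>13}"
        lines.append(header)
        lines.append("-" * len(header))
        for name, b in self.backends.items():
            pct = b.metrics.as_percent_strings()
            conc = "undef" if b.concordance.rate is None else f"{b.concordance.rate:.4f}"
            lines.append(
                f"{name:<16}"
                f"{(pct['accuracy'] + '%'):>10}"
                f"{((pct['recall'] or 'undef') + '%'):>10}"
                f"{((pct['precision'] or 'undef') + '%'):>11}"
                f"{conc:>13}"
            )
        for label, chi in (
            ("recall", self.recall_chi2),
            ("concordance", self.concordance_chi2),
        ):
            if chi is not None:
                note = " (degenerate table)" if chi.degenerate else ""
                lines.append(
                    f"chi-square ({label}): statistic={chi.statistic:.4f} "
                    f"df={chi.df} p={chi.p_value:.4g}{note}"
                )
        return "\n".join(lines)


def _chi_or_degenerate(table: list[list[float]], k: int) -> ChiSquareResult:
    try:
        return chi_square_2xk(table)
    except ValueError:
        return ChiSquareResult(statistic=0.0, df=k - 1, p_value=1.0, degenerate=True)


def compare_models(
    decision_sets: Mapping[str, list[ScreeningDecision]],
    gold: Mapping[str, str],
    gold_reasons: Mapping[str, str] | None = None,
    stage: str = "title_abstract",
    alpha: float = 0.05,
) -> EvalReport:
    """Per-backend metrics/concordance plus chi-square comparisons across
    backends on recall (TP/FN) and concordance (matched/unmatched)."""
    if not decision_sets:
        raise ValueError("decision_sets must be non-empty")
    gold_reasons = gold_reasons or {}
    id_sets = {name: {d.record_id for d in ds} for name, ds in decision_sets.items()}
    reference = next(iter(id_sets.values()))
    for name, ids in id_sets.items():
        if ids != reference:
            raise AccountingError(
                f"decision set {name!r} does not cover the same records",
                record_ids=sorted(ids ^ reference),
            )
    report = EvalReport(stage=stage, n_records=len(reference), alpha=alpha)
    for name, decisions in decision_sets.items():
        confusion = confusion_from_decisions(decisions, gold)
        report.backends[name] = BackendEval(
            confusion=confusion,
            metrics=compute_metrics(confusion),
            concordance=exclusion_reason_concordance(decisions, gold_reasons),
        )
    k = len(decision_sets)
    if k >= 2:
        evals = list(report.backends.values())
        report.recall_chi2 = _chi_or_degenerate(
            [[b.confusion.tp for b in evals], [b.confusion.fn for b in evals]], k
        )
        report.concordance_chi2 = _chi_or_degenerate(
            [
                [b.concordance.matched for b in evals],
                [b.concordance.compared - b.concordance.matched for b in evals],
            ],
            k,
        )
    return report


# ---------------------------------------------------------------------------
# gold standard I/O (CSV: record_id, decision, reason)


def load_gold(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a gold-standard CSV into (decision map, exclusion-reason map)."""
    gold: dict[str, str] = {}
    reasons: dict[str, str] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            rid = row["record_id"]
            gold[rid] = row["decision"]
            reason = (row.get("reason") or "").strip()
            if reason:
                reasons[rid] = reason
    return gold, reasons
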