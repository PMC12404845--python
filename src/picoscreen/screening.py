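"""Chained eligibility screening and PRISMA flow accounting.

Each stage runs an ordered suite of per-dimension tasks; the first failing
task short-circuits the chain and supplies the exclusion reason, so the
emitted reason is always the chain-earliest failing dimension.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import criteria_prompt as cp
from .corpus_io import DedupReport, Record
from .errors import AccountingError, BackendUnavailableError, MalformedResponseError
from .llm_backend import Backend, BackendParams, complete
from .pdf_structure import StructuredArticle

STAGES = ("title_abstract", "full_text")

#: Reading order used to flatten a structured article for full-text screening.
CANONICAL_SECTION_ORDER = (
    "title",
    "abstract",
    "introduction",
    "methods",
    "results",
    "discussion",
    "conclusion",
    "other",
    "references",
)

_JSON_REMINDER = "\n\nReminder: respond with JSON only."

_PASS_VALUES = {"yes", "y", "true", "1", "pass", "met"}
_FAIL_VALUES = {"no", "n", "false", "0", "fail", "not met"}


@dataclass
class ChainTask:
    dimension: str
    reason_label: str
    stage: str
    prompt_spec: cp.PromptSpec
    prompt_spec_ref: str = ""
    few_shot: list[cp.FewShotExample] = field(default_factory=list)


@dataclass
class TraceEntry:
    dimension: str
    raw_answer: str
    passed: bool


@dataclass
class ScreeningDecision:
    record_id: str
    stage: str
    decision: str  # "include" | "exclude"
    exclusion_reason: str | None = None
    trace: list[TraceEntry] = field(default_factory=list)
    backend_name: str = ""

    def __post_init__(self) -> None:
        if (self.decision == "exclude") != (self.exclusion_reason is not None):
            raise ValueError("decision=exclude iff exclusion_reason present")


@dataclass
class PrismaCounts:
    identified: int
    after_dedup: int
    ta_included: int
    ta_excluded: int
    ft_excluded: int
    final_included: int

    def validate(self) -> None:
        if self.after_dedup != self.ta_included + self.ta_excluded:
            raise AccountingError("after_dedup must equal ta_included + ta_excluded")
        if self.final_included != self.ta_included - self.ft_excluded:
            raise AccountingError("final_included must equal ta_included - ft_excluded")


def make_prisma(
    identified: int, after_dedup: int, ta_included: int, ft_excluded: int
) -> PrismaCounts:
    """Build flow counts from the four free quantities; derived fields follow
    the flow invariants."""
    counts = PrismaCounts(
        identified=identified,
        after_dedup=after_dedup,
        ta_included=ta_included,
        ta_excluded=after_dedup - ta_included,
        ft_excluded=ft_excluded,
        final_included=ta_included - ft_excluded,
    )
    counts.validate()
    return counts


# ---------------------------------------------------------------------------
# task suites


def default_task_suite(
    criteria: cp.PICOSCriteria,
    taxonomy: cp.ExclusionReasonTaxonomy,
    stage: str,
    few_shot: dict[str, list[cp.FewShotExample]] | None = None,
) -> list[ChainTask]:
    """One task per taxonomy entry, in chain order, with default prompt specs.
    Title–abstract and full-text stages get distinct suites."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    few_shot = few_shot or {}
    return [
        ChainTask(
            dimension=dimension,
            reason_label=label,
            stage=stage,
            prompt_spec=cp.default_prompt_spec(dimension, criteria, stage),
            prompt_spec_ref=f"{stage}:{dimension}",
            few_shot=list(few_shot.get(dimension, [])),
        )
        for dimension, label in taxonomy
    ]


# ---------------------------------------------------------------------------
# chain execution


def _interpret(answer: dict) -> bool:
    value = answer.get("criterion_met")
    text = str(value).strip().casefold()
    if text in _PASS_VALUES or value is True:
        return True
    if text in _FAIL_VALUES or value is False:
        return False
    raise MalformedResponseError(f"unrecognized criterion_met value {value!r}")


def run_chain(
    document: str,
    tasks: list[ChainTask],
    backend: Backend,
    params: BackendParams,
    criteria: cp.PICOSCriteria,
    record_id: str = "",
) -> ScreeningDecision:
    """Execute tasks in order; the first failing task short-circuits with its
    reason label. All tasks passing (or an empty suite) yields include."""
    if not document:
        raise ValueError("document must be non-empty")
    stage = tasks[0].stage if tasks else "title_abstract"
    trace: list[TraceEntry] = []
    for task in tasks:
        prompt, spec = cp.build_prompt(task, criteria, task.few_shot, document)
        try:
            result = complete(prompt, backend, params)
            try:
                answer = cp.parse_model_json(result.text, spec.output_schema)
                passed = _interpret(answer)
            except MalformedResponseError:
                # single automatic retry with an appended JSON-only reminder
                result = complete(prompt + _JSON_REMINDER, backend, params)
                answer = cp.parse_model_json(result.text, spec.output_schema)
                passed = _interpret(answer)
        except BackendUnavailableError as exc:
            exc.partial_trace = list(trace)
            raise
        trace.append(TraceEntry(task.dimension, result.text, passed))
        if not passed:
            return ScreeningDecision(
                record_id=record_id,
                stage=task.stage,
                decision="exclude",
                exclusion_reason=task.reason_label,
                trace=trace,
                backend_name=backend.name,
            )
    return ScreeningDecision(
        record_id=record_id,
        stage=stage,
        decision="include",
        exclusion_reason=None,
        trace=trace,
        backend_name=backend.name,
    )


def screen_title_abstract(
    record: Record,
    tasks: list[ChainTask],
    backend: Backend,
    params: BackendParams,
    criteria: cp.PICOSCriteria,
) -> ScreeningDecision:
    """Chain input is the title + abstract concatenation (title alone when the
    abstract is empty)."""
    document = record.title if not record.abstract else f"{record.title}\n\n{record.abstract}"
    return run_chain(document, tasks, backend, params, criteria, record_id=record.record_id)


def screen_records(
    records: Iterable[Record],
    tasks: list[ChainTask],
    backend: Backend,
    params: BackendParams,
    criteria: cp.PICOSCriteria,
) -> list[ScreeningDecision]:
    return [screen_title_abstract(r, tasks, backend, params, criteria) for r in records]


def article_document(article: StructuredArticle) -> str:
    """Flatten sections in canonical reading order (unknown labels last)."""
    parts = [
        article.sections[label]
        for label in CANONICAL_SECTION_ORDER
        if article.sections.get(label)
    ]
    parts.extend(
        text
        for label, text in article.sections.items()
        if label not in CANONICAL_SECTION_ORDER and text
    )
    return "\n\n".join(parts)


def screen_full_text(
    article: StructuredArticle,
    tasks: list[ChainTask],
    backend: Backend,
    params: BackendParams,
    criteria: cp.PICOSCriteria,
) -> ScreeningDecision:
    document = article_document(article)
    if not document.strip():
        raise ValueError(f"article {article.record_id!r} has no non-empty section")
    return run_chain(document, tasks, backend, params, criteria, record_id=article.record_id)


# ---------------------------------------------------------------------------
# PRISMA accounting


def prisma_counts(
    dedup_report: DedupReport,
    ta_decisions: list[ScreeningDecision],
    ft_decisions: list[ScreeningDecision],
) -> PrismaCounts:
    """Assemble flow counts; full-text decisions must cover exactly the
    title–abstract includes."""
    ta_included_ids = {d.record_id for d in ta_decisions if d.decision == "include"}
    ft_ids = {d.record_id for d in ft_decisions}
    mismatch = sorted(ta_included_ids ^ ft_ids)
    if mismatch:
        raise AccountingError(
            f"full-text decisions must cover exactly the title–abstract includes; "
            f"offending ids: {mismatch}",
            record_ids=mismatch,
        )
    return make_prisma(
        identified=dedup_report.input_count,
        after_dedup=dedup_report.unique_count,
        ta_included=len(ta_included_ids),
        ft_excluded=sum(1 for d in ft_decisions if d.decision == "exclude"),
    )


def flow_summary(counts: PrismaCounts) -> str:
    return (
        f"records identified: {counts.identified}\n"
        f"after duplicate removal: {counts.after_dedup}\n"
        f"title–abstract included: {counts.ta_included} "
        f"(excluded: {counts.ta_excluded})\n"
        f"full-text excluded: {counts.ft_excluded}\n"
        f"final included: {counts.final_included}"
    )


# ---------------------------------------------------------------------------
# decision serialization (JSON lines)


def decision_to_dict(decision: ScreeningDecision) -> dict:
    return {
        "record_id": decision.record_id,
        "stage": decision.stage,
        "decision": decision.decision,
        "exclusion_reason": decision.exclusion_reason,
        "trace": [
            {"dimension": t.dimension, "raw_answer": t.raw_answer, "passed": t.passed}
            for t in decision.trace
        ],
        "backend_name": decision.backend_name,
    }


def write_decisions_jsonl(decisions: Iterable[ScreeningDecision], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in decisions:
            fh.write(json.dumps(decision_to_dict(d), ensure_ascii=False, sort_keys=True) + "\n")


def read_decisions_jsonl(path: str | Path) -> list[ScreeningDecision]:
    decisions = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            decisions.append(
                ScreeningDecision(
                    record_id=obj["record_id"],
                    stage=obj["stage"],
                    decision=obj["decision"],
                    exclusion_reason=obj.get("exclusion_reason"),
                    trace=[
                        TraceEntry(t["dimension"], t["raw_answer"], t["passed"])
                        for t in obj.get("trace", [])
                    ],
                    backend_name=obj.get("backend_name", ""),
                )
            )
    return decisions
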