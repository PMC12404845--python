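"""PICOS criteria, exclusion-reason taxonomy, and chained-task prompt assembly.

Eligibility is decomposed into four sequential dimensions (the comparator is
folded into the intervention task). Each dimension carries one exclusion
reason; prompts are assembled deterministically from role text, domain
definitions, stepwise-reasoning instructions, few-shot examples, a JSON
output-format instruction, and the document under review.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

from .errors import ConfigurationError, MalformedResponseError

#: Fixed evaluation order of the chained eligibility tasks.
CHAIN_ORDER = ("intervention_comparator", "population", "outcome", "study_design")

#: Which PICOSCriteria field supplies each dimension's criterion text.
_CRITERION_FIELD = {
    "intervention_comparator": "intervention",
    "population": "population",
    "outcome": "outcomes",
    "study_design": "study_design",
}

#: Negation templates used when no explicit reason label is configured.
_REASON_TEMPLATES = {
    "intervention_comparator": "Intervention measure is not {criterion}",
    "population": "Research subjects are not {criterion}",
    "outcome": "Outcome indicators are not {criterion}",
    "study_design": "Study design is not {criterion}",
}

_DIMENSION_TITLES = {
    "intervention_comparator": "intervention and comparator",
    "population": "study population",
    "outcome": "outcome indicators",
    "study_design": "study design",
}

DEFAULT_OUTPUT_SCHEMA: dict[str, str] = {"criterion_met": "str", "rationale": "str"}

_TYPE_MAP = {
    "str": str,
    "int": int,
    "float": (int, float),
    "bool": bool,
    "list": list,
    "dict": dict,
}


@dataclass
class PICOSCriteria:
    population: str
    intervention: str
    outcomes: str
    study_design: str
    comparison: str | None = None
    scenario_name: str = ""


@dataclass
class ExclusionReasonTaxonomy:
    """Ordered (dimension, reason label) pairs, one per chain task."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        dims = [d for d, _ in self.entries]
        if len(dims) != len(set(dims)):
            raise ConfigurationError("taxonomy dimensions must be unique")
        if tuple(dims) != CHAIN_ORDER[: len(dims)]:
            raise ConfigurationError("taxonomy must follow the fixed chain order")

    def label_for(self, dimension: str) -> str:
        for d, label in self.entries:
            if d == dimension:
                return label
        raise KeyError(dimension)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FewShotExample:
    document_snippet: str
    expected_answer: dict[str, Any]
    provenance: str = "representative"  # or "misclassified"


@dataclass
class PromptSpec:
    role_task: str
    medical_definitions: str
    thought_steps: list[str]
    few_shot_examples: list[FewShotExample] = field(default_factory=list)
    output_schema: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_OUTPUT_SCHEMA))


# ---------------------------------------------------------------------------
# criteria loading


def load_criteria(
    config: str | Path | Mapping[str, Any],
) -> tuple[PICOSCriteria, ExclusionReasonTaxonomy]:
    """Load a criteria config (YAML/JSON file or mapping) and derive the
    exclusion-reason taxonomy, one negated reason per chained dimension."""
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ConfigurationError("criteria config must be a mapping")
    picos = config.get("picos")
    if not isinstance(picos, Mapping):
        raise ConfigurationError("criteria config missing 'picos' block")
    mandatory = ("population", "intervention", "outcomes", "study_design")
    for key in mandatory:
        if not (picos.get(key) or "").strip():
            raise ConfigurationError(f"criteria config missing mandatory PICOS dimension {key!r}")
    criteria = PICOSCriteria(
        population=picos["population"].strip(),
        intervention=picos["intervention"].strip(),
        outcomes=picos["outcomes"].strip(),
        study_design=picos["study_design"].strip(),
        comparison=(picos.get("comparison") or None) and str(picos["comparison"]).strip(),
        scenario_name=str(config.get("scenario", "")),
    )
    configured = config.get("exclusion_reasons") or {}
    entries = []
    for dimension in CHAIN_ORDER:
        label = configured.get(dimension)
        if not label:
            criterion = getattr(criteria, _CRITERION_FIELD[dimension])
            label = _REASON_TEMPLATES[dimension].format(criterion=criterion)
        entries.append((dimension, str(label)))
    return criteria, ExclusionReasonTaxonomy(entries)


def default_criteria() -> tuple[PICOSCriteria, ExclusionReasonTaxonomy]:
    """The bundled RSV vaccine-safety scenario config."""
    path = resources.files("picoscreen").joinpath("data/rsv_criteria.yaml")
    with resources.as_file(path) as p:
        return load_criteria(p)


# ---------------------------------------------------------------------------
# prompt specs

#: Default guardrail for the outcome task at the title–abstract stage:
#: short trial abstracts often omit explicit safety endpoints.
RCT_OUTCOME_GUIDANCE = (
    "If the document reports a randomized controlled trial of the intervention, "
    "do not fail it merely because the abstract does not explicitly mention the "
    "outcome of interest; such outcomes are typically reported in the full text."
)


def default_prompt_spec(
    dimension: str, criteria: PICOSCriteria, stage: str = "title_abstract"
) -> PromptSpec:
    criterion = getattr(criteria, _CRITERION_FIELD[dimension])
    if dimension == "intervention_comparator" and criteria.comparison:
        criterion = f"{criterion} (comparator: {criteria.comparison})"
    title = _DIMENSION_TITLES[dimension]
    steps = [
        f"Identify every statement in the document describing the {title}.",
        f"Compare those statements with the criterion: {criterion}.",
        "Answer 'yes' if the criterion is satisfied, otherwise 'no', and justify briefly.",
    ]
    if dimension == "outcome" and stage == "title_abstract":
        steps.insert(2, RCT_OUTCOME_GUIDANCE)
    return PromptSpec(
        role_task=(
            "As an expert in epidemiology and evidence-based medicine, familiar with "
            f"drug intervention studies, decide whether the document's {title} "
            f"satisfies the eligibility criterion for the scenario "
            f"'{criteria.scenario_name or 'unnamed'}'."
        ),
        medical_definitions=f"Eligibility criterion ({title}): {criterion}.",
        thought_steps=steps,
        few_shot_examples=[],
        output_schema=dict(DEFAULT_OUTPUT_SCHEMA),
    )


# ---------------------------------------------------------------------------
# prompt rendering

DOCUMENT_MARKER = "# Document"
DIMENSION_MARKER = "# Task dimension:"


def build_prompt(
    task: Any,
    criteria: PICOSCriteria,
    examples: list[FewShotExample],
    document: str,
) -> tuple[str, PromptSpec]:
    """Render the chained-task prompt. Pure: identical inputs yield
    byte-identical output. ``task`` needs ``dimension`` and ``prompt_spec``."""
    if not document:
        raise ValueError("document must be non-empty")
    spec: PromptSpec = task.prompt_spec
    spec = dataclasses.replace(spec, few_shot_examples=list(examples))
    parts = [
        "# Role",
        spec.role_task,
        f"{DIMENSION_MARKER} {task.dimension}",
        "# Medical definitions",
        spec.medical_definitions,
        "# Step-by-step thinking",
    ]
    parts.extend(f"{i}. {step}" for i, step in enumerate(spec.thought_steps, start=1))
    if spec.few_shot_examples:
        parts.append("# Examples")
        for i, ex in enumerate(spec.few_shot_examples, start=1):
            parts.append(f"Example {i} ({ex.provenance}):")
            parts.append(f"Document: {ex.document_snippet}")
            parts.append(
                "Answer: " + json.dumps(ex.expected_answer, ensure_ascii=False, sort_keys=True)
            )
    parts.append("# Output format")
    keys = ", ".join(f'"{key}": {typ}' for key, typ in spec.output_schema.items())
    parts.append(
        "The response must be in JSON format. The return format is as follows: "
        "{" + keys + "}. Respond with JSON only."
    )
    parts.append(DOCUMENT_MARKER)
    parts.append(document)
    return "\n".join(parts), spec


# ---------------------------------------------------------------------------
# response parsing


def _first_json_object(text: str) -> str | None:
    start = text.find("{")
    while start != -1:
        depth = 0
        in_string = False
        escaped = False
        for i in range(start, len(text)):
            ch = text[i]
            if in_string:
                if escaped:
                    escaped = False
                elif ch == "\\":
                    escaped = True
                elif ch == '"':
                    in_string = False
            elif ch == '"':
                in_string = True
            elif ch == "{":
                depth += 1
            elif ch == "}":
                depth -= 1
                if depth == 0:
                    return text[start : i + 1]
        start = text.find("{", start + 1)
    return None


def validate_answer(answer: Any, schema: Mapping[str, str]) -> dict[str, Any]:
    if not isinstance(answer, dict):
        raise MalformedResponseError("response is not a JSON object")
    for key, typename in schema.items():
        if key not in answer:
            raise MalformedResponseError(f"response missing required key {key!r}")
        expected = _TYPE_MAP.get(typename)
        if expected is not None and not isinstance(answer[key], expected):
            raise MalformedResponseError(
                f"response key {key!r} has wrong type (expected {typename})"
            )
    return answer


def parse_model_json(response: str, schema: Mapping[str, str]) -> dict[str, Any]:
    """Strip surrounding prose/code fences, parse the first JSON object, and
    validate it against the schema fragment (required keys + types)."""
    text = re.sub(r"```[a-zA-Z]*", "", response)
    candidate = _first_json_object(text)
    if candidate is None:
        raise MalformedResponseError("no JSON object found in response", raw=response)
    try:
        answer = json.loads(candidate)
    except json.JSONDecodeError as exc:
        raise MalformedResponseError(f"invalid JSON: {exc}", raw=response) from exc
    try:
        return validate_answer(answer, schema)
    except MalformedResponseError as exc:
        raise MalformedResponseError(str(exc), raw=response) from exc


# ---------------------------------------------------------------------------
# few-shot stores


def add_error_examples(
    store: list[FewShotExample],
    misclassified: list[tuple[str, dict[str, Any]]],
    schema: Mapping[str, str] = DEFAULT_OUTPUT_SCHEMA,
) -> list[FewShotExample]:
    """Append misclassified cases as few-shot examples (the targeted-refinement
    loop). Deduplicated on document snippet; existing order preserved."""
    result = list(store)
    seen = {ex.document_snippet for ex in result}
    for document, gold in misclassified:
        try:
            validate_answer(gold, schema)
        except MalformedResponseError as exc:
            raise ConfigurationError(f"invalid gold answer for error example: {exc}") from exc
        if document in seen:
            continue
        seen.add(document)
        result.append(FewShotExample(document, dict(gold), provenance="misclassified"))
    return result
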