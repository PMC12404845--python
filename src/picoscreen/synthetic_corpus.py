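"""Seeded synthetic screening corpora for offline testing.

Generated records carry human-plausible text plus machine-readable sentinels
(«INC» / «EXC:dimension») consistent with their gold labels, so the mock
backend can screen them without any NLP. Also provides stratified training
splits, duplicate-cluster injection, and sectioned full-text page fixtures.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus_io import DedupReport, Record
from .criteria_prompt import CHAIN_ORDER, ExclusionReasonTaxonomy, default_criteria
from .pdf_structure import RawPage

SENTINEL_INCLUDE = "«INC»"


def sentinel_exclude(dimension: str) -> str:
    return f"«EXC:{dimension}»"


def strip_sentinels(text: str) -> str:
    return " ".join(re.sub(r"«[^»]*»", " ", text).split())


@dataclass
class CorpusProfile:
    n_records: int
    prevalence: float = 0.1
    reason_mix: dict[str, float] | None = None  # None = uniform over dimensions
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be non-negative")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        if self.reason_mix is not None:
            if set(self.reason_mix) - set(CHAIN_ORDER):
                raise ValueError("reason_mix keys must be chain dimensions")
            if abs(sum(self.reason_mix.values()) - 1.0) > 1e-9:
                raise ValueError("reason_mix must sum to 1")


@dataclass
class GoldLabel:
    record_id: str
    decision: str  # "include" | "exclude"
    reason_dimension: str | None = None
    reason_label: str | None = None

    def __post_init__(self) -> None:
        if (self.decision == "exclude") != (self.reason_dimension is not None):
            raise ValueError("exclude iff a reason is present")


# ---------------------------------------------------------------------------
# corpus generation

_INTERVENTIONS = (
    "a bivalent prefusion F vaccine",
    "an adjuvanted subunit vaccine",
    "a live-attenuated intranasal vaccine",
    "a vector-based vaccine candidate",
    "a protein nanoparticle vaccine",
)
_POPULATIONS = (
    "older adults",
    "pregnant women",
    "healthy infants",
    "immunocompromised patients",
    "community-dwelling seniors",
)
_DESIGNS = (
    "randomized controlled trial",
    "prospective cohort study",
    "case-control study",
    "open-label phase 2 trial",
    "retrospective observational study",
)
_JOURNALS = (
    "Journal of Applied Epidemiology",
    "Vaccine Science Reports",
    "Clinical Trials Quarterly",
    "Preventive Medicine Letters",
)
_SURNAMES = (
    "Alvarez", "Brown", "Chen", "Dubois", "Eriksen", "Fischer",
    "Garcia", "Huang", "Ivanov", "Johnson", "Kim", "Larsen",
)


def _largest_remainder(total: int, fractions: dict[str, float]) -> dict[str, int]:
    quotas = {k: total * v for k, v in fractions.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    remainder = total - sum(counts.values())
    # deterministic tie-break: fractional part desc, then chain order
    order = sorted(
        fractions,
        key=lambda k: (-(quotas[k] - counts[k]), CHAIN_ORDER.index(k)),
    )
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def generate_corpus(
    profile: CorpusProfile,
    taxonomy: ExclusionReasonTaxonomy | None = None,
) -> tuple[list[Record], list[GoldLabel]]:
    """Deterministic labeled corpus: class counts are the rounding of
    n×prevalence; excluded records carry a sentinel for their gold dimension."""
    if taxonomy is None:
        _, taxonomy = default_criteria()
    rng = np.random.default_rng(profile.seed)
    n = profile.n_records
    n_included = int(round(n * profile.prevalence))
    mix = profile.reason_mix or {d: 1 / len(CHAIN_ORDER) for d in CHAIN_ORDER}
    reason_counts = _largest_remainder(n - n_included, mix)
    assignments: list[str | None] = [None] * n_included
    for dimension in CHAIN_ORDER:
        assignments.extend([dimension] * reason_counts.get(dimension, 0))
    rng.shuffle(assignments)  # type: ignore[arg-type]

    records: list[Record] = []
    labels: list[GoldLabel] = []
    for i, dimension in enumerate(assignments):
        rid = f"S{i:05d}"
        intervention = _INTERVENTIONS[rng.integers(len(_INTERVENTIONS))]
        population = _POPULATIONS[rng.integers(len(_POPULATIONS))]
        design = _DESIGNS[rng.integers(len(_DESIGNS))]
        title = (
            f"Safety of {intervention} in {population}: "
            f"a {design} (protocol {i:05d})"
        )
        sentinel = SENTINEL_INCLUDE if dimension is None else sentinel_exclude(dimension)
        abstract = (
            f"We evaluated {intervention} administered to {population} in a {design}. "
            f"Solicited local and systemic adverse events were recorded for 28 days. "
            f"Screening sentinel: {sentinel}."
        )
        n_authors = int(rng.integers(1, 4))
        authors = [
            f"{_SURNAMES[rng.integers(len(_SURNAMES))]}, {chr(65 + int(rng.integers(26)))}."
            for _ in range(n_authors)
        ]
        records.append(
            Record(
                record_id=rid,
                title=title,
                abstract=abstract,
                authors=authors,
                year=int(rng.integers(2005, 2025)),
                journal=_JOURNALS[rng.integers(len(_JOURNALS))],
                source_db="synthetic",
            )
        )
        if dimension is None:
            labels.append(GoldLabel(rid, "include"))
        else:
            labels.append(
                GoldLabel(rid, "exclude", dimension, taxonomy.label_for(dimension))
            )
    return records, labels


# ---------------------------------------------------------------------------
# stratified training splits


def stratified_sample(
    records: list[Record],
    labels: list[GoldLabel],
    total: int,
    ratio_included_to_excluded: tuple[int, int],
    seed: int = 0,
) -> tuple[list[Record], list[GoldLabel]]:
    """Sample exactly total×a/(a+b) includes and total×b/(a+b) excludes
    (ratio a:b), without replacement, seed-deterministic, pool order kept."""
    a, b = ratio_included_to_excluded
    if a <= 0 or b <= 0:
        raise ValueError("ratio parts must be positive")
    if total == 0:
        return [], []
    if (total * a) % (a + b) != 0:
        raise ValueError(
            f"total {total} does not split evenly at ratio {a}:{b}"
        )
    n_inc = total * a // (a + b)
    n_exc = total - n_inc
    inc_idx = [i for i, lab in enumerate(labels) if lab.decision == "include"]
    exc_idx = [i for i, lab in enumerate(labels) if lab.decision == "exclude"]
    if len(inc_idx) < n_inc or len(exc_idx) < n_exc:
        raise ValueError(
            f"pool too small: need {n_inc} includes / {n_exc} excludes, "
            f"have {len(inc_idx)} / {len(exc_idx)}"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(
        list(rng.choice(inc_idx, size=n_inc, replace=False))
        + list(rng.choice(exc_idx, size=n_exc, replace=False))
    )
    return [records[i] for i in chosen], [labels[i] for i in chosen]


# ---------------------------------------------------------------------------
# duplicate injection


def _mutate_title(title: str, rng: np.random.Generator) -> str:
    """Case/punctuation/whitespace mutations that keep the dedup key intact."""
    choice = int(rng.integers(4))
    if choice == 0:
        mutated = title.upper()
    elif choice == 1:
        mutated = title.lower()
    elif choice == 2:
        mutated = title.title()
    else:
        mutated = title
    if rng.random() < 0.5:
        mutated = mutated.rstrip(".") + "."
    if rng.random() < 0.5:
        mutated = mutated.replace(": ", " :  ", 1)
    return mutated


def inject_duplicates(
    records: list[Record], rate: float, seed: int = 0
) -> tuple[list[Record], DedupReport]:
    """Append mutated duplicate copies of a seed-chosen ⌊rate·n⌉ subset and
    return the ground-truth report that deduplicate must reproduce."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_dup = int(round(rate * len(records)))
    if n_dup == 0:
        return list(records), DedupReport(len(records), len(records), 0, [])
    targets = sorted(rng.choice(len(records), size=n_dup, replace=False).tolist())
    augmented = list(records)
    clusters: list[tuple[str, tuple[str, ...]]] = []
    for k, t in enumerate(targets):
        original = records[t]
        dup = Record(
            record_id=f"{original.record_id}-dup{k}",
            title=_mutate_title(original.title, rng),
            abstract=original.abstract,
            authors=list(original.authors),
            year=None if rng.random() < 0.3 else original.year,
            journal=original.journal,
            source_db=original.source_db,
            language=original.language,
        )
        augmented.append(dup)
        clusters.append((original.record_id, (dup.record_id,)))
    report = DedupReport(
        input_count=len(augmented),
        unique_count=len(records),
        removed_count=n_dup,
        clusters=clusters,
    )
    report.validate()
    return augmented, report


# ---------------------------------------------------------------------------
# full-text page fixtures

#: Section in which each gold exclusion dimension's sentinel is planted.
_DIMENSION_SECTION = {
    "intervention_comparator": "methods",
    "population": "methods",
    "outcome": "results",
    "study_design": "methods",
}


def generate_fulltext_pages(
    record: Record, gold: GoldLabel, layout: str = "imrad"
) -> list[RawPage]:
    """Sectioned (imrad) or heading-free page stream for one record, with the
    sentinel placed in the section appropriate to the gold reason."""
    if layout not in ("imrad", "headingless"):
        raise ValueError(f"unknown layout {layout!r}")
    abstract = strip_sentinels(record.abstract)
    if gold.decision == "include":
        sentinel, target_section = SENTINEL_INCLUDE, "methods"
    else:
        assert gold.reason_dimension is not None
        sentinel = sentinel_exclude(gold.reason_dimension)
        target_section = _DIMENSION_SECTION[gold.reason_dimension]

    if layout == "headingless":
        body = (
            f"{record.title}\n\n{abstract}\n"
            f"The study procedures and findings are described in running text. "
            f"Screening sentinel: {sentinel}."
        )
        return [RawPage(text=body)]

    def section(name: str, body: str) -> str:
        extra = f" Screening sentinel: {sentinel}." if name == target_section else ""
        return body + extra

    page1 = "\n".join(
        [
            record.title,
            "",
            "Abstract",
            abstract,
            "",
            "Introduction",
            section(
                "introduction",
                "Respiratory infections remain a significant burden; this study "
                "addresses an open safety question.",
            ),
            "Table 1. Baseline characteristics of the enrolled participants.",
        ]
    )
    page2 = "\n".join(
        [
            "Methods",
            section(
                "methods",
                "Participants were enrolled, allocated, and followed according to "
                "the prespecified protocol.",
            ),
            "",
            "Results",
            section(
                "results",
                "Outcomes were tabulated for all participants over the follow-up "
                "period.",
            ),
            "Figure 1. Participant flow through the study.",
            "",
            "Discussion",
            section("discussion", "Findings are consistent with prior reports."),
            "",
            "Conclusion",
            section("conclusion", "The results support the stated conclusions."),
            "",
            "References",
            "1. Placeholder reference list entry.",
        ]
    )
    return [RawPage(text=page1), RawPage(text=page2)]


# ---------------------------------------------------------------------------
# gold label I/O


def write_gold_csv(labels: list[GoldLabel], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "decision", "reason_dimension", "reason"])
        for lab in labels:
            writer.writerow(
                [lab.record_id, lab.decision, lab.reason_dimension or "", lab.reason_label or ""]
            )


def read_gold_csv(path: str | Path) -> list[GoldLabel]:
    labels = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            dim = (row.get("reason_dimension") or "").strip() or None
            labels.append(
                GoldLabel(
                    record_id=row["record_id"],
                    decision=row["decision"],
                    reason_dimension=dim,
                    reason_label=(row.get("reason") or "").strip() or None,
                )
            )
    return labels
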