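"""Full-text page streams → canonically sectioned structured articles.

The module consumes plain page text (from a PDF reader adapter, a form-feed
separated fixture file, or an OCR contract for image-only pages), detects
section headings against an editable vocabulary, and partitions every prose
line into exactly one section or a non-prose (table/figure caption) element.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

from .errors import UnreadablePageError

CANONICAL_LABELS = (
    "title",
    "abstract",
    "introduction",
    "methods",
    "results",
    "discussion",
    "conclusion",
    "references",
    "other",
)

#: label → heading phrases (matched after enumeration stripping, case-insensitive).
DEFAULT_HEADING_VOCABULARY: dict[str, list[str]] = {
    "abstract": ["abstract", "summary", "structured abstract"],
    "introduction": ["introduction", "background"],
    "methods": [
        "methods",
        "method",
        "methodology",
        "materials and methods",
        "patients and methods",
        "study design and methods",
        "subjects and methods",
    ],
    "results": ["results", "findings"],
    "discussion": ["discussion"],
    "conclusion": ["conclusion", "conclusions"],
    "references": ["references", "bibliography", "literature cited"],
    "other": [
        "acknowledgments",
        "acknowledgements",
        "funding",
        "conflicts of interest",
        "supplementary material",
    ],
}

MAX_HEADING_TOKENS = 8

OCRContract = Callable[[Any], list[str]]


@dataclass
class RawPage:
    """Adapter-level page: ``text`` is the extracted text layer (None when the
    page is image-only, in which case ``image`` holds the OCR payload)."""

    text: str | None = None
    image: Any = None


@dataclass
class PageText:
    page_number: int
    lines: list[str]
    has_text_layer: bool = True


@dataclass
class HeadingHit:
    page_number: int
    line_index: int
    raw_text: str
    canonical_label: str


@dataclass
class NonProseElement:
    kind: str  # "table" | "figure"
    caption: str
    location: tuple[int, int]  # (page_number, line_index)


@dataclass
class StructuredArticle:
    record_id: str
    sections: dict[str, str]
    nonprose_elements: list[NonProseElement] = field(default_factory=list)
    provenance: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "record_id": self.record_id,
                "sections": self.sections,
                "nonprose_elements": [
                    {"kind": e.kind, "caption": e.caption, "location": list(e.location)}
                    for e in self.nonprose_elements
                ],
                "provenance": self.provenance,
            },
            ensure_ascii=False,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "StructuredArticle":
        obj = json.loads(text)
        return cls(
            record_id=obj["record_id"],
            sections=dict(obj["sections"]),
            nonprose_elements=[
                NonProseElement(e["kind"], e["caption"], tuple(e["location"]))
                for e in obj.get("nonprose_elements", [])
            ],
            provenance=obj.get("provenance", ""),
        )


# ---------------------------------------------------------------------------
# page extraction


def pages_from_text(stream: str) -> list[RawPage]:
    """Split a form-feed separated plain-text stream into raw pages."""
    return [RawPage(text=chunk) for chunk in stream.split("\f")]


def pages_from_pdf(path: str | Path) -> list[RawPage]:  # pragma: no cover - adapter
    """Thin PDF reader adapter; requires an optional PDF library at runtime."""
    try:
        from pypdf import PdfReader  # type: ignore[import-not-found]
    except ImportError as exc:
        raise ImportError(
            "PDF input requires the optional 'pypdf' dependency; "
            "convert to a plain-text page stream instead"
        ) from exc
    reader = PdfReader(str(path))
    pages = []
    for page in reader.pages:
        text = page.extract_text() or ""
        pages.append(RawPage(text=text if text.strip() else None, image=page))
    return pages


def extract_page_texts(
    source: Sequence[RawPage | str], ocr: OCRContract | None = None
) -> list[PageText]:
    """Turn raw pages into ordered PageTexts, routing image-only pages through
    the OCR contract when supplied."""
    pages: list[PageText] = []
    unreadable: list[int] = []
    for i, raw in enumerate(source, start=1):
        if isinstance(raw, str):
            raw = RawPage(text=raw)
        if raw.text is not None:
            pages.append(PageText(i, raw.text.splitlines(), has_text_layer=True))
        elif ocr is not None:
            pages.append(PageText(i, list(ocr(raw.image)), has_text_layer=False))
        else:
            unreadable.append(i)
    if unreadable:
        raise UnreadablePageError(
            f"image-only page(s) {unreadable} and no OCR contract provided",
            pages=unreadable,
        )
    return pages


# ---------------------------------------------------------------------------
# heading detection

# leading enumeration: "2.", "2.1", "III.", "(b)", "B)", "IV)" …
_ENUM = re.compile(
    r"""^\s*(?:
        \(?\d+(?:\.\d+)*[\.\)]?
      | \(?[ivxlcdm]+[\.\)]
      | \(?[IVXLCDM]+[\.\)]
      | \([A-Za-z]\)
      | [A-Za-z][\.\)](?=\s)
    )\s*""",
    re.VERBOSE,
)


def _strip_enumeration(line: str) -> str:
    prev = None
    while prev != line:
        prev = line
        line = _ENUM.sub("", line, count=1)
    return line


def _normalize_heading(line: str) -> str:
    line = _strip_enumeration(line)
    line = line.strip().rstrip(".:;,—–-").strip()
    return " ".join(line.casefold().split())


def _vocabulary_index(vocabulary: dict[str, list[str]]) -> dict[str, str]:
    index: dict[str, str] = {}
    for label, phrases in vocabulary.items():
        for phrase in phrases:
            index[" ".join(phrase.casefold().split())] = label
    return index


def detect_headings(
    pages: list[PageText],
    vocabulary: dict[str, list[str]] | None = None,
) -> list[HeadingHit]:
    """Find section headings: short lines (≤ 8 tokens after enumeration
    stripping) that match the vocabulary, in document order."""
    vocabulary = vocabulary if vocabulary is not None else DEFAULT_HEADING_VOCABULARY
    if not vocabulary:
        raise ValueError("heading vocabulary must be non-empty")
    index = _vocabulary_index(vocabulary)
    hits: list[HeadingHit] = []
    for page in pages:
        for li, line in enumerate(page.lines):
            normalized = _normalize_heading(line)
            if not normalized or len(normalized.split()) > MAX_HEADING_TOKENS:
                continue
            label = index.get(normalized)
            if label is not None:
                hits.append(HeadingHit(page.page_number, li, line, label))
    return hits


# ---------------------------------------------------------------------------
# sectioning

_CAPTION = re.compile(
    r"^\s*(?P<kind>table|fig(?:ure)?)\.?\s+(?:[A-Za-z]?\d|[IVXLC]+\b)", re.IGNORECASE
)


def _caption_kind(line: str) -> str | None:
    m = _CAPTION.match(line)
    if not m:
        return None
    return "table" if m.group("kind").casefold() == "table" else "figure"


def segment_sections(
    pages: list[PageText],
    hits: list[HeadingHit],
    record_id: str = "",
    provenance: str = "",
) -> StructuredArticle:
    """Partition every non-empty prose line into exactly one section.

    Lines before the first heading become front matter (first non-empty line
    is the title, the remainder the abstract). Each span between consecutive
    headings takes the earlier heading's label; same-label spans merge.
    Table/figure caption lines are diverted to nonprose_elements.
    """
    hit_at = {(h.page_number, h.line_index): h.canonical_label for h in hits}
    sections: dict[str, list[str]] = {}
    nonprose: list[NonProseElement] = []
    current: str | None = None  # None = front matter
    front: list[str] = []
    any_line = False
    for page in pages:
        for li, line in enumerate(page.lines):
            if not line.strip():
                continue
            any_line = True
            kind = _caption_kind(line)
            if kind is not None and (page.page_number, li) not in hit_at:
                nonprose.append(NonProseElement(kind, line.strip(), (page.page_number, li)))
                continue
            label = hit_at.get((page.page_number, li))
            if label is not None:
                current = label
                sections.setdefault(current, []).append(line)
                continue
            if current is None:
                front.append(line)
            else:
                sections[current].append(line)
    if not any_line:
        raise ValueError("empty document: no non-empty lines to segment")

    ordered: dict[str, str] = {}
    if front:
        ordered["title"] = front[0].strip()
        if len(front) > 1:
            ordered["abstract"] = "\n".join(front[1:])
    for label, lines in sections.items():
        if label in ordered:
            ordered[label] = ordered[label] + "\n" + "\n".join(lines)
        else:
            ordered[label] = "\n".join(lines)
    return StructuredArticle(
        record_id=record_id,
        sections=ordered,
        nonprose_elements=nonprose,
        provenance=provenance,
    )


def structure_pages(
    source: Sequence[RawPage | str],
    ocr: OCRContract | None = None,
    vocabulary: dict[str, list[str]] | None = None,
    record_id: str = "",
    provenance: str = "",
) -> StructuredArticle:
    """Convenience pipeline: extract → detect → segment."""
    pages = extract_page_texts(source, ocr=ocr)
    hits = detect_headings(pages, vocabulary)
    return segment_sections(pages, hits, record_id=record_id, provenance=provenance)
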