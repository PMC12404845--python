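"""Bibliographic record I/O for the title–abstract stage.

Reads RIS, CSV, PubMed MEDLINE (.nbib) and the internal corpus XML format,
cleans free text, deduplicates on a normalized title + compatible-year key,
and serializes corpora as XML.
"""

from __future__ import annotations

import csv
import html
import re
import unicodedata
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ConfigurationError, RecordParseError

FORMATS = ("ris", "csv", "medline", "corpus_xml")

CSV_COLUMNS = (
    "record_id",
    "title",
    "abstract",
    "authors",
    "year",
    "journal",
    "source_db",
    "language",
)


@dataclass
class Record:
    """One bibliographic item flowing through screening.

    Optional metadata is ``None`` when absent — never the empty string.
    """

    record_id: str
    title: str
    abstract: str = ""
    authors: list[str] = field(default_factory=list)
    year: int | None = None
    journal: str | None = None
    source_db: str | None = None
    language: str | None = None


@dataclass(frozen=True)
class DedupKey:
    norm_title: str
    year: int | None = None
    first_author_surname: str | None = None


@dataclass
class DedupReport:
    input_count: int
    unique_count: int
    removed_count: int
    clusters: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def validate(self) -> None:
        if self.input_count != self.unique_count + self.removed_count:
            raise ValueError("dedup conservation violated")
        removed = [rid for _, rem in self.clusters for rid in rem]
        if len(removed) != len(set(removed)) or len(removed) != self.removed_count:
            raise ValueError("removed ids must appear in exactly one cluster")


# ---------------------------------------------------------------------------
# text cleaning


def clean_text(raw: str) -> str:
    """Normalize free text: decode entity remnants, strip markup and control
    characters, collapse whitespace. Idempotent; empty input yields empty output."""
    if not raw:
        return ""
    text = raw
    # entity decoding and tag stripping to a fixed point so that a second
    # application is a no-op even for nested remnants like "&amp;lt;b&amp;gt;"
    for _ in range(100):
        prev = text
        text = html.unescape(text)
        text = re.sub(r"<[^<>]*>", " ", text)
        if text == prev:
            break
    text = "".join(
        " " if unicodedata.category(ch) in ("Cc", "Cf") else ch for ch in text
    )
    return re.sub(r"\s+", " ", text).strip()


def normalize_title(title: str) -> str:
    """NFKC, casefold, non-alphanumerics to spaces, runs collapsed."""
    s = unicodedata.normalize("NFKC", title).casefold()
    s = "".join(ch if ch.isalnum() else " " for ch in s)
    return " ".join(s.split())


def clean_record(record: Record) -> Record:
    """Return a copy with title/abstract passed through :func:`clean_text`."""
    return Record(
        record_id=record.record_id,
        title=clean_text(record.title),
        abstract=clean_text(record.abstract),
        authors=[clean_text(a) for a in record.authors],
        year=record.year,
        journal=clean_text(record.journal) if record.journal else record.journal,
        source_db=record.source_db,
        language=record.language,
    )


# ---------------------------------------------------------------------------
# reading


def read_records(path: str | Path, format: str) -> list[Record]:
    """Read a bibliographic file in the named dialect into Records."""
    if format not in FORMATS:
        raise ConfigurationError(
            f"unknown corpus format {format!r}; expected one of {FORMATS}"
        )
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if format == "ris":
        return _read_ris(text)
    if format == "medline":
        return _read_medline(text)
    if format == "csv":
        return _read_csv(text)
    return _read_corpus_xml(path)


_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def _year_from(value: str, index: int, what: str) -> int:
    m = re.search(r"\d{4}", value)
    if not m:
        raise RecordParseError(
            f"entry {index}: cannot parse year from {what} field {value!r}", index
        )
    return int(m.group(0))


def _read_ris(text: str) -> list[Record]:
    records: list[Record] = []
    tags: list[tuple[str, str]] = []
    index = 0

    def flush() -> None:
        nonlocal index, tags
        if tags:
            records.append(_record_from_ris(tags, index))
            index += 1
            tags = []

    for line in text.splitlines():
        if not line.strip():
            continue
        m = _RIS_TAG.match(line)
        if m:
            tag, value = m.group(1), m.group(2).strip()
            if tag == "ER":
                flush()
            else:
                tags.append((tag, value))
        elif tags:
            # continuation line of the previous tag
            tag, value = tags[-1]
            tags[-1] = (tag, (value + " " + line.strip()).strip())
        else:
            raise RecordParseError(f"entry {index}: stray line {line!r}", index)
    flush()
    return records


def _first(tags: list[tuple[str, str]], *names: str) -> str | None:
    for tag, value in tags:
        if tag in names and value:
            return value
    return None


def _record_from_ris(tags: list[tuple[str, str]], index: int) -> Record:
    title = _first(tags, "TI", "T1")
    if not title:
        raise RecordParseError(f"entry {index}: missing title (TI/T1)", index)
    year_raw = _first(tags, "PY", "Y1")
    year = _year_from(year_raw, index, "PY") if year_raw else None
    authors = [v for t, v in tags if t in ("AU", "A1") and v]
    return Record(
        record_id=_first(tags, "ID") or f"ris-{index:04d}",
        title=title,
        abstract=_first(tags, "AB", "N2") or "",
        authors=authors,
        year=year,
        journal=_first(tags, "JO", "JF", "T2"),
        source_db=_first(tags, "DB"),
        language=_first(tags, "LA"),
    )


_MEDLINE_TAG = re.compile(r"^([A-Z0-9]{1,4})\s*- (.*)$")


def _read_medline(text: str) -> list[Record]:
    records: list[Record] = []
    for index, block in enumerate(re.split(r"\n\s*\n", text.strip())):
        if not block.strip():
            continue
        tags: list[tuple[str, str]] = []
        for line in block.splitlines():
            if not line.strip():
                continue
            m = _MEDLINE_TAG.match(line)
            if m:
                tags.append((m.group(1), m.group(2).strip()))
            elif line.startswith("      ") and tags:
                tag, value = tags[-1]
                tags[-1] = (tag, (value + " " + line.strip()).strip())
            else:
                raise RecordParseError(f"entry {index}: stray line {line!r}", index)
        title = _first(tags, "TI")
        if not title:
            raise RecordParseError(f"entry {index}: missing title (TI)", index)
        dp = _first(tags, "DP")
        records.append(
            Record(
                record_id=_first(tags, "PMID") or f"medline-{index:04d}",
                title=title,
                abstract=_first(tags, "AB") or "",
                authors=[v for t, v in tags if t == "AU" and v],
                year=_year_from(dp, index, "DP") if dp else None,
                journal=_first(tags, "JT", "TA"),
                source_db="medline",
                language=_first(tags, "LA"),
            )
        )
    return records


def _read_csv(text: str) -> list[Record]:
    reader = csv.DictReader(text.splitlines())
    if reader.fieldnames is None or "title" not in reader.fieldnames:
        raise ConfigurationError("CSV corpus requires a header row with a 'title' column")
    records = []
    for index, row in enumerate(reader):
        title = (row.get("title") or "").strip()
        if not title:
            raise RecordParseError(f"entry {index}: missing title", index)
        year_raw = (row.get("year") or "").strip()
        year = _year_from(year_raw, index, "year") if year_raw else None
        authors_raw = (row.get("authors") or "").strip()
        records.append(
            Record(
                record_id=(row.get("record_id") or "").strip() or f"csv-{index:04d}",
                title=title,
                abstract=(row.get("abstract") or "").strip(),
                authors=[a.strip() for a in authors_raw.split(";") if a.strip()],
                year=year,
                journal=(row.get("journal") or "").strip() or None,
                source_db=(row.get("source_db") or "").strip() or None,
                language=(row.get("language") or "").strip() or None,
            )
        )
    return records


def write_records_csv(records: Iterable[Record], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.title,
                    r.abstract,
                    "; ".join(r.authors),
                    "" if r.year is None else r.year,
                    r.journal or "",
                    r.source_db or "",
                    r.language or "",
                ]
            )


# ---------------------------------------------------------------------------
# corpus XML
#
# Schema: <corpus><record id="..."><title/><abstract/><authors><author/>...
# </authors><year/><journal/><source_db/><language/></record>...</corpus>
# Absent optional fields emit no element; read_records inverts losslessly.


def write_corpus_xml(records: Iterable[Record], path: str | Path) -> None:
    root = ET.Element("corpus")
    for r in records:
        el = ET.SubElement(root, "record", id=r.record_id)
        ET.SubElement(el, "title").text = r.title
        ET.SubElement(el, "abstract").text = r.abstract
        if r.authors:
            authors = ET.SubElement(el, "authors")
            for a in r.authors:
                ET.SubElement(authors, "author").text = a
        if r.year is not None:
            ET.SubElement(el, "year").text = str(r.year)
        for tag in ("journal", "source_db", "language"):
            value = getattr(r, tag)
            if value is not None:
                ET.SubElement(el, tag).text = value
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def _read_corpus_xml(path: Path) -> list[Record]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise RecordParseError(f"malformed corpus XML: {exc}") from exc
    records = []
    for index, el in enumerate(root.findall("record")):
        rid = el.get("id")
        title_el = el.find("title")
        if rid is None or title_el is None or not (title_el.text or "").strip():
            raise RecordParseError(f"entry {index}: record missing id or title", index)
        year_el = el.find("year")
        abstract_el = el.find("abstract")
        records.append(
            Record(
                record_id=rid,
                title=title_el.text or "",
                abstract=(abstract_el.text or "") if abstract_el is not None else "",
                authors=[a.text or "" for a in el.findall("authors/author")],
                year=int(year_el.text) if year_el is not None else None,
                journal=_opt_text(el, "journal"),
                source_db=_opt_text(el, "source_db"),
                language=_opt_text(el, "language"),
            )
        )
    return records


def _opt_text(el: ET.Element, tag: str) -> str | None:
    child = el.find(tag)
    return None if child is None else (child.text or "")


# ---------------------------------------------------------------------------
# deduplication


def _surname(author: str) -> str | None:
    author = author.strip()
    if not author:
        return None
    if "," in author:
        return author.split(",", 1)[0].strip().casefold() or None
    return author.split()[-1].casefold()


def dedup_key(record: Record) -> DedupKey:
    return DedupKey(
        norm_title=normalize_title(record.title),
        year=record.year,
        first_author_surname=_surname(record.authors[0]) if record.authors else None,
    )


def _years_compatible(a: int | None, b: int | None) -> bool:
    return a is None or b is None or a == b


def _token_jaccard(a: str, b: str) -> float:
    ta, tb = set(a.split()), set(b.split())
    if not ta and not tb:
        return 1.0
    return len(ta & tb) / len(ta | tb)


def deduplicate(
    records: list[Record], fuzzy_jaccard: float | None = None
) -> tuple[list[Record], DedupReport]:
    """Remove duplicates (first-seen wins, input order preserved).

    Two records are duplicates iff their normalized titles match exactly and
    their years are equal or either is absent. ``fuzzy_jaccard`` optionally
    also merges titles whose token Jaccard similarity reaches the threshold
    (off by default).
    """
    ids = [r.record_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("record_ids must be unique before deduplication")
    kept: list[Record] = []
    kept_keys: list[DedupKey] = []
    clusters: dict[str, list[str]] = {}
    for record in records:
        key = dedup_key(record)
        match_id = None
        for kr, kk in zip(kept, kept_keys):
            if not _years_compatible(kk.year, key.year):
                continue
            if kk.norm_title == key.norm_title or (
                fuzzy_jaccard is not None
                and _token_jaccard(kk.norm_title, key.norm_title) >= fuzzy_jaccard
            ):
                match_id = kr.record_id
                break
        if match_id is None:
            kept.append(record)
            kept_keys.append(key)
        else:
            clusters.setdefault(match_id, []).append(record.record_id)
    report = DedupReport(
        input_count=len(records),
        unique_count=len(kept),
        removed_count=len(records) - len(kept),
        clusters=[(k, tuple(v)) for k, v in clusters.items()],
    )
    report.validate()
    return kept, report
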