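"""Full-text document parsing and entity-lexicon loading.

Published localisation studies arrive either as XML-tagged documents (a
JATS-like dialect) or as plain text with section headers.  Only the three
subsections likely to carry subcellular evidence are kept: the abstract, the
results (figure captions folded in) and the materials & methods.  Entity
lexicons — protein names with synonyms, compartment names, methodology terms —
are plain term lists with an optional canonical-form column.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from lxml import etree

SECTION_NAMES = ("abstract", "results", "methods")

CATEGORIES = ("protein", "location", "method")

#: header text -> canonical section name (case-insensitive full-line match)
_SECTION_PATTERNS = (
    ("abstract", re.compile(r"^\s*(?:\d+\.?\s*)?abstract\s*$", re.IGNORECASE)),
    ("results", re.compile(r"^\s*(?:\d+\.?\s*)?results?(?:\s+and\s+discussion)?\s*$", re.IGNORECASE)),
    ("methods", re.compile(r"^\s*(?:\d+\.?\s*)?(?:materials?\s+and\s+methods|methods)\s*$", re.IGNORECASE)),
)

_CAPTION_RE = re.compile(r"^\s*(?:figure|fig\.)\s*\d+", re.IGNORECASE)


class DocumentError(ValueError):
    """Raised for malformed or empty input documents."""


class LexiconError(ValueError):
    """Raised for malformed lexicon files."""


def _normalize(text: str) -> str:
    """NFC-normalize (typographic hyphens/Greek variants) and collapse whitespace."""
    text = unicodedata.normalize("NFC", text)
    text = text.replace("‐", "-").replace("‑", "-").replace("–", "-")
    return re.sub(r"[ \t]+", " ", text).strip()


@dataclass
class DocumentRecord:
    """One article reduced to its informative sections."""

    doc_id: str
    sections: dict[str, str]
    source_format: str = "txt"

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise DocumentError("doc_id must be non-empty")
        unknown = set(self.sections) - set(SECTION_NAMES)
        if unknown:
            raise DocumentError(f"unknown section names: {sorted(unknown)}")
        if not self.sections:
            raise DocumentError(f"{self.doc_id}: no recognizable section found")

    def to_json(self) -> str:
        return json.dumps(
            {"doc_id": self.doc_id, "sections": self.sections, "source_format": self.source_format},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "DocumentRecord":
        d = json.loads(line)
        return cls(doc_id=d["doc_id"], sections=d["sections"], source_format=d.get("source_format", "txt"))


def serialize_document(record: DocumentRecord) -> str:
    """Render a record in the plain-text dialect (header lines + section bodies)."""
    headers = {"abstract": "Abstract", "results": "Results", "methods": "Materials and Methods"}
    parts = []
    for name in SECTION_NAMES:
        if name in record.sections:
            parts.append(headers[name] + "\n\n" + record.sections[name])
    return "\n\n".join(parts) + "\n"


def _classify_header(line: str) -> str | None:
    for name, pat in _SECTION_PATTERNS:
        if pat.match(line):
            return name
    return None


def _parse_txt(raw: str, doc_id: str) -> dict[str, str]:
    sections: dict[str, list[str]] = {}
    captions: list[str] = []
    current: str | None = None
    for line in raw.splitlines():
        name = _classify_header(line)
        if name is not None:
            current = name
            sections.setdefault(current, [])
            continue
        if current is None:
            continue
        if _CAPTION_RE.match(line):
            captions.append(line.strip())
            continue
        sections[current].append(line)
    out = {}
    for name, lines in sections.items():
        text = _normalize("\n".join(lines))
        if text:
            out[name] = text
    if captions:
        cap = _normalize(" ".join(captions))
        out["results"] = (out.get("results", "") + " " + cap).strip()
    return out


def _sec_title(sec: etree._Element) -> str:
    title = sec.get("title") or sec.get("sec-type") or ""
    if not title:
        child = sec.find("title")
        if child is not None:
            title = "".join(child.itertext())
    return title


def _text_of(el: etree._Element, skip: set[str]) -> str:
    """Concatenate text content, skipping listed child tags."""
    parts = []

    def walk(node: etree._Element) -> None:
        if node.tag in skip:
            return
        if node.text:
            parts.append(node.text)
        for ch in node:
            walk(ch)
            if ch.tail:
                parts.append(ch.tail)

    walk(el)
    return " ".join(parts)


def _parse_xml(raw: str, doc_id: str) -> dict[str, str]:
    try:
        root = etree.fromstring(raw.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise DocumentError(f"{doc_id}: malformed XML — {exc}") from exc
    sections: dict[str, list[str]] = {}
    for abstract in root.iter("abstract"):
        sections.setdefault("abstract", []).append(_text_of(abstract, skip={"title"}))
    captions: list[str] = []
    for sec in root.iter("sec"):
        name = _classify_header(_sec_title(sec))
        if name is None:
            continue
        for cap in sec.iter("caption"):
            captions.append(_text_of(cap, skip=set()))
        sections.setdefault(name, []).append(_text_of(sec, skip={"title", "caption"}))
    # captions outside recognized sections still belong with results
    for fig in root.iter("fig"):
        for cap in fig.iter("caption"):
            t = _text_of(cap, skip=set())
            if t and not any(t in c for c in captions):
                captions.append(t)
    out = {}
    for name, chunks in sections.items():
        text = _normalize(" ".join(chunks))
        if text:
            out[name] = text
    if captions:
        # deduplicate while preserving order
        seen: set[str] = set()
        uniq = [c for c in (_normalize(c) for c in captions) if c and not (c in seen or seen.add(c))]
        if uniq:
            out["results"] = (out.get("results", "") + " " + " ".join(uniq)).strip()
    return out


def parse_document(raw: str, format: str, doc_id: str) -> DocumentRecord:
    """Parse one article into a :class:`DocumentRecord`.

    Parameters
    ----------
    raw:
        Full document content.
    format:
        ``"xml"`` for the JATS-like dialect (``<abstract>``, ``<sec title=...>``),
        ``"txt"`` for plain text with section-header lines.
    doc_id:
        PubMed ID or DOI used downstream for paper-disjoint data splits.
    """
    if format not in ("xml", "txt"):
        raise ValueError(f"unknown format {format!r}")
    sections = _parse_xml(raw, doc_id) if format == "xml" else _parse_txt(raw, doc_id)
    if not sections:
        raise DocumentError(f"{doc_id}: no recognizable section found")
    return DocumentRecord(doc_id=doc_id, sections=sections, source_format=format)


@dataclass
class Lexicon:
    """Case-insensitive term list for one entity category."""

    category: str
    terms: set[str] = field(default_factory=set)
    synonym_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise LexiconError(f"unknown lexicon category {self.category!r}")

    @staticmethod
    def fold(surface: str) -> str:
        return _normalize(surface).casefold()

    def add(self, surface: str, canonical: str | None = None) -> None:
        canonical = _normalize(canonical if canonical is not None else surface)
        key = self.fold(surface)
        if not key:
            raise LexiconError("empty term")
        existing = self.synonym_map.get(key)
        if existing is not None:
            if self.fold(existing) == self.fold(canonical):
                return  # case variant of an already-loaded entry
            raise LexiconError(
                f"synonym {surface!r} maps to both {existing!r} and {canonical!r}"
            )
        self.terms.add(canonical)
        self.synonym_map[key] = canonical
        self.synonym_map.setdefault(self.fold(canonical), canonical)

    def lookup(self, surface: str) -> str | None:
        """Canonical term for a surface form, or None if not in the lexicon."""
        return self.synonym_map.get(self.fold(surface))

    def surfaces(self) -> list[str]:
        """All matchable surface forms, longest first (for longest-match semantics)."""
        return sorted(self.synonym_map, key=lambda s: (-len(s), s))

    @classmethod
    def from_terms(cls, category: str, terms: Iterable[str]) -> "Lexicon":
        lex = cls(category)
        for t in terms:
            lex.add(t)
        return lex


def load_lexicon(path: str | Path, category: str) -> Lexicon:
    """Load a TSV lexicon: ``surface`` or ``surface<TAB>canonical``, one per line."""
    path = Path(path)
    lex = Lexicon(category)
    n_loaded = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) > 2:
            raise LexiconError(f"{path.name}:{lineno}: expected at most 2 columns, got {len(cols)}")
        surface = cols[0].strip()
        canonical = cols[1].strip() if len(cols) == 2 else None
        if not surface:
            raise LexiconError(f"{path.name}:{lineno}: empty term")
        lex.add(surface, canonical)
        n_loaded += 1
    if n_loaded == 0:
        raise LexiconError(f"{path.name}: lexicon file is empty")
    return lex


def write_corpus(records: Iterable[DocumentRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_corpus(path: str | Path) -> list[DocumentRecord]:
    with open(path, encoding="utf-8") as fh:
        return [DocumentRecord.from_json(line) for line in fh if line.strip()]
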