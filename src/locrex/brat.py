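"""BRAT standoff reading/writing and schema validation.

The annotation schema distinguishes four protein-like entity types (plain
protein names, fluorophore-tagged proteins such as ``SUVR2a-GFP``, mutated or
truncated variants, and locus identifiers), methodology terms, subcellular
locations and two bookkeeping entity types.  Relations are pairwise and always
anchored on the protein: ``Located_In`` / ``Not_Located_In`` tie a protein to a
compartment, ``Subcellular_methodology`` ties it to the technique that
established the location.  Tagged proteins concatenate protein and methodology
in one surface form; sub-labels (serialized as annotator-note lines, since
standoff has no native sub-span record) mark which part is which.

Offsets are 0-based half-open Unicode code-point indices, BRAT's convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

ENTITY_TYPES = (
    "Protein",
    "Tagged_Protein",
    "Protein_variant",
    "Protein_Locus",
    "Methodology",
    "Subcellular_Location",
    "Identifier",
    "Gene_Locus",
)

RELATION_TYPES = (
    "Located_In",
    "Not_Located_In",
    "Subcellular_methodology",
    "Protein_identifier",
    "Locus_link",
)

#: allowed (entity1, entity2, relation) rows of the annotation schema
SCHEMA_ROWS: frozenset[tuple[str, str, str]] = frozenset(
    {
        ("Protein", "Subcellular_Location", "Located_In"),
        ("Tagged_Protein", "Subcellular_Location", "Located_In"),
        ("Protein", "Methodology", "Subcellular_methodology"),
        ("Protein_Locus", "Subcellular_Location", "Located_In"),
        ("Protein_Locus", "Methodology", "Subcellular_methodology"),
        ("Protein_variant", "Subcellular_Location", "Located_In"),
        ("Protein_variant", "Methodology", "Subcellular_methodology"),
        ("Protein", "Identifier", "Protein_identifier"),
        ("Protein", "Gene_Locus", "Locus_link"),
        ("Protein", "Subcellular_Location", "Not_Located_In"),
        ("Tagged_Protein", "Subcellular_Location", "Not_Located_In"),
    }
)

#: entity types that can fill the protein slot of a candidate triplet
PROTEIN_GROUP = frozenset({"Protein", "Tagged_Protein", "Protein_variant", "Protein_Locus"})


class StandoffError(ValueError):
    """Malformed standoff input or annotation/text integrity violation."""


@dataclass(frozen=True)
class EntityAnnotation:
    ann_id: str
    etype: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not re.fullmatch(r"T\d+", self.ann_id):
            raise StandoffError(f"entity id must be T-prefixed: {self.ann_id!r}")
        if self.etype not in ENTITY_TYPES:
            raise StandoffError(f"{self.ann_id}: unknown entity type {self.etype!r}")
        if not 0 <= self.start < self.end:
            raise StandoffError(f"{self.ann_id}: invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class RelationAnnotation:
    ann_id: str
    rtype: str
    arg1: str
    arg2: str

    def __post_init__(self) -> None:
        if not re.fullmatch(r"R\d+", self.ann_id):
            raise StandoffError(f"relation id must be R-prefixed: {self.ann_id!r}")
        if self.rtype not in RELATION_TYPES:
            raise StandoffError(f"{self.ann_id}: unknown relation type {self.rtype!r}")


@dataclass(frozen=True)
class SubLabel:
    """Protein-part / method-part sub-spans of a Tagged_Protein (absolute offsets)."""

    protein_span: tuple[int, int]
    method_span: tuple[int, int]


@dataclass
class AnnotatedSentence:
    sent_id: str
    text: str
    entities: list[EntityAnnotation] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)
    sub_labels: dict[str, SubLabel] = field(default_factory=dict)
    doc_id: str = ""

    def __post_init__(self) -> None:
        self.check_integrity()

    def check_integrity(self) -> None:
        ids = {e.ann_id for e in self.entities}
        if len(ids) != len(self.entities):
            raise StandoffError(f"{self.sent_id}: duplicate entity ids")
        for e in self.entities:
            if e.end > len(self.text):
                raise StandoffError(f"{self.sent_id}/{e.ann_id}: span exceeds text length")
            if self.text[e.start:e.end] != e.surface:
                raise StandoffError(
                    f"{self.sent_id}/{e.ann_id}: surface {e.surface!r} != text slice "
                    f"{self.text[e.start:e.end]!r}"
                )
        for r in self.relations:
            for arg in (r.arg1, r.arg2):
                if arg not in ids:
                    raise StandoffError(f"{self.sent_id}/{r.ann_id}: dangling argument {arg}")
        for tid, sub in self.sub_labels.items():
            if tid not in ids:
                raise StandoffError(f"{self.sent_id}: sub-label for unknown entity {tid}")
            ent = self.entity(tid)
            for a, b in (sub.protein_span, sub.method_span):
                if not (ent.start <= a < b <= ent.end):
                    raise StandoffError(f"{self.sent_id}/{tid}: sub-span outside entity span")

    def entity(self, ann_id: str) -> EntityAnnotation:
        for e in self.entities:
            if e.ann_id == ann_id:
                return e
        raise KeyError(ann_id)

    def entities_of(self, *etypes: str) -> list[EntityAnnotation]:
        return sorted((e for e in self.entities if e.etype in etypes), key=lambda e: (e.start, e.ann_id))


def validate_schema(sentence: AnnotatedSentence) -> list[str]:
    """Schema violations: relations whose (etype1, etype2, rtype) is not an allowed row."""
    violations = []
    ents = {e.ann_id: e for e in sentence.entities}
    for r in sentence.relations:
        if r.arg1 not in ents or r.arg2 not in ents:
            violations.append(f"{r.ann_id}: dangling argument")
            continue
        row = (ents[r.arg1].etype, ents[r.arg2].etype, r.rtype)
        if row not in SCHEMA_ROWS:
            violations.append(
                f"{r.ann_id}: ({row[0]}, {row[1]}) is not an allowed argument pair for {r.rtype}"
            )
    return violations


def _ann_sort_key(ann_id: str) -> int:
    return int(ann_id[1:])


def format_standoff(sentence: AnnotatedSentence) -> str:
    """Canonical .ann content: T lines, then R lines, then sub-label notes."""
    lines = []
    for e in sorted(sentence.entities, key=lambda e: _ann_sort_key(e.ann_id)):
        lines.append(f"{e.ann_id}\t{e.etype} {e.start} {e.end}\t{e.surface}")
    for r in sorted(sentence.relations, key=lambda r: _ann_sort_key(r.ann_id)):
        lines.append(f"{r.ann_id}\t{r.rtype} Arg1:{r.arg1} Arg2:{r.arg2}")
    for i, tid in enumerate(sorted(sentence.sub_labels, key=_ann_sort_key), start=1):
        sub = sentence.sub_labels[tid]
        lines.append(
            f"#{i}\tSubLabel {tid}\tprotein {sub.protein_span[0]} {sub.protein_span[1]} "
            f"method {sub.method_span[0]} {sub.method_span[1]}"
        )
    return "".join(line + "\n" for line in lines)


_NOTE_RE = re.compile(
    r"protein (\d+) (\d+) method (\d+) (\d+)\s*$"
)


def parse_standoff(text: str, ann_content: str, sent_id: str, doc_id: str = "") -> AnnotatedSentence:
    """Build an :class:`AnnotatedSentence` from raw .txt content and .ann content."""
    entities: list[EntityAnnotation] = []
    relations: list[RelationAnnotation] = []
    sub_labels: dict[str, SubLabel] = {}
    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag.startswith("T"):
            if len(fields) < 3:
                raise StandoffError(f"{sent_id}:{lineno}: malformed entity line")
            etype, start, end = fields[1].split(" ")
            entities.append(EntityAnnotation(tag, etype, int(start), int(end), fields[2]))
        elif tag.startswith("R"):
            m = re.fullmatch(r"(\S+) Arg1:(\S+) Arg2:(\S+)", fields[1].strip())
            if m is None:
                raise StandoffError(f"{sent_id}:{lineno}: malformed relation line")
            relations.append(RelationAnnotation(tag, m.group(1), m.group(2), m.group(3)))
        elif tag.startswith("#"):
            if len(fields) < 3 or not fields[1].startswith("SubLabel "):
                continue  # foreign note lines are ignored
            tid = fields[1].split(" ", 1)[1].strip()
            m = _NOTE_RE.fullmatch(fields[2])
            if m is None:
                raise StandoffError(f"{sent_id}:{lineno}: malformed SubLabel note")
            a, b, c, d = (int(g) for g in m.groups())
            sub_labels[tid] = SubLabel(protein_span=(a, b), method_span=(c, d))
        elif tag.startswith("A"):
            continue  # attribute lines not used by this schema
        else:
            raise StandoffError(f"{sent_id}:{lineno}: unsupported record {tag!r}")
    return AnnotatedSentence(
        sent_id=sent_id, text=text, entities=entities, relations=relations,
        sub_labels=sub_labels, doc_id=doc_id,
    )


def read_standoff(txt_path: str | Path, ann_path: str | Path, doc_id: str = "") -> AnnotatedSentence:
    """Read a BRAT .txt/.ann pair; surfaces are verified against the text slices."""
    txt_path, ann_path = Path(txt_path), Path(ann_path)
    text = txt_path.read_text(encoding="utf-8")
    if text.endswith("\n"):
        text = text[:-1]
    return parse_standoff(text, ann_path.read_text(encoding="utf-8"), sent_id=txt_path.stem, doc_id=doc_id)


def write_standoff(sentence: AnnotatedSentence, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the .txt/.ann pair; ``read_standoff`` of the output round-trips."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    txt = out_dir / f"{sentence.sent_id}.txt"
    ann = out_dir / f"{sentence.sent_id}.ann"
    txt.write_text(sentence.text + "\n", encoding="utf-8")
    ann.write_text(format_standoff(sentence), encoding="utf-8")
    return txt, ann


def write_annotation_conf(out_dir: str | Path) -> Path:
    """Emit a BRAT annotation.conf mirroring the entity/relation schema."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["[entities]"] + list(ENTITY_TYPES) + ["", "[relations]"]
    for e1, e2, rt in sorted(SCHEMA_ROWS, key=lambda row: (row[2], row[0], row[1])):
        lines.append(f"{rt}\tArg1:{e1}, Arg2:{e2}")
    lines += ["", "[events]", "", "[attributes]"]
    path = out_dir / "annotation.conf"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
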