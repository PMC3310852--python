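"""Six-way relationship typology over parent-child hierarchy edges.

Every parent-child link in a classification is read, by default, as
subsumption (is-a).  The audit vocabulary adds four process predicates
drawn from an upper ontology (SubProcess, Agent, Patient, Instrument)
plus Complexity, which has no upper-ontology counterpart and is kept as
an annotation-level distinction between simple and complex variants of
an activity.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .codes import chapter_of, classify_code
from .errors import IntegrityError, VocabularyError
from .model import Classification, ClassificationConcept

if TYPE_CHECKING:  # pragma: no cover
    from .stats import RelationshipCountTable

__all__ = [
    "RelationshipType",
    "CodedEdge",
    "EdgeAnnotation",
    "enumerate_edges",
    "load_annotations",
    "write_annotations",
    "suggest_relationship",
    "default_lexicon",
    "tabulate",
]


class RelationshipType(enum.Enum):
    """The six admissible edge relationship types."""

    SUBSUMPTION = "Subsumption"
    SUBPROCESS = "SubProcess"
    AGENT = "Agent"
    PATIENT = "Patient"
    INSTRUMENT = "Instrument"
    COMPLEXITY = "Complexity"

    def __str__(self) -> str:
        return self.value

    @property
    def from_upper_ontology(self) -> bool:
        """Whether the relation is grounded in the upper ontology's
        process predicates (Complexity is not)."""
        return self is not RelationshipType.COMPLEXITY

    @classmethod
    def from_string(cls, name: str) -> "RelationshipType":
        key = name.strip().lower().replace("_", "").replace("-", "")
        for member in cls:
            if member.value.lower() == key:
                return member
        legal = ", ".join(m.value for m in cls)
        raise VocabularyError(f"unknown relationship {name!r}; legal values: {legal}")


RELATION_NAMES: tuple[str, ...] = tuple(m.value for m in RelationshipType)


@dataclass(frozen=True)
class CodedEdge:
    """A logical parent->child link, tagged with its hierarchy level.

    ``level`` is ``top`` when the parent is a chapter (blocks being
    transparent), ``lower`` otherwise.
    """

    parent_code: str
    child_code: str
    level: str

    def __post_init__(self) -> None:
        if self.level not in ("top", "lower"):
            raise ValueError(f"level must be 'top' or 'lower', not {self.level!r}")

    @classmethod
    def from_codes(cls, parent_code: str, child_code: str) -> "CodedEdge":
        level = "top" if classify_code(parent_code).kind == "chapter" else "lower"
        return cls(parent_code, child_code, level)

    @property
    def chapter(self) -> str:
        """Chapter code both endpoints belong to; raises on disagreement."""
        pc, cc = chapter_of(self.parent_code), chapter_of(self.child_code)
        if pc != cc:
            raise IntegrityError(
                f"edge {self.parent_code} -> {self.child_code} spans chapters {pc} and {cc}"
            )
        return pc


@dataclass(frozen=True)
class EdgeAnnotation:
    """One relationship assignment for one edge."""

    edge: CodedEdge
    relation: RelationshipType
    note: str = ""


def enumerate_edges(c: Classification, include_residual: bool = False) -> list[CodedEdge]:
    """All logical parent-child edges of *c*, blocks collapsed,
    residual endpoints excluded unless requested."""
    return [
        CodedEdge.from_codes(p, ch)
        for p, ch in c.iter_logical_edges(include_residual=include_residual)
    ]


# ---------------------------------------------------------------------------
# Annotation table I/O

_HEADER = ("parent_code", "child_code", "relation", "note")


def load_annotations(text: str, classification: Classification | None = None) -> list[EdgeAnnotation]:
    """Parse an annotation TSV (parent, child, relation[, note]).

    Lines starting with ``#`` are comments.  Relation names are matched
    case-insensitively.  Duplicate parent-child pairs and, when a
    classification is supplied, edges absent from it are rejected.
    """
    annotations: list[EdgeAnnotation] = []
    seen: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if tuple(p.strip() for p in parts[:4]) == _HEADER[: len(parts)]:
            continue  # header row
        if len(parts) < 3:
            raise IntegrityError(
                f"line {lineno}: expected at least 3 tab-separated fields, got {len(parts)}"
            )
        parent, child, relname = (p.strip() for p in parts[:3])
        note = parts[3].strip() if len(parts) > 3 else ""
        if (parent, child) in seen:
            raise IntegrityError(f"line {lineno}: duplicate edge {parent} -> {child}")
        seen.add((parent, child))
        relation = RelationshipType.from_string(relname)
        edge = CodedEdge.from_codes(parent, child)
        if classification is not None:
            _check_edge(edge, classification)
        annotations.append(EdgeAnnotation(edge, relation, note))
    return annotations


def _check_edge(edge: CodedEdge, c: Classification) -> None:
    for code in (edge.parent_code, edge.child_code):
        if code not in c:
            raise IntegrityError(f"edge references unknown code {code}")
    actual = c.logical_parent_code(edge.child_code)
    if actual != edge.parent_code:
        raise IntegrityError(
            f"{edge.child_code} is not a (logical) child of {edge.parent_code}"
            + (f"; its parent is {actual}" if actual else "")
        )


def write_annotations(annotations: Iterable[EdgeAnnotation]) -> str:
    lines = ["\t".join(_HEADER)]
    for a in annotations:
        lines.append(f"{a.edge.parent_code}\t{a.edge.child_code}\t{a.relation.value}\t{a.note}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Rule-based suggestion from lexical cues

#: Default cue lexicon.  Advisory only: curated annotation tables always
#: override suggestions.  Editable copies can be loaded from YAML via the
#: CLI.  Patient has no reliable lexical cue (the object of an activity
#: is rarely signalled by a fixed phrase), so its default list is empty.
_DEFAULT_LEXICON: dict[str, tuple[str, ...]] = {
    "SubProcess": ("starting", "sustaining", "ending", "completing", "initiating",
                   "terminating", "preparing"),
    "Agent": ("with one person", "with many people", "one person", "many people",
              "alone", "in a group", "as a member of a group"),
    "Patient": (),
    "Instrument": ("using", "by means of", "with devices", "device", "machine"),
    "Complexity": ("simple", "complex", "single", "multiple"),
}

#: When several cues fire the first matching relation in this order wins.
SUGGESTION_PRECEDENCE = ("SubProcess", "Agent", "Patient", "Instrument", "Complexity")


def default_lexicon() -> dict[str, tuple[str, ...]]:
    return {k: tuple(v) for k, v in _DEFAULT_LEXICON.items()}


def load_lexicon(path) -> dict[str, tuple[str, ...]]:
    """Load an editable cue lexicon from a YAML file (relation -> phrases)."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    lexicon: dict[str, tuple[str, ...]] = {}
    for key, phrases in raw.items():
        relation = RelationshipType.from_string(str(key))
        if relation is RelationshipType.SUBSUMPTION:
            raise VocabularyError("Subsumption is the default and takes no cues")
        lexicon[relation.value] = tuple(str(p) for p in (phrases or []))
    return lexicon


def suggest_relationship(
    parent: ClassificationConcept,
    child: ClassificationConcept,
    lexicon: Mapping[str, Sequence[str]] | None = None,
) -> RelationshipType | None:
    """Suggest a non-subsumption relation from cue phrases in the child
    title, or ``None`` when no cue fires (caller defaults to subsumption)."""
    lex = lexicon if lexicon is not None else _DEFAULT_LEXICON
    title = child.title.lower()
    for relname in SUGGESTION_PRECEDENCE:
        for cue in lex.get(relname, ()):
            if re.search(rf"\b{re.escape(cue.lower())}\b", title):
                return RelationshipType.from_string(relname)
    return None


def suggest_all(
    c: Classification,
    lexicon: Mapping[str, Sequence[str]] | None = None,
) -> list[EdgeAnnotation]:
    """Propose an annotation for every logical non-residual edge,
    defaulting to subsumption when no cue fires."""
    out = []
    for edge in enumerate_edges(c):
        suggestion = suggest_relationship(c[edge.parent_code], c[edge.child_code], lexicon)
        relation = suggestion or RelationshipType.SUBSUMPTION
        note = "suggested" if suggestion else "default"
        out.append(EdgeAnnotation(edge, relation, note))
    return out


# ---------------------------------------------------------------------------


def tabulate(annotations: Iterable[EdgeAnnotation]) -> "RelationshipCountTable":
    """Cross-tabulate annotations per chapter, level and relation."""
    from .stats import RelationshipCountTable

    table = RelationshipCountTable()
    for a in annotations:
        table.add(a.edge.chapter, a.edge.level, a.relation.value)
    return table
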