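"""Classification-to-upper-ontology mapping tables and coverage statistics.

Mappings are curated assertions linking a classification code to a named
concept in an upper ontology.  They are kept strictly at the annotation
level when exported (SKOS-style match properties), never as cross-ontology
subclass axioms: the source mappings are tentative by nature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .codes import classify_code
from .errors import IntegrityError, ParseError, VocabularyError
from .model import Classification
from .rdf import OWL, RDF, SKOS, Graph, IRI, Literal
from .owl_export import DEFAULT_BASE_IRI, OntologyDocument

__all__ = [
    "MATCH_KINDS",
    "LEVELS",
    "MappingEntry",
    "LevelCoverage",
    "CoverageReport",
    "load_mappings",
    "write_mappings",
    "coverage",
    "load_level_totals",
    "export_mapping_annotations",
]

MATCH_KINDS = ("broader", "equivalent", "partial")
LEVELS = ("chapter", "block", "category", "subcategory")

#: SKOS annotation property used per match kind
_MATCH_PROPS = {
    "broader": SKOS + "broadMatch",
    "equivalent": SKOS + "exactMatch",
    "partial": SKOS + "relatedMatch",
}

DEFAULT_TARGET_BASE = "http://www.ontologyportal.org/SUMO.owl"


@dataclass(frozen=True)
class MappingEntry:
    """One code -> upper-ontology concept assertion."""

    source: str
    target: str
    match_kind: str = "broader"
    note: str = ""

    def __post_init__(self) -> None:
        classify_code(self.source)  # raises CodeFormatError on bad codes
        if not self.target:
            raise VocabularyError("mapping target must be non-empty")
        if self.match_kind not in MATCH_KINDS:
            raise VocabularyError(
                f"unknown match kind {self.match_kind!r}; legal values: {', '.join(MATCH_KINDS)}"
            )

    @property
    def level(self) -> str:
        return classify_code(self.source).kind


def load_mappings(text: str) -> list[MappingEntry]:
    """Parse a mapping TSV: source_code, target_concept[, match_kind[, note]].

    ``#`` lines are comments; the match kind defaults to ``broader``;
    duplicate (source, target) pairs are rejected.
    """
    entries: list[MappingEntry] = []
    seen: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if parts[:2] == ["source_code", "target_concept"]:
            continue
        if len(parts) < 2:
            raise ParseError(f"line {lineno}: expected at least 2 tab-separated fields")
        source, target = parts[0], parts[1]
        match_kind = parts[2] if len(parts) > 2 and parts[2] else "broader"
        note = parts[3] if len(parts) > 3 else ""
        if (source, target) in seen:
            raise IntegrityError(f"line {lineno}: duplicate mapping {source} -> {target}")
        seen.add((source, target))
        entries.append(MappingEntry(source, target, match_kind, note))
    return entries


def write_mappings(entries: Iterable[MappingEntry]) -> str:
    lines = ["source_code\ttarget_concept\tmatch_kind\tnote"]
    for e in entries:
        lines.append(f"{e.source}\t{e.target}\t{e.match_kind}\t{e.note}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Coverage


@dataclass(frozen=True)
class LevelCoverage:
    level: str
    mapped: int
    total: int
    unmapped_codes: tuple[str, ...] | None  # None when only totals are known

    @property
    def unmapped(self) -> int:
        return self.total - self.mapped


@dataclass(frozen=True)
class CoverageReport:
    levels: tuple[LevelCoverage, ...]

    def __getitem__(self, level: str) -> LevelCoverage:
        for lc in self.levels:
            if lc.level == level:
                return lc
        raise KeyError(level)

    def to_dict(self) -> dict:
        return {
            lc.level: {
                "mapped": lc.mapped,
                "total": lc.total,
                "unmapped_codes": None if lc.unmapped_codes is None else list(lc.unmapped_codes),
            }
            for lc in self.levels
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def render_tsv(self) -> str:
        lines = ["level\tmapped\ttotal"]
        for lc in self.levels:
            lines.append(f"{lc.level}\t{lc.mapped}\t{lc.total}")
        return "\n".join(lines) + "\n"


def load_level_totals(text: str) -> dict[str, int]:
    """Parse a level-total TSV (columns: level, total)."""
    totals: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in raw.split("\t")]
        if parts[:2] == ["level", "total"]:
            continue
        if len(parts) < 2:
            raise ParseError(f"line {lineno}: expected 2 tab-separated fields")
        level, total = parts[0], parts[1]
        if level not in LEVELS:
            raise VocabularyError(f"line {lineno}: unknown level {level!r}")
        totals[level] = int(total)
    return totals


def coverage(
    mappings: Iterable[MappingEntry],
    levels: Classification | Mapping[str, int] | Sequence[str],
    lenient: bool = False,
) -> CoverageReport:
    """Per-level coverage of *mappings* against a code universe.

    *levels* can be a full :class:`Classification`, a plain sequence of
    codes, or a level -> total mapping when only denominators are known.
    A mapping source outside the supplied universe raises
    :class:`IntegrityError`, or is dropped with a warning when *lenient*.
    """
    mappings = list(mappings)
    codes_by_level: dict[str, list[str]] | None
    if isinstance(levels, Classification):
        codes_by_level = {lv: [] for lv in LEVELS}
        for concept in levels.sorted_concepts():
            codes_by_level.setdefault(concept.kind, []).append(concept.code)
        totals = {lv: len(v) for lv, v in codes_by_level.items()}
    elif isinstance(levels, Mapping):
        codes_by_level = None
        totals = dict(levels)
    else:
        codes_by_level = {lv: [] for lv in LEVELS}
        for code in levels:
            codes_by_level[classify_code(code).kind].append(code)
        codes_by_level = {lv: v for lv, v in codes_by_level.items() if v}
        totals = {lv: len(v) for lv, v in codes_by_level.items()}

    mapped_by_level: dict[str, set[str]] = {lv: set() for lv in totals}
    for entry in mappings:
        level = entry.level
        universe = None if codes_by_level is None else codes_by_level.get(level)
        known = (level in totals) and (universe is None or entry.source in universe)
        if not known:
            msg = f"mapping source {entry.source} ({level}) not in the supplied universe"
            if lenient:
                warnings.warn(msg, stacklevel=2)
                continue
            raise IntegrityError(msg)
        mapped_by_level[level].add(entry.source)

    out = []
    for level in LEVELS:
        if level not in totals:
            continue
        mapped = mapped_by_level.get(level, set())
        unmapped = (
            None
            if codes_by_level is None
            else tuple(cd for cd in codes_by_level.get(level, []) if cd not in mapped)
        )
        out.append(LevelCoverage(level, len(mapped), totals[level], unmapped))
    return CoverageReport(tuple(out))


# ---------------------------------------------------------------------------
# OWL annotation fragment


def export_mapping_annotations(
    mappings: Iterable[MappingEntry],
    base_iri: str = DEFAULT_BASE_IRI,
    target_base: str = DEFAULT_TARGET_BASE,
    dialect: str = "turtle",
) -> OntologyDocument:
    """One cross-ontology match annotation per entry; no logical axioms."""
    base = base_iri.rstrip("#/")
    graph = Graph()
    note_prop = IRI(f"{base}#note")
    used_props: set[str] = set()
    entries = list(mappings)
    for e in entries:
        prop = IRI(_MATCH_PROPS[e.match_kind])
        if str(prop) not in used_props:
            graph.add(prop, IRI(RDF + "type"), IRI(OWL + "AnnotationProperty"))
            used_props.add(str(prop))
        source = IRI(f"{base}#{e.source}")
        graph.add(source, prop, IRI(f"{target_base}#{e.target}"))
        if e.note:
            if "note" not in used_props:
                graph.add(note_prop, IRI(RDF + "type"), IRI(OWL + "AnnotationProperty"))
                used_props.add("note")
            graph.add(source, note_prop, Literal(e.note))
    return OntologyDocument(
        graph=graph,
        ontology_iri=base,
        base_iri=base,
        dialect=dialect,
        prefixes={"cls": base + "#", "sumo": target_base + "#"},
    )
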