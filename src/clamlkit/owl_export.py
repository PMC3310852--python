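"""Render a classification (optionally with edge annotations) as OWL.

Every concept becomes an ``owl:Class`` whose IRI is ``<base>#<code>``;
every logical parent-child edge becomes an ``rdfs:subClassOf`` axiom.
Rubrics are annotations: the preferred title is ``rdfs:label``, the
remaining rubric kinds get dedicated annotation properties.  Inclusion
and exclusion rubrics are *never* turned into logical axioms (no
disjointness is asserted).

Two annotated-export modes exist.  The default is non-destructive: the
full subclass hierarchy is kept and each non-subsumption edge gains an
annotation naming the proposed relation.  Strict mode operationalizes
the proposal: non-subsumption subclass axioms are replaced by an
existential restriction on the matching object property, except for
Complexity, which stays at the annotation level because it has no
upper-ontology grounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import IntegrityError
from .model import Classification
from .rdf import OWL, RDF, RDFS, BNode, Graph, IRI, Literal, serialize
from .relationships import EdgeAnnotation, RelationshipType

__all__ = ["OntologyDocument", "to_owl", "to_owl_annotated", "DEFAULT_BASE_IRI"]

DEFAULT_BASE_IRI = "http://clamlkit.example.org/classification"

_RUBRIC_PROPS = {
    "definition": "definition",
    "inclusion": "inclusion",
    "exclusion": "exclusion",
    "coding-hint": "codingHint",
    "other": "note",
}

#: object properties used in strict mode, one per upper-ontology predicate
_OBJECT_PROPS = {
    RelationshipType.SUBPROCESS: "subProcess",
    RelationshipType.AGENT: "agent",
    RelationshipType.PATIENT: "patient",
    RelationshipType.INSTRUMENT: "instrument",
}


@dataclass
class OntologyDocument:
    """An OWL rendering: a triple graph plus serialization preferences."""

    graph: Graph
    ontology_iri: str
    base_iri: str
    dialect: str = "turtle"
    prefixes: dict[str, str] = field(default_factory=dict)

    def serialize(self, dialect: str | None = None) -> str:
        return serialize(self.graph, dialect or self.dialect, self.prefixes)

    def class_iris(self) -> set[IRI]:
        return {s for s in self.graph.subjects(IRI(RDF + "type"), IRI(OWL + "Class"))
                if isinstance(s, IRI)}

    def subclass_axioms(self) -> list[tuple]:
        return self.graph.triples(None, IRI(RDFS + "subClassOf"), None)


class _Builder:
    def __init__(self, base_iri: str, dialect: str):
        self.base = base_iri.rstrip("#/")
        self.graph = Graph()
        self.dialect = dialect
        self._seen_iris: dict[str, str] = {}
        self._bnode_counter = 0

    def iri(self, code: str) -> IRI:
        candidate = f"{self.base}#{code}"
        owner = self._seen_iris.setdefault(candidate, code)
        if owner != code:
            raise IntegrityError(f"IRI collision: {candidate} for both {owner} and {code}")
        return IRI(candidate)

    def bnode(self) -> BNode:
        self._bnode_counter += 1
        return BNode(f"b{self._bnode_counter}")

    def declare_annotation_property(self, local: str) -> IRI:
        prop = IRI(f"{self.base}#{local}")
        self.graph.add(prop, IRI(RDF + "type"), IRI(OWL + "AnnotationProperty"))
        return prop

    def declare_object_property(self, local: str) -> IRI:
        prop = IRI(f"{self.base}#{local}")
        self.graph.add(prop, IRI(RDF + "type"), IRI(OWL + "ObjectProperty"))
        return prop

    def document(self) -> OntologyDocument:
        ontology_iri = self.base
        self.graph.add(IRI(ontology_iri), IRI(RDF + "type"), IRI(OWL + "Ontology"))
        return OntologyDocument(
            graph=self.graph,
            ontology_iri=ontology_iri,
            base_iri=self.base,
            dialect=self.dialect,
            prefixes={"cls": self.base + "#"},
        )


def to_owl(
    c: Classification,
    base_iri: str = DEFAULT_BASE_IRI,
    dialect: str = "turtle",
    include_residuals: bool = True,
    blocks: str = "class",
) -> OntologyDocument:
    """Render *c* as an OWL ontology.

    ``blocks="class"`` keeps block concepts as classes with the raw
    chapter -> block -> category chain; ``blocks="annotation"`` drops them
    as classes, rewires subclass axioms along logical edges, and records
    block membership as a ``block`` annotation on the member classes.
    """
    if blocks not in ("class", "annotation"):
        raise ValueError(f"blocks must be 'class' or 'annotation', not {blocks!r}")
    b = _Builder(base_iri, dialect)
    code_prop = b.declare_annotation_property("code")
    rubric_props = {k: b.declare_annotation_property(v) for k, v in _RUBRIC_PROPS.items()}
    block_prop = b.declare_annotation_property("block") if blocks == "annotation" else None

    def included(code: str) -> bool:
        concept = c[code]
        if concept.kind == "block" and blocks == "annotation":
            return False
        if not include_residuals and concept.is_residual:
            return False
        return True

    for concept in c.sorted_concepts():
        if not included(concept.code):
            continue
        iri = b.iri(concept.code)
        b.graph.add(iri, IRI(RDF + "type"), IRI(OWL + "Class"))
        b.graph.add(iri, code_prop, Literal(concept.code))
        for rubric in concept.rubrics:
            if rubric.kind == "preferred":
                b.graph.add(iri, IRI(RDFS + "label"), Literal(rubric.text, lang="en"))
            else:
                b.graph.add(iri, rubric_props[rubric.kind], Literal(rubric.text))
        parent = (
            c.logical_parent_code(concept.code)
            if blocks == "annotation"
            else concept.parent_code
        )
        if parent is not None and included(parent):
            b.graph.add(iri, IRI(RDFS + "subClassOf"), b.iri(parent))
        if block_prop is not None and concept.parent_code is not None:
            if c[concept.parent_code].kind == "block":
                b.graph.add(iri, block_prop, Literal(concept.parent_code))
    return b.document()


def to_owl_annotated(
    c: Classification,
    annotations: Iterable[EdgeAnnotation],
    strict: bool = False,
    base_iri: str = DEFAULT_BASE_IRI,
    dialect: str = "turtle",
    include_residuals: bool = True,
    blocks: str = "class",
) -> OntologyDocument:
    """Render *c* with relationship annotations applied to its edges.

    Default mode only *adds* triples (one ``proposedRelation`` annotation
    per non-subsumption edge).  Strict mode removes the subclass axiom of
    each non-subsumption edge and substitutes an existential restriction
    (or, for Complexity, a ``complexity`` annotation derived from the
    child title).
    """
    annotations = list(annotations)
    valid_edges = {
        (p, ch) for p, ch in c.iter_logical_edges(include_residual=True)
    }
    for a in annotations:
        if (a.edge.parent_code, a.edge.child_code) not in valid_edges:
            raise IntegrityError(
                f"annotation references edge {a.edge.parent_code} -> {a.edge.child_code} "
                f"which is not a logical edge of the classification"
            )

    doc = to_owl(c, base_iri=base_iri, dialect=dialect,
                 include_residuals=include_residuals, blocks=blocks)
    b = _Builder(base_iri, dialect)  # namespace helper only
    graph = doc.graph

    interesting = [a for a in annotations if a.relation is not RelationshipType.SUBSUMPTION]
    if not interesting:
        return doc

    if not strict:
        prop = IRI(f"{b.base}#proposedRelation")
        graph.add(prop, IRI(RDF + "type"), IRI(OWL + "AnnotationProperty"))
        for a in interesting:
            child = IRI(f"{b.base}#{a.edge.child_code}")
            graph.add(child, prop, Literal(f"{a.relation.value} of {a.edge.parent_code}"))
        return doc

    complexity_prop: IRI | None = None
    declared_props: dict[RelationshipType, IRI] = {}
    counter = 0
    for a in interesting:
        child = IRI(f"{b.base}#{a.edge.child_code}")
        parent = IRI(f"{b.base}#{a.edge.parent_code}")
        graph.discard(child, IRI(RDFS + "subClassOf"), parent)
        if a.relation is RelationshipType.COMPLEXITY:
            if complexity_prop is None:
                complexity_prop = IRI(f"{b.base}#complexity")
                graph.add(complexity_prop, IRI(RDF + "type"), IRI(OWL + "AnnotationProperty"))
            value = "complex" if "complex" in c[a.edge.child_code].title.lower() else "simple"
            graph.add(child, complexity_prop, Literal(value))
        else:
            prop = declared_props.get(a.relation)
            if prop is None:
                prop = IRI(f"{b.base}#{_OBJECT_PROPS[a.relation]}")
                graph.add(prop, IRI(RDF + "type"), IRI(OWL + "ObjectProperty"))
                declared_props[a.relation] = prop
            counter += 1
            restriction = BNode(f"r{counter}")
            graph.add(child, IRI(RDFS + "subClassOf"), restriction)
            graph.add(restriction, IRI(RDF + "type"), IRI(OWL + "Restriction"))
            graph.add(restriction, IRI(OWL + "onProperty"), prop)
            graph.add(restriction, IRI(OWL + "someValuesFrom"), parent)
    return doc
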