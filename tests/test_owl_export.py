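import pytest

from clamlkit.errors import IntegrityError
from clamlkit.model import Classification
from clamlkit.owl_export import DEFAULT_BASE_IRI, to_owl, to_owl_annotated
from clamlkit.rdf import OWL, RDF, RDFS, IRI, parse
from clamlkit.relationships import (
    CodedEdge,
    EdgeAnnotation,
    RelationshipType,
    enumerate_edges,
)

BASE = DEFAULT_BASE_IRI


def reparse(doc, dialect="turtle"):
    """Independent re-parse of the serialized output."""
    return parse(doc.serialize(dialect), dialect)


def named_classes(g):
    return {s for s in g.subjects(IRI(RDF + "type"), IRI(OWL + "Class"))}


def subclass_axioms_to_named(g):
    return [
        (s, o) for s, _, o in g.triples(None, IRI(RDFS + "subClassOf"), None)
        if isinstance(o, IRI)
    ]


class TestToOwl:
    def test_empty_classification(self):
        doc = to_owl(Classification())
        g = reparse(doc)
        assert named_classes(g) == set()
        assert (IRI(doc.ontology_iri), IRI(RDF + "type"), IRI(OWL + "Ontology")) in g

    def test_three_concept_chain_counts(self, chain3):
        g = reparse(to_owl(chain3))
        assert len(named_classes(g)) == 3
        assert len(subclass_axioms_to_named(g)) == 2
        assert (IRI(f"{BASE}#d1100"), IRI(RDFS + "subClassOf"), IRI(f"{BASE}#d110")) in g

    def test_labels_and_code_annotations(self, chain3):
        g = reparse(to_owl(chain3))
        labels = g.objects(IRI(f"{BASE}#d110"), IRI(RDFS + "label"))
        assert {lit.text for lit in labels} == {"Watching"}
        codes = g.objects(IRI(f"{BASE}#d110"), IRI(f"{BASE}#code"))
        assert {lit.text for lit in codes} == {"d110"}

    def test_rubrics_become_distinct_annotations(self, chain3):
        from clamlkit.model import Rubric

        chain3["d110"].rubrics += [
            Rubric("inclusion", "looking"), Rubric("inclusion", "observing"),
            Rubric("exclusion", "listening"),
        ]
        g = reparse(to_owl(chain3))
        iri = IRI(f"{BASE}#d110")
        assert len(g.objects(iri, IRI(f"{BASE}#inclusion"))) == 2
        assert len(g.objects(iri, IRI(f"{BASE}#exclusion"))) == 1
        # exclusions stay annotations: no disjointness axioms anywhere
        assert not g.triples(None, IRI(OWL + "disjointWith"), None)

    def test_class_count_conservation(self, blocky):
        g = reparse(to_owl(blocky))  # blocks as classes, residuals kept
        assert len(named_classes(g)) == len(blocky)
        g2 = reparse(to_owl(blocky, include_residuals=False, blocks="annotation"))
        expected = sum(
            1 for x in blocky if x.kind != "block" and not x.is_residual
        )
        assert len(named_classes(g2)) == expected

    def test_block_annotation_mode_rewires_edges(self, blocky):
        g = reparse(to_owl(blocky, blocks="annotation"))
        assert (IRI(f"{BASE}#d450"), IRI(RDFS + "subClassOf"), IRI(f"{BASE}#d4")) in g
        assert IRI(f"{BASE}#d450-d469") not in named_classes(g)
        blocks = g.objects(IRI(f"{BASE}#d450"), IRI(f"{BASE}#block"))
        assert {lit.text for lit in blocks} == {"d450-d469"}

    def test_dialect_equivalence(self, blocky):
        from clamlkit.rdf import isomorphic

        doc = to_owl(blocky)
        assert isomorphic(reparse(doc, "turtle"), reparse(doc, "rdfxml"))

    def test_deterministic_serialization(self, blocky):
        assert to_owl(blocky).serialize() == to_owl(blocky).serialize()


def conversation_annotations(c):
    rel = {
        "d3500": RelationshipType.SUBPROCESS,
        "d3501": RelationshipType.SUBPROCESS,
        "d3502": RelationshipType.SUBPROCESS,
        "d3503": RelationshipType.AGENT,
        "d3504": RelationshipType.AGENT,
    }
    return [
        EdgeAnnotation(e, rel.get(e.child_code, RelationshipType.SUBSUMPTION))
        for e in enumerate_edges(c)
    ]


class TestToOwlAnnotated:
    def test_all_subsumption_is_identity(self, chain3):
        annotations = [
            EdgeAnnotation(e, RelationshipType.SUBSUMPTION) for e in enumerate_edges(chain3)
        ]
        plain = to_owl(chain3).serialize()
        annotated = to_owl_annotated(chain3, annotations).serialize()
        assert plain == annotated

    def test_default_mode_only_adds(self, conversation_tree):
        base_graph = reparse(to_owl(conversation_tree))
        doc = to_owl_annotated(conversation_tree, conversation_annotations(conversation_tree))
        g = reparse(doc)
        assert len(subclass_axioms_to_named(g)) == len(subclass_axioms_to_named(base_graph))
        for triple in base_graph:
            assert triple in g  # monotone: nothing removed
        proposals = g.triples(None, IRI(f"{BASE}#proposedRelation"), None)
        assert len(proposals) == 5  # one per non-subsumption edge
        texts = {o.text for _, _, o in proposals}
        assert "SubProcess of d350" in texts and "Agent of d350" in texts

    def test_strict_mode_replaces_edges(self, conversation_tree):
        doc = to_owl_annotated(
            conversation_tree, conversation_annotations(conversation_tree), strict=True)
        g = reparse(doc)
        named = subclass_axioms_to_named(g)
        # 5 of the 6 subclass axioms to named classes removed (d350->d3 kept)
        assert named == [(IRI(f"{BASE}#d350"), IRI(f"{BASE}#d3"))]
        restrictions = g.subjects(IRI(RDF + "type"), IRI(OWL + "Restriction"))
        assert len(restrictions) == 5
        on_props = {
            list(g.objects(r, IRI(OWL + "onProperty")))[0] for r in restrictions
        }
        assert on_props == {IRI(f"{BASE}#subProcess"), IRI(f"{BASE}#agent")}
        for r in restrictions:
            assert g.objects(r, IRI(OWL + "someValuesFrom")) == {IRI(f"{BASE}#d350")}
        # the object properties are declared
        assert (IRI(f"{BASE}#agent"), IRI(RDF + "type"), IRI(OWL + "ObjectProperty")) in g

    def test_strict_mode_complexity_is_annotation(self, chain3):
        annotations = [
            EdgeAnnotation(CodedEdge("d110", "d1100", "lower"), RelationshipType.COMPLEXITY),
        ]
        g = reparse(to_owl_annotated(chain3, annotations, strict=True))
        assert (IRI(f"{BASE}#d1100"), IRI(RDFS + "subClassOf"), IRI(f"{BASE}#d110")) not in g
        values = g.objects(IRI(f"{BASE}#d1100"), IRI(f"{BASE}#complexity"))
        assert {lit.text for lit in values} == {"simple"}
        # never an object property
        assert (IRI(f"{BASE}#complexity"), IRI(RDF + "type"), IRI(OWL + "ObjectProperty")) not in g

    def test_unknown_edge_rejected(self, chain3):
        bad = [EdgeAnnotation(CodedEdge("d1", "d1100", "top"), RelationshipType.AGENT)]
        with pytest.raises(IntegrityError):
            to_owl_annotated(chain3, bad)

    def test_iri_collision_detected(self):
        from clamlkit.owl_export import _Builder

        b = _Builder("http://x.org/o", "turtle")
        b.iri("d1")
        b._seen_iris["http://x.org/o#d2"] = "other"
        with pytest.raises(IntegrityError):
            b.iri("d2")
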