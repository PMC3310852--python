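import warnings

import pytest

from clamlkit import fixtures as fx
from clamlkit.errors import CodeFormatError, IntegrityError, VocabularyError
from clamlkit.rdf import OWL, RDF, SKOS, IRI, parse
from clamlkit.sumo_mapping import (
    CoverageReport,
    MappingEntry,
    coverage,
    export_mapping_annotations,
    load_level_totals,
    load_mappings,
    write_mappings,
)


class TestMappingEntry:
    def test_basic(self):
        e = MappingEntry("d2", "IntentionalProcess", "broader")
        assert e.level == "chapter"

    def test_bad_match_kind(self):
        with pytest.raises(VocabularyError):
            MappingEntry("d2", "IntentionalProcess", "narrower")

    def test_bad_source_code(self):
        with pytest.raises(CodeFormatError):
            MappingEntry("foo!", "IntentionalProcess")

    def test_empty_target(self):
        with pytest.raises(VocabularyError):
            MappingEntry("d2", "")


class TestLoadMappings:
    def test_empty(self):
        assert load_mappings("") == []
        assert load_mappings("# comment only\n") == []

    def test_single_row(self):
        (e,) = load_mappings("d2\tIntentionalProcess\tbroader\n")
        assert e == MappingEntry("d2", "IntentionalProcess", "broader")

    def test_match_kind_defaults_to_broader(self):
        (e,) = load_mappings("d4\tMotion\n")
        assert e.match_kind == "broader"

    def test_note_preserved(self):
        (e,) = load_mappings("d4\tMotion\tbroader\tnot an intentional process\n")
        assert e.note == "not an intentional process"

    def test_duplicate_pair_rejected(self):
        text = "d2\tIntentionalProcess\nd2\tIntentionalProcess\tbroader\n"
        with pytest.raises(IntegrityError, match="duplicate"):
            load_mappings(text)

    def test_round_trip(self):
        entries = fx.load_block_category_mappings()
        assert load_mappings(write_mappings(entries)) == entries

    def test_packaged_chapter_fixture(self, chapter_mappings):
        assert [e.source for e in chapter_mappings] == ["d2", "d4", "d5", "d6"]
        assert all(e.match_kind == "broader" for e in chapter_mappings)


class TestCoverage:
    def test_empty_mappings_against_chapter_list(self, chapter_codes):
        report = coverage([], chapter_codes)
        assert report["chapter"].mapped == 0
        assert report["chapter"].total == 9

    def test_packaged_chapter_coverage(self, chapter_mappings, chapter_codes):
        report = coverage(chapter_mappings, chapter_codes)
        assert (report["chapter"].mapped, report["chapter"].total) == (4, 9)
        assert set(report["chapter"].unmapped_codes) == {"d1", "d3", "d7", "d8", "d9"}

    def test_two_of_three_categories(self):
        entries = [MappingEntry("d110", "Watching"), MappingEntry("d115", "Listening")]
        report = coverage(entries, ["d110", "d115", "d120"])
        assert (report["category"].mapped, report["category"].total) == (2, 3)
        assert report["category"].unmapped_codes == ("d120",)

    def test_multiple_entries_count_once(self):
        entries = [MappingEntry("d2", "IntentionalProcess"),
                   MappingEntry("d2", "Process", "partial")]
        report = coverage(entries, ["d2", "d3"])
        assert report["chapter"].mapped == 1

    def test_level_partition(self, chapter_mappings, chapter_codes):
        lc = coverage(chapter_mappings, chapter_codes)["chapter"]
        assert lc.mapped + len(lc.unmapped_codes) == lc.total

    def test_against_classification(self, blocky):
        entries = [MappingEntry("d4", "Motion"), MappingEntry("d450-d469", "Walking")]
        report = coverage(entries, blocky)
        assert (report["chapter"].mapped, report["chapter"].total) == (1, 1)
        assert (report["block"].mapped, report["block"].total) == (1, 1)
        assert report["category"].mapped == 0 and report["category"].total == 2
        assert report["subcategory"].total == 3

    def test_against_level_totals(self):
        totals = {"chapter": 9, "block": 18, "category": 118, "subcategory": 266}
        entries = fx.load_chapter_mappings() + fx.load_block_category_mappings()
        report = coverage(entries, totals)
        assert report["chapter"].mapped == 4
        assert report["block"].mapped == 4
        assert report["category"].mapped == 5
        assert report["chapter"].unmapped_codes is None
        assert report["block"].unmapped == 14

    def test_unknown_source_strict_vs_lenient(self, chapter_codes):
        entries = [MappingEntry("d999", "Process")]  # category, not in the chapter list
        with pytest.raises(IntegrityError):
            coverage(entries, chapter_codes)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            report = coverage(entries, chapter_codes, lenient=True)
        assert caught and report["chapter"].mapped == 0

    def test_monotonicity(self, chapter_mappings, chapter_codes):
        before = coverage(chapter_mappings, chapter_codes)["chapter"].mapped
        extra = chapter_mappings + [MappingEntry("d8", "SocialInteraction")]
        after = coverage(extra, chapter_codes)["chapter"].mapped
        assert after == before + 1

    def test_load_level_totals(self):
        totals = load_level_totals("level\ttotal\nchapter\t9\nblock\t18\n")
        assert totals == {"chapter": 9, "block": 18}


class TestExportAnnotations:
    def test_empty_fragment(self):
        doc = export_mapping_annotations([])
        assert len(parse(doc.serialize(), "turtle")) == 0

    def test_single_entry_single_annotation(self):
        doc = export_mapping_annotations([MappingEntry("d2", "IntentionalProcess")])
        g = parse(doc.serialize(), "turtle")
        matches = g.triples(None, IRI(SKOS + "broadMatch"), None)
        assert len(matches) == 1
        s, _, o = matches[0]
        assert str(s).endswith("#d2") and str(o).endswith("#IntentionalProcess")

    def test_chapter_fixture_four_broader_annotations(self, chapter_mappings):
        g = parse(export_mapping_annotations(chapter_mappings).serialize(), "turtle")
        assert len(g.triples(None, IRI(SKOS + "broadMatch"), None)) == 4
        assert not g.triples(None, IRI(SKOS + "exactMatch"), None)

    def test_no_cross_ontology_subclass_axioms(self, chapter_mappings):
        from clamlkit.rdf import RDFS

        g = parse(export_mapping_annotations(chapter_mappings).serialize(), "turtle")
        assert not g.triples(None, IRI(RDFS + "subClassOf"), None)

    def test_match_kinds_use_distinct_properties(self):
        entries = [
            MappingEntry("d170", "Writing", "equivalent"),
            MappingEntry("d330-d349", "ContentDevelopment", "partial"),
        ]
        g = parse(export_mapping_annotations(entries).serialize(), "turtle")
        assert len(g.triples(None, IRI(SKOS + "exactMatch"), None)) == 1
        assert len(g.triples(None, IRI(SKOS + "relatedMatch"), None)) == 1
        # properties are declared
        assert (IRI(SKOS + "exactMatch"), IRI(RDF + "type"),
                IRI(OWL + "AnnotationProperty")) in g
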