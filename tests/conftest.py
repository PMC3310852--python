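"""Shared fixtures: hand-built classifications and packaged reference data."""

import pytest

from clamlkit import fixtures as fx
from clamlkit.model import Classification, ClassificationConcept, Rubric


def build_classification(spec):
    """Build a classification from (code, kind, parent, title) tuples."""
    c = Classification(name="test", version="0")
    links = []
    for code, kind, parent, title in spec:
        c.add(ClassificationConcept(code=code, kind=kind,
                                    rubrics=[Rubric("preferred", title)]))
        if parent:
            links.append((parent, code))
    for parent, child in links:
        c.link(parent, child)
    from clamlkit.claml_io import detect_residual

    for concept in c:
        concept.is_residual = detect_residual(concept)
    return c


@pytest.fixture
def chain3():
    """Chapter -> category -> subcategory chain."""
    return build_classification([
        ("d1", "chapter", None, "Learning and applying knowledge"),
        ("d110", "category", "d1", "Watching"),
        ("d1100", "subcategory", "d110", "Watching closely"),
    ])


@pytest.fixture
def blocky():
    """Chapter with a block between chapter and categories, plus residuals."""
    return build_classification([
        ("d4", "chapter", None, "Mobility"),
        ("d450-d469", "block", "d4", "Walking and moving"),
        ("d450", "category", "d450-d469", "Walking"),
        ("d455", "category", "d450-d469", "Moving around"),
        ("d4500", "subcategory", "d450", "Walking short distances"),
        ("d4508", "subcategory", "d450", "Other specified walking"),
        ("d4509", "subcategory", "d450", "Unspecified walking"),
    ])


@pytest.fixture
def conversation_tree():
    """Conversation parent with three stage children and two agent-count
    children (the classic mixed-relationship subtree)."""
    return build_classification([
        ("d3", "chapter", None, "Communication"),
        ("d350", "category", "d3", "Conversation"),
        ("d3500", "subcategory", "d350", "Starting a conversation"),
        ("d3501", "subcategory", "d350", "Sustaining a conversation"),
        ("d3502", "subcategory", "d350", "Ending a conversation"),
        ("d3503", "subcategory", "d350", "Conversing with one person"),
        ("d3504", "subcategory", "d350", "Conversing with many people"),
    ])


@pytest.fixture(scope="session")
def table2():
    return fx.load_table2_counts()


@pytest.fixture(scope="session")
def chapter_codes():
    return fx.table1_chapter_codes()


@pytest.fixture(scope="session")
def chapter_mappings():
    return fx.load_chapter_mappings()
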