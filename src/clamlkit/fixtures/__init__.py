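"""Synthetic generators and packaged reference data.

The packaged files under ``data/`` encode published reference tables for
the ICF Activities and Participation component: its nine chapters, the
per-chapter relationship-usage counts, and the curated SUMO mapping
entries, plus a tiny ClaML excerpt used by the suggestion tests.
"""

from __future__ import annotations

from importlib import resources

from ..claml_io import parse_claml
from ..model import Classification
from ..relationships import EdgeAnnotation  # noqa: F401  (re-export convenience)
from ..stats import RelationshipCountTable, load_count_table
from ..sumo_mapping import MappingEntry, load_mappings
from .synthesis import (
    SynthesisParams,
    make_synthetic_annotations,
    make_synthetic_classification,
    make_synthetic_model,
    spread,
)

__all__ = [
    "SynthesisParams",
    "make_synthetic_classification",
    "make_synthetic_model",
    "make_synthetic_annotations",
    "spread",
    "data_text",
    "load_table1_chapters",
    "table1_chapter_codes",
    "load_table2_counts",
    "load_chapter_mappings",
    "load_block_category_mappings",
    "conversation_classification",
]


def data_text(name: str) -> str:
    """UTF-8 text of a packaged data file."""
    return (resources.files(__package__) / "data" / name).read_text(encoding="utf-8")


def load_table1_chapters() -> list[tuple[str, str]]:
    """The nine (code, title) chapter pairs."""
    out = []
    for line in data_text("table1_chapters.tsv").splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("code\t"):
            continue
        code, title = line.split("\t")
        out.append((code, title))
    return out


def table1_chapter_codes() -> list[str]:
    return [code for code, _ in load_table1_chapters()]


def load_table2_counts() -> RelationshipCountTable:
    """The per-chapter, per-level, per-relation edge count table."""
    return load_count_table(data_text("table2_counts.tsv"))


def load_chapter_mappings() -> list[MappingEntry]:
    return load_mappings(data_text("chapter_mappings.tsv"))


def load_block_category_mappings() -> list[MappingEntry]:
    return load_mappings(data_text("block_category_mappings.tsv"))


def conversation_classification() -> Classification:
    """The packaged Discussion subtree (chapter, category, two agent-cue
    subcategories)."""
    return parse_claml(data_text("conversation_subtree.xml"))
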