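"""Cross-tabulation of edge relationships and derived summary statistics.

The central object is :class:`RelationshipCountTable`: per-chapter,
per-level (top = chapter-to-category, lower = deeper) counts for each of
the six relationship types.  :func:`summarize` derives the headline
percentages: how often subsumption is used at the top level, and how
often something *other* than subsumption is used below it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

from .errors import ClamlKitError, IntegrityError, ParseError, VocabularyError
from .relationships import RELATION_NAMES

__all__ = [
    "LEVELS",
    "RelationshipCountTable",
    "SummaryReport",
    "summarize",
    "render_table",
    "load_count_table",
    "parse_rendered_tsv",
    "pct_half_away",
]

LEVELS = ("top", "lower")


class EmptyTableError(ClamlKitError):
    """Raised when a summary is requested for an all-zero table."""


def pct_half_away(numerator: int, denominator: int) -> int:
    """``100 * numerator / denominator`` rounded half away from zero.

    This rounding rule reproduces every percentage derivable from the
    reference count table (88/98 -> 90, 72/175 -> 41, 13/14 -> 93,
    15/27 -> 56, 4/4 -> 100).
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty row is undefined")
    if numerator < 0 or denominator < 0:
        raise ValueError("counts must be non-negative")
    return (200 * numerator + denominator) // (2 * denominator)


class RelationshipCountTable:
    """Per-chapter, per-level, per-relation edge counts.

    Row and column totals are always derived from the cells, so the
    consistency invariants (row total = sum over relations, grand totals
    = column sums) hold by construction.
    """

    def __init__(self) -> None:
        self._cells: dict[tuple[str, str, str], int] = {}
        self._chapters: set[str] = set()

    # -- construction -------------------------------------------------------

    def add(self, chapter: str, level: str, relation: str, count: int = 1) -> None:
        self._check_keys(level, relation)
        if count < 0:
            raise IntegrityError(f"negative count for {chapter}/{level}/{relation}")
        key = (chapter, level, relation)
        self._cells[key] = self._cells.get(key, 0) + count
        self._chapters.add(chapter)

    @staticmethod
    def _check_keys(level: str, relation: str) -> None:
        if level not in LEVELS:
            raise VocabularyError(f"unknown level {level!r}; legal values: top, lower")
        if relation not in RELATION_NAMES:
            raise VocabularyError(
                f"unknown relation {relation!r}; legal values: {', '.join(RELATION_NAMES)}"
            )

    # -- access -------------------------------------------------------------

    @property
    def chapters(self) -> list[str]:
        return sorted(self._chapters)

    def get(self, chapter: str, level: str, relation: str) -> int:
        self._check_keys(level, relation)
        return self._cells.get((chapter, level, relation), 0)

    def row_total(self, chapter: str, level: str) -> int:
        return sum(self.get(chapter, level, r) for r in RELATION_NAMES)

    def column_total(self, level: str, relation: str) -> int:
        return sum(self.get(ch, level, relation) for ch in self._chapters)

    def grand_total(self, level: str) -> int:
        return sum(self.row_total(ch, level) for ch in self._chapters)

    def total_edges(self) -> int:
        return sum(self._cells.values())

    # -- equality -----------------------------------------------------------

    def _normalized(self) -> dict[tuple[str, str, str], int]:
        return {k: v for k, v in self._cells.items() if v != 0}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RelationshipCountTable):
            return NotImplemented
        return self._normalized() == other._normalized()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<RelationshipCountTable chapters={self.chapters} edges={self.total_edges()}>"


# ---------------------------------------------------------------------------
# Summary statistics


@dataclass(frozen=True)
class SummaryReport:
    """Headline statistics derived from a count table.

    Percentages are integer percent (half-away-from-zero rounding);
    chapters whose lower-level row is empty have ``None`` ("undefined")
    instead of a number.  ``fractions`` carries the exact ratios behind
    each rounded value.
    """

    top_subsumption_pct: int
    lower_other_pct: int
    per_chapter_lower_other_pct: dict[str, int | None]
    majority_nonsubsumption_chapters: list[str]
    all_subsumption_chapters: list[str]
    fractions: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        per_chapter = {
            ch: ("undefined" if v is None else v)
            for ch, v in self.per_chapter_lower_other_pct.items()
        }
        return {
            "top_subsumption_pct": self.top_subsumption_pct,
            "lower_other_pct": self.lower_other_pct,
            "per_chapter_lower_other_pct": per_chapter,
            "majority_nonsubsumption_chapters": self.majority_nonsubsumption_chapters,
            "all_subsumption_chapters": self.all_subsumption_chapters,
            "fractions": self.fractions,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def summarize(t: RelationshipCountTable) -> SummaryReport:
    """Derive the summary report from a count table.

    Raises :class:`EmptyTableError` when the table has no edges at all.
    """
    if t.total_edges() == 0:
        raise EmptyTableError("cannot summarize an all-zero count table")

    top_total = t.grand_total("top")
    top_subs = t.column_total("top", "Subsumption")
    lower_total = t.grand_total("lower")
    lower_subs = t.column_total("lower", "Subsumption")

    fractions = {}
    if top_total == 0 or lower_total == 0:
        raise EmptyTableError("need at least one edge at each level to summarize")
    top_pct = pct_half_away(top_subs, top_total)
    lower_other = lower_total - lower_subs
    lower_pct = pct_half_away(lower_other, lower_total)
    fractions["top_subsumption"] = f"{top_subs}/{top_total}"
    fractions["lower_other"] = f"{lower_other}/{lower_total}"

    per_chapter: dict[str, int | None] = {}
    majority: list[str] = []
    all_subs: list[str] = []
    for ch in t.chapters:
        ch_lower_total = t.row_total(ch, "lower")
        ch_lower_other = ch_lower_total - t.get(ch, "lower", "Subsumption")
        if ch_lower_total == 0:
            per_chapter[ch] = None
            fractions[f"{ch}_lower_other"] = "undefined"
        else:
            per_chapter[ch] = pct_half_away(ch_lower_other, ch_lower_total)
            fractions[f"{ch}_lower_other"] = f"{ch_lower_other}/{ch_lower_total}"
            # strict majority: exact-fraction comparison, not the rounded %
            if Fraction(ch_lower_other, ch_lower_total) > Fraction(1, 2):
                majority.append(ch)
        ch_total = ch_lower_total + t.row_total(ch, "top")
        ch_subs = t.get(ch, "top", "Subsumption") + t.get(ch, "lower", "Subsumption")
        if ch_total > 0 and ch_subs == ch_total:
            all_subs.append(ch)

    return SummaryReport(
        top_subsumption_pct=top_pct,
        lower_other_pct=lower_pct,
        per_chapter_lower_other_pct=per_chapter,
        majority_nonsubsumption_chapters=majority,
        all_subsumption_chapters=all_subs,
        fractions=fractions,
    )


# ---------------------------------------------------------------------------
# Rendering and parsing


def render_table(t: RelationshipCountTable, format: str = "tsv") -> str:
    """Render the table in the classic wide shape: one row per chapter,
    one column per relation, each cell ``top/lower``, plus a Total row.

    ``tsv`` output round-trips through :func:`parse_rendered_tsv`.
    """
    if format not in ("tsv", "markdown"):
        raise VocabularyError(f"unknown format {format!r}; legal values: tsv, markdown")

    header = ["chapter", "total", *RELATION_NAMES]
    rows: list[list[str]] = []
    for ch in t.chapters:
        cells = [ch, f"{t.row_total(ch, 'top')}/{t.row_total(ch, 'lower')}"]
        cells += [f"{t.get(ch, 'top', r)}/{t.get(ch, 'lower', r)}" for r in RELATION_NAMES]
        rows.append(cells)
    total = ["Total", f"{t.grand_total('top')}/{t.grand_total('lower')}"]
    total += [f"{t.column_total('top', r)}/{t.column_total('lower', r)}" for r in RELATION_NAMES]
    rows.append(total)

    if format == "tsv":
        return "\n".join("\t".join(r) for r in [header, *rows]) + "\n"
    widths = [max(len(r[i]) for r in [header, *rows]) for i in range(len(header))]
    md_rows = [header, ["-" * w for w in widths], *rows]
    return "\n".join(
        "| " + " | ".join(cell.ljust(w) for cell, w in zip(r, widths)) + " |" for r in md_rows
    ) + "\n"


def parse_rendered_tsv(text: str) -> RelationshipCountTable:
    """Inverse of ``render_table(t, "tsv")``; verifies the Total row."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError("empty rendered table")
    header = lines[0].split("\t")
    if header[:2] != ["chapter", "total"] or tuple(header[2:]) != RELATION_NAMES:
        raise ParseError(f"unexpected header: {lines[0]!r}")
    t = RelationshipCountTable()
    totals_row: list[str] | None = None
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise ParseError(f"row width mismatch: {ln!r}")
        if cells[0] == "Total":
            totals_row = cells
            continue
        for relation, cell in zip(RELATION_NAMES, cells[2:]):
            top, lower = _split_cell(cell)
            t.add(cells[0], "top", relation, top)
            t.add(cells[0], "lower", relation, lower)
        top, lower = _split_cell(cells[1])
        if (top, lower) != (t.row_total(cells[0], "top"), t.row_total(cells[0], "lower")):
            raise IntegrityError(f"row {cells[0]}: total cell disagrees with relation cells")
    if totals_row is not None:
        if _split_cell(totals_row[1]) != (t.grand_total("top"), t.grand_total("lower")):
            raise IntegrityError("Total row disagrees with chapter rows for the edge totals")
        for relation, cell in zip(RELATION_NAMES, totals_row[2:]):
            if _split_cell(cell) != (t.column_total("top", relation), t.column_total("lower", relation)):
                raise IntegrityError(f"Total row disagrees with chapter rows for {relation}")
    return t


def _split_cell(cell: str) -> tuple[int, int]:
    try:
        top, lower = cell.split("/")
        return int(top), int(lower)
    except ValueError as exc:
        raise ParseError(f"bad top/lower cell {cell!r}") from exc


def load_count_table(text: str) -> RelationshipCountTable:
    """Load a long-format count TSV: columns chapter, level, relation, count.

    ``#`` lines are comments; a header row is recognised and skipped.
    """
    t = RelationshipCountTable()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in raw.split("\t")]
        if parts[:4] == ["chapter", "level", "relation", "count"]:
            continue
        if len(parts) < 4:
            raise ParseError(f"line {lineno}: expected 4 tab-separated fields")
        chapter, level, relation, count = parts[:4]
        try:
            n = int(count)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: bad count {count!r}") from exc
        t.add(chapter, level, relation, n)
    return t


def dump_count_table(t: RelationshipCountTable) -> str:
    """Long-format TSV inverse of :func:`load_count_table` (zero cells omitted)."""
    lines = ["chapter\tlevel\trelation\tcount"]
    for ch in t.chapters:
        for level in LEVELS:
            for relation in RELATION_NAMES:
                n = t.get(ch, level, relation)
                if n:
                    lines.append(f"{ch}\t{level}\t{relation}\t{n}")
    return "\n".join(lines) + "\n"
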