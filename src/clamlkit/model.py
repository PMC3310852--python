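"""In-memory model of a hierarchical coded classification.

A :class:`Classification` is a forest of coded concepts: chapters at the
roots, categories and subcategories below, with optional *block* concepts
(code-range groupings) in between.  Blocks are ordinary concepts for
storage purposes but are treated as transparent when hierarchy edges are
enumerated for analysis: a chapter -> block -> category chain contributes a
single logical chapter -> category edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .codes import classify_code
from .errors import CodeFormatError, IntegrityError

__all__ = [
    "RUBRIC_KINDS",
    "CONCEPT_KINDS",
    "Rubric",
    "ClassificationConcept",
    "Classification",
]

RUBRIC_KINDS = ("preferred", "definition", "inclusion", "exclusion", "coding-hint", "other")
CONCEPT_KINDS = ("chapter", "block", "category", "subcategory")


@dataclass(frozen=True)
class Rubric:
    """One piece of rubric text attached to a concept.

    Unknown source kinds are normalised to ``other`` with the original
    kind kept in ``note``.
    """

    kind: str
    text: str
    note: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in RUBRIC_KINDS:
            raise ValueError(f"unknown rubric kind {self.kind!r}; use 'other' + note")
        if not self.text:
            raise ValueError("rubric text must be non-empty")

    @classmethod
    def from_raw(cls, kind: str, text: str) -> "Rubric":
        """Build a rubric, mapping unrecognised kinds to ``other``."""
        k = kind.strip().lower() if kind else "other"
        aliases = {"codinghint": "coding-hint", "coding_hint": "coding-hint",
                   "text": "definition"}
        k = aliases.get(k, k)
        if k in RUBRIC_KINDS:
            return cls(k, text)
        return cls("other", text, note=f"original kind: {kind}")


@dataclass
class ClassificationConcept:
    """One coded node in the classification forest."""

    code: str
    kind: str
    rubrics: list[Rubric] = field(default_factory=list)
    parent_code: str | None = None
    child_codes: list[str] = field(default_factory=list)
    is_residual: bool = False

    @property
    def title(self) -> str:
        """The preferred rubric text."""
        for r in self.rubrics:
            if r.kind == "preferred":
                return r.text
        raise IntegrityError(f"concept {self.code} has no preferred rubric")

    def rubrics_of(self, kind: str) -> list[Rubric]:
        return [r for r in self.rubrics if r.kind == kind]

    def validate(self) -> list[str]:
        issues: list[str] = []
        if self.kind not in CONCEPT_KINDS:
            issues.append(f"{self.code}: unknown concept kind {self.kind!r}")
        n_pref = len(self.rubrics_of("preferred"))
        if n_pref != 1:
            issues.append(f"{self.code}: expected exactly 1 preferred rubric, found {n_pref}")
        if len(set(self.child_codes)) != len(self.child_codes):
            issues.append(f"{self.code}: duplicate child codes")
        try:
            info = classify_code(self.code)
        except CodeFormatError as exc:
            issues.append(str(exc))
        else:
            if info.kind != self.kind:
                issues.append(
                    f"{self.code}: kind {self.kind!r} inconsistent with code shape "
                    f"(expected {info.kind!r})"
                )
        return issues


class Classification:
    """A named, code-indexed forest of :class:`ClassificationConcept`."""

    def __init__(self, name: str = "", version: str = ""):
        self.name = name
        self.version = version
        self._concepts: dict[str, ClassificationConcept] = {}

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._concepts)

    def __contains__(self, code: str) -> bool:
        return code in self._concepts

    def __getitem__(self, code: str) -> ClassificationConcept:
        return self._concepts[code]

    def __iter__(self) -> Iterator[ClassificationConcept]:
        return iter(self._concepts.values())

    @property
    def concepts(self) -> dict[str, ClassificationConcept]:
        return self._concepts

    @property
    def roots(self) -> list[str]:
        return [c.code for c in self._concepts.values() if c.parent_code is None]

    @property
    def chapters(self) -> list[str]:
        return [c.code for c in self._concepts.values() if c.kind == "chapter"]

    # -- construction -------------------------------------------------------

    def add(self, concept: ClassificationConcept) -> None:
        if concept.code in self._concepts:
            raise IntegrityError(f"duplicate code {concept.code!r}")
        self._concepts[concept.code] = concept

    def link(self, parent_code: str, child_code: str) -> None:
        """Record a parent-child edge (idempotent for repeated calls)."""
        parent = self._concepts[parent_code]
        child = self._concepts[child_code]
        if child.parent_code is not None and child.parent_code != parent_code:
            raise IntegrityError(
                f"{child_code} already has parent {child.parent_code}, "
                f"cannot re-parent under {parent_code}"
            )
        child.parent_code = parent_code
        if child_code not in parent.child_codes:
            parent.child_codes.append(child_code)

    # -- hierarchy queries --------------------------------------------------

    def logical_parent_code(self, code: str) -> str | None:
        """Nearest non-block ancestor; blocks are transparent groupings."""
        cur = self._concepts[code].parent_code
        while cur is not None and self._concepts[cur].kind == "block":
            cur = self._concepts[cur].parent_code
        return cur

    def iter_logical_edges(self, include_residual: bool = False):
        """Yield ``(parent_code, child_code)`` over non-block concepts,
        with blocks collapsed out of the chain.

        Residual concepts ("Other specified ...", "Unspecified ...") are
        skipped unless *include_residual*; an edge is dropped when either
        endpoint is residual.
        """
        for concept in self.sorted_concepts():
            if concept.kind == "block":
                continue
            parent = self.logical_parent_code(concept.code)
            if parent is None:
                continue
            if not include_residual and (
                concept.is_residual or self._concepts[parent].is_residual
            ):
                continue
            yield parent, concept.code

    def sorted_concepts(self) -> list[ClassificationConcept]:
        return [self._concepts[c] for c in sorted(self._concepts)]

    def count_by_kind(self) -> dict[str, int]:
        out = {k: 0 for k in CONCEPT_KINDS}
        for c in self._concepts.values():
            out[c.kind] = out.get(c.kind, 0) + 1
        return out

    # -- validation ---------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of human-readable integrity issues (empty = valid)."""
        issues: list[str] = []
        if not self.chapters:
            issues.append("no chapters")
        for concept in self._concepts.values():
            issues.extend(concept.validate())
            if concept.parent_code is not None:
                parent = self._concepts.get(concept.parent_code)
                if parent is None:
                    issues.append(
                        f"{concept.code}: parent {concept.parent_code} not in classification"
                    )
                elif concept.code not in parent.child_codes:
                    issues.append(
                        f"{concept.code}: not listed among children of {concept.parent_code}"
                    )
            elif concept.kind not in ("chapter",):
                issues.append(f"{concept.code}: non-chapter concept without a parent")
            for child in concept.child_codes:
                c = self._concepts.get(child)
                if c is None:
                    issues.append(f"{concept.code}: child {child} not in classification")
                elif c.parent_code != concept.code:
                    issues.append(
                        f"{concept.code}: child {child} points back to {c.parent_code}"
                    )
        issues.extend(self._find_cycles())
        return issues

    def _find_cycles(self) -> list[str]:
        issues = []
        seen_ok: set[str] = set()
        for code in self._concepts:
            path: list[str] = []
            on_path: set[str] = set()
            cur: str | None = code
            while cur is not None and cur not in seen_ok:
                if cur in on_path:
                    cycle = path[path.index(cur):] + [cur]
                    issues.append("cycle in parent links: " + " -> ".join(cycle))
                    return issues
                path.append(cur)
                on_path.add(cur)
                nxt = self._concepts[cur].parent_code
                cur = nxt if nxt in self._concepts else None
            seen_ok.update(path)
        return issues

    def check(self) -> None:
        """Raise :class:`IntegrityError` listing all issues, if any."""
        issues = self.validate()
        if issues:
            raise IntegrityError("; ".join(issues))

    # -- equality (structural) ----------------------------------------------

    def structurally_equal(self, other: "Classification") -> bool:
        if set(self._concepts) != set(other._concepts):
            return False
        for code, a in self._concepts.items():
            b = other._concepts[code]
            if (a.kind, a.parent_code, a.child_codes, a.rubrics, a.is_residual) != (
                b.kind, b.parent_code, b.child_codes, b.rubrics, b.is_residual
            ):
                return False
        return True
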