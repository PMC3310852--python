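"""Deterministic synthetic classification and annotation generators.

Stand-ins for real classification files: structurally faithful (chapters,
categories, subcategories, optional residual children) but with generated
titles.  Output is byte-deterministic per seed so snapshots are stable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ..claml_io import write_claml
from ..errors import ParameterError
from ..model import Classification, ClassificationConcept, Rubric
from ..relationships import (
    RELATION_NAMES,
    EdgeAnnotation,
    RelationshipType,
    enumerate_edges,
)

__all__ = [
    "SynthesisParams",
    "spread",
    "make_synthetic_model",
    "make_synthetic_classification",
    "make_synthetic_annotations",
]

_NOUNS = (
    "walking", "reading", "writing", "washing", "dressing", "eating", "drinking",
    "lifting", "carrying", "speaking", "listening", "counting", "drawing",
    "cooking", "cleaning", "shopping", "driving", "climbing", "singing",
    "planning", "greeting", "building", "folding", "sorting",
)
_MODIFIERS = (
    "basic", "fine", "gross", "daily", "household", "formal", "informal",
    "indoor", "outdoor", "assisted", "independent", "routine",
)


def spread(total: int, parts: int) -> list[int]:
    """Split *total* into *parts* near-equal non-negative integers."""
    if parts <= 0:
        raise ParameterError("cannot spread over zero parts")
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


@dataclass(frozen=True)
class SynthesisParams:
    """Shape parameters for a synthetic classification.

    ``categories_per_chapter`` may be a single int or one quota per
    chapter; ``subcategories_per_category`` a single int or one quota per
    category (flattened in chapter order).
    """

    n_chapters: int = 3
    categories_per_chapter: int | Sequence[int] = 4
    subcategories_per_category: int | Sequence[int] = 2
    residual_fraction: float = 0.0
    relation_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"Subsumption": 1.0}
    )
    seed: int = 0
    component: str = "d"

    def __post_init__(self) -> None:
        if not 1 <= self.n_chapters <= 9:
            raise ParameterError(
                f"n_chapters must be between 1 and 9 (single-digit chapter codes), "
                f"got {self.n_chapters}"
            )
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ParameterError(f"residual_fraction must be in [0,1], got {self.residual_fraction}")
        cats = self.category_quotas()
        if any(q < 0 for q in cats):
            raise ParameterError("category quotas must be non-negative")
        if any(q > 100 for q in cats):
            raise ParameterError("at most 100 categories per chapter (two trailing digits)")
        subs = self.subcategory_quotas()
        if any(q < 0 for q in subs):
            raise ParameterError("subcategory quotas must be non-negative")
        if any(q > 10 for q in subs):
            raise ParameterError("at most 10 subcategories per category (one trailing digit)")
        if self.residual_fraction > 0 and sum(subs) == 0:
            raise ParameterError("residual_fraction > 0 requires at least one subcategory")
        dist = dict(self.relation_distribution)
        for name in dist:
            RelationshipType.from_string(name)  # raises VocabularyError
        if any(p < 0 for p in dist.values()):
            raise ParameterError("relation probabilities must be non-negative")
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ParameterError(f"relation distribution must sum to 1, got {sum(dist.values())}")

    def category_quotas(self) -> list[int]:
        q = self.categories_per_chapter
        if isinstance(q, int):
            return [q] * self.n_chapters
        q = list(q)
        if len(q) != self.n_chapters:
            raise ParameterError(
                f"expected {self.n_chapters} category quotas, got {len(q)}"
            )
        return q

    def subcategory_quotas(self) -> list[int]:
        n_categories = sum(self.category_quotas())
        q = self.subcategories_per_category
        if isinstance(q, int):
            return [q] * n_categories
        q = list(q)
        if len(q) != n_categories:
            raise ParameterError(f"expected {n_categories} subcategory quotas, got {len(q)}")
        return q


def _title(rng: random.Random) -> str:
    return f"{rng.choice(_MODIFIERS).capitalize()} {rng.choice(_NOUNS)}"


def make_synthetic_model(p: SynthesisParams) -> Classification:
    """Build the in-memory classification described by *p*."""
    rng = random.Random(p.seed)
    c = Classification(name="synthetic", version=f"seed-{p.seed}")
    cat_quotas = p.category_quotas()
    sub_quotas = p.subcategory_quotas()
    cat_index = 0
    for ch in range(1, p.n_chapters + 1):
        ch_code = f"{p.component}{ch}"
        c.add(ClassificationConcept(
            code=ch_code, kind="chapter",
            rubrics=[Rubric("preferred", f"Chapter {_title(rng).lower()}")],
        ))
        for j in range(cat_quotas[ch - 1]):
            cat_code = f"{ch_code}{j:02d}"
            c.add(ClassificationConcept(
                code=cat_code, kind="category",
                rubrics=[Rubric("preferred", _title(rng))],
            ))
            c.link(ch_code, cat_code)
            n_subs = sub_quotas[cat_index]
            cat_index += 1
            n_residual = int(p.residual_fraction * n_subs)  # floor, per sibling group
            for k in range(n_subs):
                sub_code = f"{cat_code}{k}"
                if k >= n_subs - n_residual:
                    prefix = "Other specified" if (n_subs - k) % 2 == 0 else "Unspecified"
                    title = f"{prefix} {_title(rng).lower()}"
                else:
                    title = _title(rng)
                c.add(ClassificationConcept(
                    code=sub_code, kind="subcategory",
                    rubrics=[Rubric("preferred", title)],
                    is_residual=k >= n_subs - n_residual,
                ))
                c.link(cat_code, sub_code)
    return c


def make_synthetic_classification(p: SynthesisParams) -> str:
    """ClaML XML text for the classification described by *p*.

    Identical parameters (including seed) produce identical bytes.
    """
    return write_claml(make_synthetic_model(p))


def make_synthetic_annotations(c: Classification, p: SynthesisParams) -> list[EdgeAnnotation]:
    """Annotate every logical non-residual edge of *c*, drawing relations
    from ``p.relation_distribution`` deterministically per seed."""
    rng = random.Random((p.seed << 1) ^ 0x5EED)
    dist = dict(p.relation_distribution)
    names = [n for n in RELATION_NAMES if dist.get(n, 0) > 0]
    weights = [dist[n] for n in names]
    out = []
    for edge in enumerate_edges(c):
        relation = RelationshipType.from_string(rng.choices(names, weights=weights)[0])
        out.append(EdgeAnnotation(edge, relation))
    return out
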