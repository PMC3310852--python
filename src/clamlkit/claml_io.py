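"""Reading and writing ClaML classification documents.

ClaML is the XML exchange format for WHO-family classifications.  The
dialect accepted here is deliberately permissive: ``Class`` elements with
``code`` and ``kind`` attributes, ``SuperClass``/``SubClass`` links, and
``Rubric``/``Label`` text.  Concepts whose code carries four or more
digits are re-kinded ``subcategory`` whatever the file says, so that the
category / subcategory split follows code shape alone.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET

from .codes import CodeInfo, chapter_of, classify_code  # noqa: F401  (re-export)
from .errors import CodeFormatError, IntegrityError, ParseError
from .model import Classification, ClassificationConcept, Rubric

__all__ = [
    "parse_claml",
    "parse_claml_file",
    "write_claml",
    "detect_residual",
    "classify_code",
    "to_tsv",
    "from_tsv",
]

CLAML_VERSION = "2.0.0"

#: Titles beginning with one of these mark residual (catch-all) classes.
RESIDUAL_PREFIXES = ("other specified", "unspecified")


def detect_residual(concept: ClassificationConcept, strict: bool = False) -> bool:
    """True iff the concept is a residual ("Other specified"/"Unspecified") class.

    Detection is title-based: the preferred title must *begin* with a
    residual cue, case-insensitively.  With ``strict=True`` a code-suffix
    heuristic is added: subcategory codes ending in 8 or 9 are also
    flagged (the conventional residual suffixes in WHO classifications).
    """
    title = concept.title.strip().lower()
    if title.startswith(RESIDUAL_PREFIXES):
        return True
    if strict and concept.kind == "subcategory" and concept.code[-1] in "89":
        return True
    return False


def _kind_for(code: str, declared: str | None) -> str:
    info = classify_code(code)
    if info.kind == "block":
        return "block"
    if info.depth >= 4:
        return "subcategory"  # re-kind regardless of the file's attribute
    if declared in ("chapter", "block", "category"):
        return declared
    return info.kind


def parse_claml(document: str | bytes, strict_residuals: bool = False) -> Classification:
    """Parse a ClaML XML document into a :class:`Classification`.

    Raises :class:`ParseError` for malformed XML (with the line number),
    :class:`IntegrityError` for duplicate codes or cycles in the
    superclass links, and :class:`CodeFormatError` for unparseable codes.
    """
    if isinstance(document, bytes):
        document = document.decode("utf-8")
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line = exc.position[0] if exc.position else None
        raise ParseError(f"malformed XML: {exc.msg.split(':')[0]}", line=line) from exc

    classification = Classification()
    title_el = root.find("Title")
    if title_el is not None:
        classification.name = title_el.get("name", "") or (title_el.text or "").strip()
        classification.version = title_el.get("version", "")

    sub_links: list[tuple[str, str]] = []  # (parent, child) in SubClass order
    super_links: list[tuple[str, str]] = []
    for class_el in root.iter("Class"):
        code = class_el.get("code")
        if not code:
            raise ParseError("Class element without a code attribute")
        concept = ClassificationConcept(code=code, kind=_kind_for(code, class_el.get("kind")))
        for rub_el in class_el.findall("Rubric"):
            label = rub_el.find("Label")
            text = "".join((label if label is not None else rub_el).itertext()).strip()
            if text:
                concept.rubrics.append(Rubric.from_raw(rub_el.get("kind", "other"), text))
        classification.add(concept)  # raises IntegrityError on duplicates
        for el in class_el.findall("SubClass"):
            child = el.get("code")
            if child:
                sub_links.append((code, child))
        for el in class_el.findall("SuperClass"):
            parent = el.get("code")
            if parent:
                super_links.append((parent, code))

    for parent, child in sub_links:
        if parent not in classification or child not in classification:
            raise IntegrityError(f"SubClass link {parent} -> {child} references unknown code")
        classification.link(parent, child)
    for parent, child in super_links:
        if parent not in classification:
            raise IntegrityError(f"SuperClass link {child} -> {parent} references unknown code")
        classification.link(parent, child)

    cycles = classification._find_cycles()
    if cycles:
        raise IntegrityError(cycles[0])

    for concept in classification:
        if concept.rubrics_of("preferred"):
            concept.is_residual = detect_residual(concept, strict=strict_residuals)
    return classification


def parse_claml_file(path, **kw) -> Classification:
    with open(path, "rb") as fh:
        return parse_claml(fh.read(), **kw)


def write_claml(c: Classification) -> str:
    """Serialize a :class:`Classification` back to ClaML XML text.

    The output re-parses to a structurally equal model.  Structural
    invariant violations abort before any output is produced.
    """
    issues = [i for i in c.validate() if i != "no chapters"]
    if issues:
        raise IntegrityError("cannot serialize invalid classification: " + "; ".join(issues))

    root = ET.Element("ClaML", version=CLAML_VERSION)
    ET.SubElement(root, "Title", name=c.name or "classification", version=c.version or "")
    for concept in c.sorted_concepts():
        # subcategories are written with the generic "category" kind, as in
        # WHO-FIC exports; the parser re-kinds by code depth
        kind = "category" if concept.kind == "subcategory" else concept.kind
        class_el = ET.SubElement(root, "Class", code=concept.code, kind=kind)
        if concept.parent_code is not None:
            ET.SubElement(class_el, "SuperClass", code=concept.parent_code)
        for child in concept.child_codes:
            ET.SubElement(class_el, "SubClass", code=child)
        for rubric in concept.rubrics:
            kind_out = rubric.kind
            if rubric.kind == "other" and rubric.note and rubric.note.startswith("original kind: "):
                kind_out = rubric.note[len("original kind: "):]
            rub_el = ET.SubElement(class_el, "Rubric", kind=kind_out)
            label = ET.SubElement(rub_el, "Label")
            label.set("xml:lang", "en")
            label.text = rubric.text
    ET.indent(root)
    buf = io.BytesIO()
    ET.ElementTree(root).write(buf, encoding="utf-8", xml_declaration=True)
    return buf.getvalue().decode("utf-8") + "\n"


# ---------------------------------------------------------------------------
# Flat TSV debugging view


def to_tsv(c: Classification) -> str:
    """Flat ``code  kind  parent  title`` view for debugging/diffing."""
    lines = ["code\tkind\tparent\ttitle"]
    for concept in c.sorted_concepts():
        lines.append(
            f"{concept.code}\t{concept.kind}\t{concept.parent_code or ''}\t{concept.title}"
        )
    return "\n".join(lines) + "\n"


def from_tsv(text: str) -> Classification:
    """Rebuild a minimal classification (preferred rubrics only) from
    :func:`to_tsv` output."""
    c = Classification()
    links = []
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if lines and lines[0].startswith("code\t"):
        lines = lines[1:]
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) != 4:
            raise ParseError(f"expected 4 tab-separated fields, got {len(parts)}: {ln!r}")
        code, kind, parent, title = parts
        c.add(ClassificationConcept(code=code, kind=kind, rubrics=[Rubric("preferred", title)]))
        if parent:
            links.append((parent, code))
    for parent, child in links:
        if parent not in c:
            raise IntegrityError(f"parent {parent} of {child} not present")
        c.link(parent, child)
    for concept in c:
        concept.is_residual = detect_residual(concept)
    return c
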