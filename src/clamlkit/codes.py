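"""Classification-code semantics.

Codes are short alphanumeric strings whose shape encodes their level:
a component letter followed by one digit is a chapter (``d1``), by three
digits a category (``d110``), by four or more digits a subcategory
(``d3550``).  Blocks are code *ranges* written ``d450-d469``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import CodeFormatError

__all__ = ["CodeInfo", "classify_code", "chapter_of"]

_SIMPLE = re.compile(r"^([A-Za-z])(\d+)$")
_BLOCK = re.compile(r"^([A-Za-z])(\d{3})-([A-Za-z])(\d{3})$")


@dataclass(frozen=True)
class CodeInfo:
    """Decomposition of a classification code."""

    code: str
    component: str  # component letter, e.g. "d"
    chapter: int  # leading digit, identifies the chapter
    kind: str  # chapter | block | category | subcategory
    depth: int  # number of digits (for blocks: digits of the range start)

    @property
    def chapter_code(self) -> str:
        return f"{self.component}{self.chapter}"


def classify_code(code: str) -> CodeInfo:
    """Decompose *code* into component letter, chapter digit, kind and depth.

    Raises :class:`CodeFormatError` for anything that is neither
    ``letter+digits`` nor a ``letter+3digits-letter+3digits`` block range.
    """
    if not isinstance(code, str) or not code:
        raise CodeFormatError(f"empty or non-string code: {code!r}")
    m = _SIMPLE.match(code)
    if m:
        letter, digits = m.group(1), m.group(2)
        depth = len(digits)
        if depth == 1:
            kind = "chapter"
        elif depth == 3:
            kind = "category"
        elif depth >= 4:
            kind = "subcategory"
        else:
            raise CodeFormatError(
                f"code {code!r} has {depth} digits; expected 1 (chapter), "
                f"3 (category) or >=4 (subcategory)"
            )
        return CodeInfo(code, letter, int(digits[0]), kind, depth)
    m = _BLOCK.match(code)
    if m:
        letter, start, letter2, end = m.groups()
        if letter != letter2:
            raise CodeFormatError(
                f"block range {code!r} mixes component letters "
                f"{letter!r} and {letter2!r}"
            )
        if int(start) > int(end):
            raise CodeFormatError(f"block range {code!r} is descending")
        return CodeInfo(code, letter, int(start[0]), "block", len(start))
    raise CodeFormatError(f"unparseable classification code: {code!r}")


def chapter_of(code: str) -> str:
    """Chapter code (letter + leading digit) that *code* belongs to."""
    return classify_code(code).chapter_code
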