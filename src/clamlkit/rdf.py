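"""A deliberately small RDF triple model with RDF/XML and Turtle support.

No RDF library ships in the target environment, so this module provides
the minimum needed to emit and re-read OWL documents: IRIs, blank nodes,
literals (with language tag or datatype), a triple set with deterministic
serialization, parsers for the two dialects, and blank-node-aware graph
isomorphism.  The writers build output text directly; the parsers go
through independent code paths (``xml.etree`` for RDF/XML, a tokenizer
for Turtle) so serializer bugs cannot hide behind a shared implementation.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Iterator

from .errors import ParseError

__all__ = [
    "IRI", "BNode", "Literal", "Graph",
    "RDF", "RDFS", "OWL", "XSD", "SKOS",
    "serialize", "parse", "isomorphic",
]

RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
OWL = "http://www.w3.org/2002/07/owl#"
XSD = "http://www.w3.org/2001/XMLSchema#"
SKOS = "http://www.w3.org/2004/02/skos/core#"

_BASE_PREFIXES = {"rdf": RDF, "rdfs": RDFS, "owl": OWL, "xsd": XSD, "skos": SKOS}


class IRI(str):
    """An absolute IRI reference."""

    __slots__ = ()


class BNode(str):
    """A blank-node label (without the ``_:`` prefix)."""

    __slots__ = ()


@dataclass(frozen=True)
class Literal:
    text: str
    lang: str | None = None
    datatype: str | None = None

    def __post_init__(self) -> None:
        if self.lang and self.datatype:
            raise ValueError("a literal cannot carry both a language tag and a datatype")


Term = IRI | BNode | Literal
Triple = tuple["IRI | BNode", IRI, Term]


class Graph:
    """An unordered set of triples."""

    def __init__(self, triples: Iterable[Triple] = ()):  # noqa: D107
        self._triples: set[Triple] = set(triples)

    def add(self, s: IRI | BNode, p: IRI, o: Term) -> None:
        self._triples.add((s, p, o))

    def discard(self, s: IRI | BNode, p: IRI, o: Term) -> None:
        self._triples.discard((s, p, o))

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triples

    def triples(self, s=None, p=None, o=None) -> list[Triple]:
        return [
            t for t in self._triples
            if (s is None or t[0] == s) and (p is None or t[1] == p) and (o is None or t[2] == o)
        ]

    def subjects(self, p=None, o=None) -> set:
        return {t[0] for t in self.triples(None, p, o)}

    def objects(self, s=None, p=None) -> set:
        return {t[2] for t in self.triples(s, p, None)}


# ---------------------------------------------------------------------------
# Shared helpers


def _sort_key(term: Term):
    if isinstance(term, IRI):
        return (0, str(term), "", "")
    if isinstance(term, BNode):
        return (1, str(term), "", "")
    return (2, term.text, term.lang or "", term.datatype or "")


def _split_iri(iri: str) -> tuple[str, str]:
    """Split an IRI into (namespace, localname) at '#' or the last '/'."""
    if "#" in iri:
        ns, local = iri.rsplit("#", 1)
        return ns + "#", local
    ns, local = iri.rsplit("/", 1)
    return ns + "/", local


_LOCAL_OK = re.compile(r"^[A-Za-z_][\w.-]*$")


def _prefix_table(graph: Graph, extra: dict[str, str] | None) -> dict[str, str]:
    table = dict(_BASE_PREFIXES)
    if extra:
        table.update(extra)
    return table


# ---------------------------------------------------------------------------
# Turtle

_TTL_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}


def _ttl_quote(text: str) -> str:
    return '"' + "".join(_TTL_ESCAPES.get(ch, ch) for ch in text) + '"'


def _ttl_term(term: Term, ns2prefix: dict[str, str]) -> str:
    if isinstance(term, BNode):
        return f"_:{term}"
    if isinstance(term, IRI):
        ns, local = _split_iri(str(term))
        if ns in ns2prefix and _LOCAL_OK.match(local):
            return f"{ns2prefix[ns]}:{local}"
        return f"<{term}>"
    out = _ttl_quote(term.text)
    if term.lang:
        out += f"@{term.lang}"
    elif term.datatype:
        ns, local = _split_iri(term.datatype)
        out += "^^" + (f"{ns2prefix[ns]}:{local}" if ns in ns2prefix else f"<{term.datatype}>")
    return out


def serialize_turtle(graph: Graph, prefixes: dict[str, str] | None = None) -> str:
    """Deterministic Turtle: sorted @prefix block, one triple per line."""
    table = _prefix_table(graph, prefixes)
    ns2prefix = {ns: p for p, ns in table.items()}
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(table.items())]
    lines.append("")
    body = sorted(graph, key=lambda t: (_sort_key(t[0]), _sort_key(t[1]), _sort_key(t[2])))
    for s, p, o in body:
        pred = "a" if p == IRI(RDF + "type") else _ttl_term(p, ns2prefix)
        lines.append(f"{_ttl_term(s, ns2prefix)} {pred} {_ttl_term(o, ns2prefix)} .")
    return "\n".join(lines) + "\n"


_TTL_TOKEN = re.compile(
    r"""\s*(?:
        (?P<iri><[^>]*>)
      | (?P<literal>"(?:[^"\\]|\\.)*")
      | (?P<bnode>_:[\w.-]+)
      | (?P<langtag>@[A-Za-z][A-Za-z0-9-]*)
      | (?P<dtsep>\^\^)
      | (?P<pname>[A-Za-z_][\w.-]*:[\w.-]*|:[\w.-]*)
      | (?P<kw>a\b)
      | (?P<dot>\.)
    )""",
    re.VERBOSE,
)

_UNESCAPE = {"\\\\": "\\", '\\"': '"', "\\n": "\n", "\\r": "\r", "\\t": "\t"}


def _ttl_unquote(quoted: str) -> str:
    return re.sub(r"\\.", lambda m: _UNESCAPE.get(m.group(0), m.group(0)[1]), quoted[1:-1])


def parse_turtle(text: str) -> Graph:
    """Parse the line-oriented Turtle subset this module emits
    (no ``;``/``,`` abbreviations, no collections)."""
    prefixes: dict[str, str] = {}
    graph = Graph()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("@prefix"):
            m = re.match(r"@prefix\s+([\w-]*):\s*<([^>]*)>\s*\.", line)
            if not m:
                raise ParseError(f"bad @prefix line: {line!r}", line=lineno)
            prefixes[m.group(1)] = m.group(2)
            continue
        terms = _parse_ttl_terms(line, prefixes, lineno)
        if len(terms) != 3:
            raise ParseError(f"expected subject predicate object '.': {line!r}", line=lineno)
        s, p, o = terms
        if isinstance(s, Literal) or not isinstance(p, IRI):
            raise ParseError(f"ill-typed triple: {line!r}", line=lineno)
        graph.add(s, p, o)
    return graph


def _parse_ttl_terms(line: str, prefixes: dict[str, str], lineno: int) -> list[Term]:
    terms: list[Term] = []
    pos = 0
    pending_dt = False
    while pos < len(line):
        m = _TTL_TOKEN.match(line, pos)
        if not m:
            raise ParseError(f"cannot tokenize near {line[pos:pos + 20]!r}", line=lineno)
        pos = m.end()
        if m.lastgroup == "dot":
            break
        if m.lastgroup == "iri":
            term: Term = IRI(m.group("iri")[1:-1])
        elif m.lastgroup == "bnode":
            term = BNode(m.group("bnode")[2:])
        elif m.lastgroup == "literal":
            term = Literal(_ttl_unquote(m.group("literal")))
        elif m.lastgroup == "langtag":
            lit = terms.pop()
            term = Literal(lit.text, lang=m.group("langtag")[1:])
        elif m.lastgroup == "dtsep":
            pending_dt = True
            continue
        elif m.lastgroup == "kw":
            term = IRI(RDF + "type")
        else:  # pname
            prefix, local = m.group("pname").split(":", 1)
            if prefix not in prefixes:
                raise ParseError(f"undeclared prefix {prefix!r}", line=lineno)
            term = IRI(prefixes[prefix] + local)
        if pending_dt:
            lit = terms.pop()
            term = Literal(lit.text, datatype=str(term))
            pending_dt = False
        terms.append(term)
    return terms


# ---------------------------------------------------------------------------
# RDF/XML


def _xml_escape(text: str, attr: bool = False) -> str:
    text = text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    if attr:
        text = text.replace('"', "&quot;").replace("\n", "&#10;").replace("\t", "&#9;")
    return text


def serialize_rdfxml(graph: Graph, prefixes: dict[str, str] | None = None) -> str:
    """Deterministic RDF/XML using flat ``rdf:Description`` elements and
    ``rdf:nodeID`` for blank nodes."""
    table = _prefix_table(graph, prefixes)
    used_ns = set()
    for s, p, o in graph:
        used_ns.add(_split_iri(str(p))[0])
    ns2prefix = {ns: pre for pre, ns in table.items()}
    for ns in sorted(used_ns):
        if ns not in ns2prefix:
            raise ValueError(f"no prefix declared for predicate namespace {ns}")

    header = ['<?xml version="1.0" encoding="utf-8"?>', "<rdf:RDF"]
    decl_prefixes = sorted({"rdf"} | {ns2prefix[ns] for ns in used_ns})
    for pre in decl_prefixes:
        header.append(f'    xmlns:{pre}="{_xml_escape(table[pre], attr=True)}"')
    header[-1] += ">"

    by_subject: dict[IRI | BNode, list[Triple]] = {}
    for t in graph:
        by_subject.setdefault(t[0], []).append(t)

    body: list[str] = []
    for subject in sorted(by_subject, key=_sort_key):
        if isinstance(subject, BNode):
            body.append(f'  <rdf:Description rdf:nodeID="{_xml_escape(subject, attr=True)}">')
        else:
            body.append(f'  <rdf:Description rdf:about="{_xml_escape(subject, attr=True)}">')
        for _, p, o in sorted(by_subject[subject], key=lambda t: (_sort_key(t[1]), _sort_key(t[2]))):
            ns, local = _split_iri(str(p))
            qname = f"{ns2prefix[ns]}:{local}"
            if isinstance(o, BNode):
                body.append(f'    <{qname} rdf:nodeID="{_xml_escape(o, attr=True)}"/>')
            elif isinstance(o, IRI):
                body.append(f'    <{qname} rdf:resource="{_xml_escape(o, attr=True)}"/>')
            elif o.lang:
                body.append(f'    <{qname} xml:lang="{o.lang}">{_xml_escape(o.text)}</{qname}>')
            elif o.datatype:
                body.append(
                    f'    <{qname} rdf:datatype="{_xml_escape(o.datatype, attr=True)}">'
                    f"{_xml_escape(o.text)}</{qname}>"
                )
            else:
                body.append(f"    <{qname}>{_xml_escape(o.text)}</{qname}>")
        body.append("  </rdf:Description>")
    return "\n".join(header + body + ["</rdf:RDF>"]) + "\n"


_XML_LANG = "{http://www.w3.org/XML/1998/namespace}lang"


def parse_rdfxml(text: str) -> Graph:
    """Parse the flat rdf:Description dialect (plus typed-node elements)."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        line = exc.position[0] if exc.position else None
        raise ParseError(f"malformed RDF/XML: {exc.msg.split(':')[0]}", line=line) from exc
    if root.tag != f"{{{RDF}}}RDF":
        raise ParseError(f"root element is {root.tag}, expected rdf:RDF")
    graph = Graph()
    for el in root:
        subject = _rdfxml_subject(el)
        if el.tag != f"{{{RDF}}}Description":
            graph.add(subject, IRI(RDF + "type"), IRI(_tag_to_iri(el.tag)))
        for prop in el:
            pred = IRI(_tag_to_iri(prop.tag))
            resource = prop.get(f"{{{RDF}}}resource")
            node_id = prop.get(f"{{{RDF}}}nodeID")
            if resource is not None:
                graph.add(subject, pred, IRI(resource))
            elif node_id is not None:
                graph.add(subject, pred, BNode(node_id))
            else:
                lang = prop.get(_XML_LANG)
                datatype = prop.get(f"{{{RDF}}}datatype")
                graph.add(subject, pred, Literal(prop.text or "", lang=lang, datatype=datatype))
    return graph


def _rdfxml_subject(el: ET.Element) -> IRI | BNode:
    about = el.get(f"{{{RDF}}}about")
    if about is not None:
        return IRI(about)
    node_id = el.get(f"{{{RDF}}}nodeID")
    if node_id is not None:
        return BNode(node_id)
    raise ParseError(f"node element {el.tag} lacks rdf:about/rdf:nodeID")


def _tag_to_iri(tag: str) -> str:
    if not tag.startswith("{"):
        raise ParseError(f"unqualified element {tag!r}")
    ns, local = tag[1:].split("}", 1)
    return ns + local


# ---------------------------------------------------------------------------
# Facade


def serialize(graph: Graph, dialect: str, prefixes: dict[str, str] | None = None) -> str:
    if dialect in ("turtle", "ttl"):
        return serialize_turtle(graph, prefixes)
    if dialect in ("rdfxml", "rdf/xml", "xml"):
        return serialize_rdfxml(graph, prefixes)
    raise ValueError(f"unknown dialect {dialect!r}; legal values: turtle, rdfxml")


def parse(text: str, dialect: str) -> Graph:
    if dialect in ("turtle", "ttl"):
        return parse_turtle(text)
    if dialect in ("rdfxml", "rdf/xml", "xml"):
        return parse_rdfxml(text)
    raise ValueError(f"unknown dialect {dialect!r}; legal values: turtle, rdfxml")


# ---------------------------------------------------------------------------
# Isomorphism


def _ground_signature(graph: Graph, colors: dict[BNode, str]) -> dict[BNode, str]:
    sig: dict[BNode, list] = {b: [] for b in colors}
    for s, p, o in graph:
        if isinstance(s, BNode):
            key = colors[o] if isinstance(o, BNode) else _sort_key(o)
            sig[s].append(("out", str(p), key))
        if isinstance(o, BNode):
            key = colors[s] if isinstance(s, BNode) else _sort_key(s)
            sig[o].append(("in", str(p), key))
    return {b: repr(sorted(v)) for b, v in sig.items()}


def _canonical(graph: Graph) -> tuple[set, dict[BNode, str]]:
    bnodes = {t[0] for t in graph if isinstance(t[0], BNode)}
    bnodes |= {t[2] for t in graph if isinstance(t[2], BNode)}
    colors: dict[BNode, str] = {b: "" for b in bnodes}
    for _ in range(3):  # colour refinement; our graphs have shallow bnode chains
        colors = _ground_signature(graph, colors)
    ground = {t for t in graph if not isinstance(t[0], BNode) and not isinstance(t[2], BNode)}
    return ground, colors


def isomorphic(g1: Graph, g2: Graph) -> bool:
    """Graph equality up to blank-node renaming."""
    if len(g1) != len(g2):
        return False
    ground1, colors1 = _canonical(g1)
    ground2, colors2 = _canonical(g2)
    if ground1 != ground2:
        return False
    if sorted(colors1.values()) != sorted(colors2.values()):
        return False
    # group by colour and try mappings within groups (groups are tiny)
    groups1: dict[str, list[BNode]] = {}
    groups2: dict[str, list[BNode]] = {}
    for b, c in colors1.items():
        groups1.setdefault(c, []).append(b)
    for b, c in colors2.items():
        groups2.setdefault(c, []).append(b)

    def try_mapping(mapping: dict[BNode, BNode]) -> bool:
        def sub(term: Term) -> Term:
            return mapping[term] if isinstance(term, BNode) else term

        return {(sub(s), p, sub(o)) for s, p, o in g1} == set(g2)

    # most graphs: all colours unique -> single candidate mapping
    option_lists = []
    keys = sorted(groups1)
    for c in keys:
        a, b = sorted(groups1[c]), sorted(groups2[c])
        if len(a) > 4:  # avoid factorial blow-up; colours should separate long before this
            return False
        option_lists.append([dict(zip(a, perm)) for perm in permutations(b)])

    def search(i: int, acc: dict[BNode, BNode]) -> bool:
        if i == len(option_lists):
            return try_mapping(acc)
        return any(search(i + 1, {**acc, **opt}) for opt in option_lists[i])

    return search(0, {})
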