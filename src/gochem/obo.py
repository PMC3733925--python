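"""OBO 1.2 flat-file reading and writing.

Covers the subset sufficient for GO/ChEBI-style content: ``[Term]`` stanzas
with id/name/namespace/def/synonym/xref/is_a/relationship/intersection_of/
is_obsolete and ``[Typedef]`` stanzas with id/name/is_a/is_transitive.
Unknown tags are preserved verbatim (queryable through
``Ontology.unsupported_tags``) so a parse/write cycle is lossless on them.

A paired ``intersection_of`` block (one genus line plus one or more
relation-filler lines) is read as a full EquivalentClasses axiom between the
term and the intersection — logical definitions are equivalences, not mere
necessary conditions.

OBO 1.2 has no syntax for general concept inclusions between unnamed class
expressions; those axioms are serialized to a sidecar plain-text dump
(``*.gci.txt``, one canonical rendering per line, UTF-8, LF endings) that
round-trips bit-exactly.

Axiom provenance survives round-trips through OBO trailing modifiers:
inferred is_a links carry ``{is_inferred="true"}``; any other non-asserted
provenance carries ``{provenance="..."}``.
"""

from __future__ import annotations

import re
from pathlib import Path

from .errors import OboParseError, OboWriteError
from .model import (
    Axiom,
    Existential,
    Intersection,
    Named,
    Ontology,
    RelationType,
    Synonym,
    Term,
    equivalent_classes,
    render,
    subclass_of,
)

__all__ = [
    "parse_obo",
    "write_obo",
    "split_axioms",
    "write_gci_text",
    "parse_gci_text",
    "save_ontology",
    "load_ontology",
]

_SUPPORTED_TERM_TAGS = {
    "id", "name", "namespace", "def", "synonym", "xref",
    "is_a", "relationship", "intersection_of", "is_obsolete",
}
_SUPPORTED_TYPEDEF_TAGS = {"id", "name", "is_a", "is_transitive"}

_DEF_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(.*)$')
_SYN_RE = re.compile(
    r'^"((?:[^"\\]|\\.)*)"(?:\s+(EXACT|BROAD|NARROW|RELATED)\b)?.*$'
)
_MODIFIER_RE = re.compile(r"\{([^{}]*)\}\s*$")


def _strip_comment(value: str) -> str:
    """Remove a trailing ``! comment``, ignoring ``!`` inside quotes."""
    in_quote = False
    i = 0
    while i < len(value):
        c = value[i]
        if c == "\\" and in_quote:
            i += 2
            continue
        if c == '"':
            in_quote = not in_quote
        elif c == "!" and not in_quote:
            return value[:i].rstrip()
        i += 1
    return value.rstrip()


def _pop_modifiers(value: str) -> tuple[str, dict[str, str]]:
    """Split off a trailing ``{key="v", ...}`` modifier block."""
    m = _MODIFIER_RE.search(value)
    if not m:
        return value, {}
    mods = {}
    for piece in m.group(1).split(","):
        piece = piece.strip()
        if not piece:
            continue
        if "=" in piece:
            k, v = piece.split("=", 1)
            mods[k.strip()] = v.strip().strip('"')
        else:
            mods[piece] = "true"
    return value[: m.start()].rstrip(), mods


def _provenance_from_modifiers(mods: dict[str, str]) -> str:
    if mods.get("is_inferred") == "true":
        return "inferred"
    return mods.get("provenance", "asserted")


def _unescape(s: str) -> str:
    return s.replace('\\"', '"').replace("\\\\", "\\")


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


# --------------------------------------------------------------------------
# Parsing

def parse_obo(text: str) -> Ontology:
    """Parse OBO 1.2 text into an :class:`Ontology`.

    The header must declare ``format-version``. Dangling axiom targets are
    registered as external references with a warning record rather than
    failing the parse.
    """
    lines = text.splitlines()
    ont = Ontology()
    i = 0
    # header
    while i < len(lines) and not lines[i].startswith("["):
        line = lines[i]
        stripped = line.strip()
        if stripped and not stripped.startswith("!"):
            if ":" not in stripped:
                raise OboParseError("malformed header line", i + 1)
            key, _, value = stripped.partition(":")
            ont.header.append((key.strip(), value.strip()))
        i += 1
    header_keys = {k for k, _ in ont.header}
    if "format-version" not in header_keys:
        raise OboParseError("missing format-version header")
    for k, v in ont.header:
        if k == "ontology":
            ont.id = v

    while i < len(lines):
        line = lines[i].strip()
        if not line or line.startswith("!"):
            i += 1
            continue
        if not line.startswith("["):
            raise OboParseError(f"expected stanza header, got {line!r}", i + 1)
        stanza_type = line.strip("[]")
        start = i
        i += 1
        tag_lines: list[tuple[str, str, int]] = []
        while i < len(lines) and not lines[i].startswith("["):
            raw = lines[i].strip()
            if raw and not raw.startswith("!"):
                if ":" not in raw:
                    raise OboParseError(f"malformed tag line {raw!r}", i + 1)
                tag, _, value = raw.partition(":")
                tag_lines.append((tag.strip(), value.strip(), i + 1))
            i += 1
        if stanza_type == "Term":
            _read_term(ont, tag_lines, start + 1)
        elif stanza_type == "Typedef":
            _read_typedef(ont, tag_lines, start + 1)
        else:
            raw_block = "\n".join(
                l for l in (x.rstrip() for x in lines[start:i]) if l
            )
            ont.unsupported_stanzas.append(raw_block)
            ont.warnings.append(f"unsupported stanza type [{stanza_type}]")

    _register_externals(ont)
    return ont


def _read_term(ont, tag_lines, stanza_line) -> None:
    tid = None
    for tag, value, lineno in tag_lines:
        if tag == "id":
            tid = _strip_comment(value)
            break
    if tid is None:
        raise OboParseError("[Term] stanza without id", stanza_line)
    term = Term(id=tid)
    synonyms: list[Synonym] = []
    xrefs: list[str] = []
    extra: list[tuple[str, str]] = []
    intersection: list[tuple[str, dict, int]] = []
    for tag, value, lineno in tag_lines:
        if tag == "id":
            continue
        if tag not in _SUPPORTED_TERM_TAGS:
            extra.append((tag, value))
            ont.unsupported_tags.append((tid, tag, value))
            continue
        body = _strip_comment(value)
        if tag == "name":
            term.label = body
        elif tag == "namespace":
            term.namespace = body
        elif tag == "def":
            m = _DEF_RE.match(body)
            if not m:
                raise OboParseError("malformed def line", lineno)
            term.textual_definition = _unescape(m.group(1))
            term.def_trailer = m.group(2)
        elif tag == "synonym":
            m = _SYN_RE.match(body)
            if not m:
                raise OboParseError("malformed synonym line", lineno)
            synonyms.append(Synonym(_unescape(m.group(1)), m.group(2) or "RELATED"))
        elif tag == "xref":
            xrefs.append(body)
        elif tag == "is_obsolete":
            term.obsolete = body.lower() == "true"
        elif tag == "is_a":
            body, mods = _pop_modifiers(body)
            target = body.strip()
            if not target:
                raise OboParseError("empty is_a target", lineno)
            ont.add_axiom(
                subclass_of(
                    Named(tid), Named(target), _provenance_from_modifiers(mods)
                )
            )
        elif tag == "relationship":
            body, mods = _pop_modifiers(body)
            parts = body.split()
            if len(parts) != 2:
                raise OboParseError("malformed relationship line", lineno)
            rel, target = parts
            ont.ensure_relation(rel)
            ont.add_axiom(
                subclass_of(
                    Named(tid),
                    Existential(rel, Named(target)),
                    _provenance_from_modifiers(mods),
                )
            )
        elif tag == "intersection_of":
            body, mods = _pop_modifiers(body)
            intersection.append((body.strip(), mods, lineno))
    if intersection:
        _finish_intersection(ont, tid, intersection)
    term.synonyms = tuple(synonyms)
    term.xrefs = tuple(xrefs)
    term.extra_tags = tuple(extra)
    ont.add_term(term)


def _finish_intersection(ont, tid, intersection) -> None:
    if len(intersection) < 2:
        raise OboParseError(
            "intersection_of block needs a genus and at least one differentia",
            intersection[0][2],
        )
    genus: str | None = None
    parts = []
    provenance = "asserted"
    for body, mods, lineno in intersection:
        if _provenance_from_modifiers(mods) != "asserted":
            provenance = _provenance_from_modifiers(mods)
        pieces = body.split()
        if len(pieces) == 1:
            if genus is not None:
                raise OboParseError(
                    "multiple genus lines in intersection_of block", lineno
                )
            genus = pieces[0]
            parts.append(Named(pieces[0]))
        elif len(pieces) == 2:
            ont.ensure_relation(pieces[0])
            parts.append(Existential(pieces[0], Named(pieces[1])))
        else:
            raise OboParseError("malformed intersection_of line", lineno)
    if genus is None:
        raise OboParseError(
            "intersection_of block lacks a genus line", intersection[0][2]
        )
    ont.add_axiom(
        equivalent_classes(Named(tid), Intersection(tuple(parts)), provenance)
    )


def _read_typedef(ont, tag_lines, stanza_line) -> None:
    rid = None
    for tag, value, lineno in tag_lines:
        if tag == "id":
            rid = _strip_comment(value)
            break
    if rid is None:
        raise OboParseError("[Typedef] stanza without id", stanza_line)
    rel = ont.relations.get(rid) or RelationType(rid)
    rel.declared = True
    parents = list(rel.parents)
    extra = list(rel.extra_tags)
    for tag, value, lineno in tag_lines:
        if tag == "id":
            continue
        body = _strip_comment(value)
        if tag not in _SUPPORTED_TYPEDEF_TAGS:
            extra.append((tag, value))
            ont.unsupported_tags.append((rid, tag, value))
        elif tag == "name":
            rel.label = body
        elif tag == "is_a":
            if body not in parents:
                parents.append(body)
        elif tag == "is_transitive":
            rel.is_transitive = body.lower() == "true"
    rel.parents = tuple(parents)
    rel.extra_tags = tuple(extra)
    ont.add_relation(rel)


def _register_externals(ont: Ontology) -> None:
    from .model import named_ids

    for ax in ont.axioms:
        for ref in named_ids(ax.a) | named_ids(ax.b):
            if ref not in ont.terms and ref not in ont.external:
                ont.add_external(ref)
                ont.warnings.append(
                    f"dangling reference {ref} registered as external"
                )


# --------------------------------------------------------------------------
# Writing

def split_axioms(ont: Ontology) -> tuple[list[Axiom], list[Axiom]]:
    """Partition axioms into stanza-hosted and sidecar (GCI) axioms.

    Stanza-hosted: SubClassOf(Named, Named), SubClassOf(Named, R some Named),
    and EquivalentClasses(Named, genus-differentia intersection) whose
    subject has a stanza. Everything else goes to the sidecar.
    """
    hosted, sidecar = [], []
    for ax in ont.axioms:
        if _hosted_form(ont, ax):
            hosted.append(ax)
        else:
            sidecar.append(ax)
    return hosted, sidecar


def _hosted_form(ont: Ontology, ax: Axiom) -> bool:
    if ax.kind == "subclass_of" and isinstance(ax.a, Named):
        if ax.a.id not in ont.terms:
            return False
        if isinstance(ax.b, Named):
            return True
        return isinstance(ax.b, Existential) and isinstance(ax.b.filler, Named)
    if ax.kind == "equivalent_classes":
        named, inter = None, None
        for x in (ax.a, ax.b):
            if isinstance(x, Named):
                named = x
            elif isinstance(x, Intersection):
                inter = x
        if named is None or inter is None or named.id not in ont.terms:
            return False
        genus = [p for p in inter.parts if isinstance(p, Named)]
        diffs = [p for p in inter.parts if isinstance(p, Existential)]
        if len(genus) != 1 or len(genus) + len(diffs) != len(inter.parts):
            return False
        return all(isinstance(d.filler, Named) for d in diffs)
    return False


def _check_serializable(ont: Ontology, ax: Axiom) -> None:
    """Reject a would-be logical definition whose differentia filler is an
    anonymous intersection: OBO intersection_of lines cannot express it, and
    hiding the whole definition in the sidecar would silently change the
    file's meaning. The user should name the inner expression instead."""
    if ax.kind != "equivalent_classes":
        return
    named = next((x for x in (ax.a, ax.b) if isinstance(x, Named)), None)
    inter = next((x for x in (ax.a, ax.b) if isinstance(x, Intersection)), None)
    if named is None or inter is None or named.id not in ont.terms:
        return
    for p in inter.parts:
        if isinstance(p, Existential) and isinstance(p.filler, Intersection):
            raise OboWriteError(
                "nested intersection inside an existential filler cannot be "
                f"serialized as intersection_of lines for {named.id}; "
                f"name the inner expression: {render(p.filler)}"
            )


def _modifier_suffix(ax: Axiom) -> str:
    if ax.provenance == "asserted":
        return ""
    if ax.provenance == "inferred" and ax.kind == "subclass_of":
        return ' {is_inferred="true"}'
    return f' {{provenance="{ax.provenance}"}}'


def write_obo(ont: Ontology) -> str:
    """Serialize to OBO 1.2. Stanzas sorted by id, tags in canonical order.

    GCI-style axioms are not emitted here; use :func:`write_gci_text` for
    the sidecar (see :func:`split_axioms`).
    """
    hosted, _ = split_axioms(ont)
    for ax in ont.axioms:
        _check_serializable(ont, ax)
    by_subject: dict[str, list[Axiom]] = {}
    for ax in hosted:
        subject = ax.a if isinstance(ax.a, Named) else ax.b
        by_subject.setdefault(subject.id, []).append(ax)

    out: list[str] = []
    header = list(ont.header)
    if not any(k == "format-version" for k, _ in header):
        header.insert(0, ("format-version", "1.2"))
    for k, v in header:
        out.append(f"{k}: {v}" if v else f"{k}:")
    for tid in sorted(ont.terms):
        term = ont.terms[tid]
        out.append("")
        out.append("[Term]")
        out.append(f"id: {tid}")
        if term.label:
            out.append(f"name: {term.label}")
        if term.namespace:
            out.append(f"namespace: {term.namespace}")
        if term.textual_definition or term.def_trailer:
            trailer = term.def_trailer or "[]"
            out.append(f'def: "{_escape(term.textual_definition)}" {trailer}')
        for syn in term.synonyms:
            out.append(f'synonym: "{_escape(syn.text)}" {syn.scope} []')
        for xref in term.xrefs:
            out.append(f"xref: {xref}")
        axs = sorted(by_subject.get(tid, []), key=Axiom.sort_key)
        for ax in axs:
            if ax.kind == "subclass_of" and isinstance(ax.b, Named):
                out.append(f"is_a: {ax.b.id}{_modifier_suffix(ax)}")
        for ax in axs:
            if ax.kind == "equivalent_classes":
                inter = ax.b if isinstance(ax.a, Named) else ax.a
                genus = [p for p in inter.parts if isinstance(p, Named)][0]
                diffs = [p for p in inter.parts if isinstance(p, Existential)]
                out.append(
                    f"intersection_of: {genus.id}{_modifier_suffix(ax)}"
                )
                for d in sorted(diffs, key=render):
                    out.append(
                        f"intersection_of: {d.relation} {d.filler.id}"
                    )
        for ax in axs:
            if ax.kind == "subclass_of" and isinstance(ax.b, Existential):
                out.append(
                    f"relationship: {ax.b.relation} {ax.b.filler.id}"
                    f"{_modifier_suffix(ax)}"
                )
        if term.obsolete:
            out.append("is_obsolete: true")
        for tag, value in term.extra_tags:
            out.append(f"{tag}: {value}")
    for rid in sorted(ont.relations):
        rel = ont.relations[rid]
        if not rel.declared:
            continue
        out.append("")
        out.append("[Typedef]")
        out.append(f"id: {rid}")
        if rel.label:
            out.append(f"name: {rel.label}")
        for p in rel.parents:
            out.append(f"is_a: {p}")
        if rel.is_transitive:
            out.append("is_transitive: true")
        for tag, value in rel.extra_tags:
            out.append(f"{tag}: {value}")
    for block in ont.unsupported_stanzas:
        out.append("")
        out.append(block)
    return "\n".join(out) + "\n"


# --------------------------------------------------------------------------
# GCI sidecar

def write_gci_text(axioms: list[Axiom]) -> str:
    """One canonical rendering per line; bit-exact round-trip."""
    lines = []
    for ax in sorted(axioms, key=Axiom.sort_key):
        name = (
            "EquivalentClasses"
            if ax.kind == "equivalent_classes"
            else "SubClassOf"
        )
        lines.append(
            f"{name}({render(ax.a)}, {render(ax.b)})"
            f' {{provenance="{ax.provenance}"}}'
        )
    return "\n".join(lines) + ("\n" if lines else "")


def parse_gci_text(text: str) -> list[Axiom]:
    out = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        body, mods = _pop_modifiers(line)
        m = re.match(r"^(EquivalentClasses|SubClassOf)\((.*)\)$", body)
        if not m:
            raise OboParseError("malformed axiom line", lineno)
        kind = (
            "equivalent_classes"
            if m.group(1) == "EquivalentClasses"
            else "subclass_of"
        )
        a_text, b_text = _split_top_level_comma(m.group(2), lineno)
        out.append(
            Axiom(
                kind,
                parse_expression(a_text),
                parse_expression(b_text),
                mods.get("provenance", "asserted"),
            )
        )
    return out


def _split_top_level_comma(s: str, lineno: int) -> tuple[str, str]:
    depth = 0
    for i, c in enumerate(s):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
        elif c == "," and depth == 0:
            return s[:i].strip(), s[i + 1:].strip()
    raise OboParseError("expected two operands", lineno)


def parse_expression(text: str):
    """Parse the canonical rendering grammar:

    ``expr := part (" and " part)*``;
    ``part := "(" expr ")" | REL " some " part | CURIE``.
    """
    tokens = _tokenize(text)
    expr, pos = _parse_intersection(tokens, 0)
    if pos != len(tokens):
        raise OboParseError(f"trailing tokens in expression {text!r}")
    return expr


def _tokenize(text: str) -> list[str]:
    return re.findall(r"\(|\)|[^\s()]+", text)


def _parse_intersection(tokens, pos):
    parts = []
    part, pos = _parse_part(tokens, pos)
    parts.append(part)
    while pos < len(tokens) and tokens[pos] == "and":
        part, pos = _parse_part(tokens, pos + 1)
        parts.append(part)
    if len(parts) == 1:
        return parts[0], pos
    return Intersection(tuple(parts)), pos


def _parse_part(tokens, pos):
    if pos >= len(tokens):
        raise OboParseError("unexpected end of expression")
    tok = tokens[pos]
    if tok == "(":
        expr, pos = _parse_intersection(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise OboParseError("unbalanced parenthesis in expression")
        return expr, pos + 1
    if pos + 1 < len(tokens) and tokens[pos + 1] == "some":
        filler, newpos = _parse_part(tokens, pos + 2)
        return Existential(tok, filler), newpos
    return Named(tok), pos + 1


# --------------------------------------------------------------------------
# File convenience

def save_ontology(ont: Ontology, path: str | Path) -> list[Path]:
    """Write ``path`` (OBO) plus a ``.gci.txt`` sidecar when GCIs exist."""
    path = Path(path)
    written = [path]
    path.write_text(write_obo(ont), encoding="utf-8")
    _, sidecar = split_axioms(ont)
    if sidecar:
        sc = path.with_suffix(".gci.txt")
        sc.write_text(write_gci_text(sidecar), encoding="utf-8")
        written.append(sc)
    return written


def load_ontology(path: str | Path) -> Ontology:
    """Read an OBO file, merging a ``.gci.txt`` sidecar when present."""
    path = Path(path)
    ont = parse_obo(path.read_text(encoding="utf-8"))
    sc = path.with_suffix(".gci.txt")
    if sc.exists():
        for ax in parse_gci_text(sc.read_text(encoding="utf-8")):
            ont.add_axiom(ax)
        _register_externals(ont)
    return ont
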