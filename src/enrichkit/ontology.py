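"""OBO ontology parsing and DAG queries.

The Gene Ontology distributes its term hierarchy as an OBO 1.2 flat file of
``[Term]`` stanzas.  Annotation propagation (the "true-path rule": a gene
annotated to a term is implicitly annotated to every ancestor of that term)
needs only a small slice of the format: term ids, names, namespaces, ``is_a``
and ``part_of`` edges, alternative ids of merged terms, and the obsolete flag.
This module parses exactly that slice, validates that the resulting relation
graph is acyclic with no dangling parent references, and serves memoized
ancestor queries.

The parser is deliberately self-contained rather than delegating to a general
ontology library: the error contract (line-numbered stanza errors, explicit
dangling-reference and cycle reports) and the retention of obsolete terms are
part of this package's interface, and the subset of OBO it needs is small.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import OboParseError, ObsoleteTermError, UnknownTermError

#: Relationship types followed during annotation propagation.  ``is_a`` and
#: ``part_of`` are the standard GO propagation relations; all other
#: relationship types found in OBO stanzas are ignored.
DEFAULT_RELATIONS: frozenset[str] = frozenset({"is_a", "part_of"})


@dataclass
class OntologyTerm:
    """One ontology term.

    Attributes
    ----------
    term_id:
        Primary accession, e.g. ``"GO:0008150"``.
    name:
        Human-readable label (may be empty if the stanza carried none).
    namespace:
        One of ``biological_process``, ``molecular_function``,
        ``cellular_component`` for GO, or whatever label a non-GO ontology
        declares.  Empty string when the stanza is silent.
    is_a_parents, part_of_parents:
        Direct parents under the respective relation.
    alt_ids:
        Alternative (merged) accessions that resolve to this term.
    obsolete:
        Obsolete terms are retained and flagged but carry no parents and
        never receive annotations.
    """

    term_id: str
    name: str = ""
    namespace: str = ""
    is_a_parents: set[str] = field(default_factory=set)
    part_of_parents: set[str] = field(default_factory=set)
    alt_ids: set[str] = field(default_factory=set)
    obsolete: bool = False

    def parents(self, relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        """Direct parents under the selected relation subset."""
        out: set[str] = set()
        relations = set(relations)
        if "is_a" in relations:
            out |= self.is_a_parents
        if "part_of" in relations:
            out |= self.part_of_parents
        return out


class Ontology:
    """A parsed ontology: terms plus an index of alternative ids.

    The relation graph over ``is_a`` and ``part_of`` edges is guaranteed
    acyclic and closed (every referenced parent exists) by construction; see
    :func:`parse_obo`.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self.alt_id_index: dict[str, str] = {}
        for term in self.terms.values():
            for alt in term.alt_ids:
                self.alt_id_index[alt] = term.term_id
        # one memo cache per relation subset
        self._ancestor_cache: dict[frozenset[str], dict[str, frozenset[str]]] = {}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_id_index

    def resolve(self, term_id: str) -> str:
        """Map an accession (primary or alternative) to its primary term id."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_id_index:
            return self.alt_id_index[term_id]
        raise UnknownTermError(f"unknown term id: {term_id!r}")

    def roots(self, relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        """Non-obsolete terms with no parents under the selected relations."""
        rel = frozenset(relations)
        return {
            t.term_id
            for t in self.terms.values()
            if not t.obsolete and not t.parents(rel)
        }

    def namespace_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace

    def ancestors(
        self, term_id: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> frozenset[str]:
        """Transitive closure of parents under ``relations``, excluding the
        term itself.

        The query term may be given by an alternative id.  Results are
        memoized per relation subset, so repeated calls cost no more than one
        traversal of the graph overall.

        Raises
        ------
        UnknownTermError
            If ``term_id`` resolves to no term at all.
        ObsoleteTermError
            If it resolves to an obsolete term (distinguished from unknown
            because obsolete terms have no parents to propagate over).
        """
        primary = self.resolve(term_id)
        term = self.terms[primary]
        if term.obsolete:
            raise ObsoleteTermError(f"term {primary} is obsolete")
        rel = frozenset(relations)
        cache = self._ancestor_cache.setdefault(rel, {})
        return self._ancestors_memo(primary, rel, cache)

    def _ancestors_memo(
        self, term_id: str, rel: frozenset[str], cache: dict[str, frozenset[str]]
    ) -> frozenset[str]:
        # iterative post-order so deep chains do not hit the recursion limit
        stack = [term_id]
        while stack:
            current = stack[-1]
            if current in cache:
                stack.pop()
                continue
            parents = self.terms[current].parents(rel)
            pending = [p for p in parents if p not in cache]
            if pending:
                stack.extend(pending)
                continue
            closure: set[str] = set(parents)
            for p in parents:
                closure |= cache[p]
            cache[current] = frozenset(closure)
            stack.pop()
        return cache[term_id]


def _strip_comment(line: str) -> str:
    """Remove an OBO trailing comment: text after an unescaped ``!``."""
    out = []
    escaped = False
    for ch in line:
        if escaped:
            out.append(ch)
            escaped = False
        elif ch == "\\":
            out.append(ch)
            escaped = True
        elif ch == "!":
            break
        else:
            out.append(ch)
    return "".join(out).strip()


def _iter_stanzas(lines: Iterable[str]) -> Iterator[tuple[str, int, list[tuple[int, str, str]]]]:
    """Yield (stanza_type, start_line, [(line_no, tag, value), ...])."""
    stanza_type: str | None = None
    start = 0
    body: list[tuple[int, str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = _strip_comment(raw.rstrip("\n"))
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            if stanza_type is not None:
                yield stanza_type, start, body
            stanza_type = line[1:-1]
            start = lineno
            body = []
            continue
        if stanza_type is None:
            continue  # header (format-version etc.)
        if ":" not in line:
            raise OboParseError(f"tag line without ':' in [{stanza_type}] stanza: {line!r}", lineno)
        tag, value = line.split(":", 1)
        body.append((lineno, tag.strip(), value.strip()))
    if stanza_type is not None:
        yield stanza_type, start, body


def _find_cycle(terms: Mapping[str, OntologyTerm]) -> list[str] | None:
    """Return one cycle over is_a ∪ part_of edges, or None if acyclic."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = {t: WHITE for t in terms}
    for start in terms:
        if color[start] != WHITE:
            continue
        path: list[str] = []
        stack: list[tuple[str, Iterator[str]]] = [
            (start, iter(sorted(terms[start].parents())))
        ]
        color[start] = GREY
        path.append(start)
        while stack:
            node, it = stack[-1]
            advanced = False
            for parent in it:
                if parent not in terms:
                    continue  # dangling refs reported separately
                if color[parent] == GREY:
                    return path[path.index(parent):] + [parent]
                if color[parent] == WHITE:
                    color[parent] = GREY
                    path.append(parent)
                    stack.append((parent, iter(sorted(terms[parent].parents()))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                path.pop()
                stack.pop()
    return None


def parse_obo(stream) -> Ontology:
    """Parse OBO 1.2 text into an :class:`Ontology`.

    ``stream`` may be an iterable of lines, an open text file, or a string of
    OBO text.  Only ``[Term]`` stanzas are kept; ``[Typedef]`` and other
    stanza types are skipped.  Trailing ``!`` comments are stripped.

    Raises :class:`OboParseError` for a stanza missing its ``id:`` line, for
    parent references to terms absent from the file, and for cyclic relation
    graphs (the message lists one cycle).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    terms: dict[str, OntologyTerm] = {}
    for stanza_type, start, body in _iter_stanzas(stream):
        if stanza_type != "Term":
            continue
        term_id = None
        for _, tag, value in body:
            if tag == "id":
                term_id = value
                break
        if not term_id:
            raise OboParseError("[Term] stanza missing 'id:' tag", start)
        term = OntologyTerm(term_id=term_id)
        for lineno, tag, value in body:
            if tag == "name":
                term.name = value
            elif tag == "namespace":
                term.namespace = value
            elif tag == "is_a":
                if not value:
                    raise OboParseError("empty is_a target", lineno)
                term.is_a_parents.add(value.split()[0])
            elif tag == "relationship":
                parts = value.split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    term.part_of_parents.add(parts[1])
                # other relationship types (regulates, has_part, ...) ignored
            elif tag == "alt_id":
                term.alt_ids.add(value)
            elif tag == "is_obsolete":
                term.obsolete = value.lower() == "true"
        if term.obsolete:
            # obsolete terms may not carry parents; drop any that slipped in
            term.is_a_parents.clear()
            term.part_of_parents.clear()
        terms[term.term_id] = term

    missing = sorted(
        parent
        for term in terms.values()
        for parent in term.parents()
        if parent not in terms
    )
    if missing:
        raise OboParseError(
            "dangling parent reference(s): " + ", ".join(sorted(set(missing)))
        )
    cycle = _find_cycle(terms)
    if cycle is not None:
        raise OboParseError("cycle detected: " + " -> ".join(cycle))
    return Ontology(terms)


def to_obo_text(ontology: Ontology) -> str:
    """Minimal deterministic OBO serialization of the parsed model.

    Writes only the fields the parser reads, in sorted order, so that
    ``parse_obo(to_obo_text(o))`` reproduces the same term and edge sets.
    """
    out = ["format-version: 1.2", ""]
    for term_id in sorted(ontology.terms):
        term = ontology.terms[term_id]
        out.append("[Term]")
        out.append(f"id: {term.term_id}")
        if term.name:
            out.append(f"name: {term.name}")
        if term.namespace:
            out.append(f"namespace: {term.namespace}")
        for alt in sorted(term.alt_ids):
            out.append(f"alt_id: {alt}")
        for parent in sorted(term.is_a_parents):
            out.append(f"is_a: {parent}")
        for parent in sorted(term.part_of_parents):
            out.append(f"relationship: part_of {parent}")
        if term.obsolete:
            out.append("is_obsolete: true")
        out.append("")
    return "\n".join(out) + "\n"
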