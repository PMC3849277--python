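"""OBO 1.2 parsing and the GO DAG.

The graph keeps only ``is_a`` and ``part_of`` edges; every other relationship
type is dropped at parse time.  Obsolete terms are excluded entirely.  Term
levels follow the longest-path convention: the namespace root has level 0 and
``level(t) = 1 + max(level(parent))``.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .errors import (
    CycleError,
    NamespaceMismatchError,
    OboParseError,
    UnknownIdentifierError,
)

GO_ID_RE = re.compile(r"^GO:\d{7}$")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

RELATIONS = ("is_a", "part_of")


@dataclass
class TermRecord:
    """One non-obsolete ``[Term]`` stanza reduced to the fields we use."""

    term_id: str
    name: str = ""
    namespace: str = ""
    parents: list[tuple[str, str]] = field(default_factory=list)
    is_obsolete: bool = False
    alt_ids: list[str] = field(default_factory=list)


class OntologyGraph:
    """The GO DAG restricted to is_a/part_of, with ancestor machinery.

    Attributes
    ----------
    terms : dict mapping primary term id to :class:`TermRecord`
    roots : dict mapping namespace to its (unique) root term id
    children_index : dict mapping term id to list of (child_id, relation)
    levels : dict mapping term id to its longest-path depth from the root
    """

    def __init__(self, terms: dict[str, TermRecord], alt_index: dict[str, str]):
        self.terms = terms
        self._alt = alt_index
        self.children_index: dict[str, list[tuple[str, str]]] = {t: [] for t in terms}
        for rec in terms.values():
            for pid, rel in rec.parents:
                self.children_index[pid].append((rec.term_id, rel))
        self.roots = self._find_roots()
        self._order = self._toposort()
        self.levels = self._compute_levels()
        self._anc_cache: dict[str, frozenset[str]] = {}

    # -- construction helpers -------------------------------------------------

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, str] = {}
        for rec in self.terms.values():
            if rec.parents:
                continue
            if rec.namespace in roots:
                raise OboParseError(
                    f"namespace {rec.namespace} has multiple parentless terms: "
                    f"{roots[rec.namespace]} and {rec.term_id}"
                )
            roots[rec.namespace] = rec.term_id
        return roots

    def _toposort(self) -> list[str]:
        """Parents-before-children order; raises CycleError on failure."""
        indeg = {t: len(rec.parents) for t, rec in self.terms.items()}
        queue = deque(sorted(t for t, d in indeg.items() if d == 0))
        order: list[str] = []
        while queue:
            t = queue.popleft()
            order.append(t)
            for child, _rel in self.children_index[t]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if len(order) != len(self.terms):
            remaining = {t for t, d in indeg.items() if d > 0}
            t = min(remaining)
            seen: list[str] = []
            while t not in seen:
                seen.append(t)
                t = next(p for p, _ in self.terms[t].parents if p in remaining)
            raise CycleError(f"cycle detected through edge {seen[-1]} -> {t}")
        return order

    def _compute_levels(self) -> dict[str, int]:
        levels: dict[str, int] = {}
        for t in self._order:
            parents = self.terms[t].parents
            levels[t] = 0 if not parents else 1 + max(levels[p] for p, _ in parents)
        return levels

    # -- lookups --------------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Map an id (possibly an alt_id) to its primary id."""
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            return self._alt[term_id]
        raise UnknownIdentifierError(f"unknown GO id: {term_id}")

    def is_alt(self, term_id: str) -> bool:
        return term_id not in self.terms and term_id in self._alt

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def namespace_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace

    def level(self, term_id: str) -> int:
        return self.levels[self.resolve(term_id)]

    def name_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].name

    def parents(self, term_id: str) -> list[tuple[str, str]]:
        return self.terms[self.resolve(term_id)].parents

    def children(self, term_id: str) -> list[tuple[str, str]]:
        return self.children_index[self.resolve(term_id)]

    def terms_in(self, namespace: str) -> list[str]:
        """Term ids of one namespace in parents-before-children order."""
        return [t for t in self._order if self.terms[t].namespace == namespace]

    def leaves_in(self, namespace: str) -> list[str]:
        return [t for t in self.terms_in(namespace) if not self.children_index[t]]

    # -- ancestor machinery ---------------------------------------------------

    def ancestors(self, term_id: str, inclusive: bool = False) -> frozenset[str]:
        """Terms reachable by following is_a/part_of edges upward."""
        t = self.resolve(term_id)
        strict = self._strict_ancestors(t)
        return strict | {t} if inclusive else strict

    def _strict_ancestors(self, t: str) -> frozenset[str]:
        cached = self._anc_cache.get(t)
        if cached is not None:
            return cached
        # iterative to survive deep chains
        stack = [t]
        while stack:
            node = stack[-1]
            missing = [
                p for p, _ in self.terms[node].parents if p not in self._anc_cache
            ]
            if missing:
                stack.extend(missing)
                continue
            stack.pop()
            acc: set[str] = set()
            for p, _ in self.terms[node].parents:
                acc.add(p)
                acc |= self._anc_cache[p]
            self._anc_cache[node] = frozenset(acc)
        return self._anc_cache[t]

    def common_ancestors(self, t1: str, t2: str) -> frozenset[str]:
        """Intersection of the two inclusive ancestor sets (same namespace)."""
        a, b = self.resolve(t1), self.resolve(t2)
        if self.terms[a].namespace != self.terms[b].namespace:
            raise NamespaceMismatchError(
                f"{t1} ({self.terms[a].namespace}) and {t2} "
                f"({self.terms[b].namespace}) are in different namespaces"
            )
        return self.ancestors(a, inclusive=True) & self.ancestors(b, inclusive=True)


def _iter_lines(stream: str | TextIO | Iterable[str]) -> Iterable[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream


def parse_obo(stream: str | TextIO | Iterable[str]) -> OntologyGraph:
    """Parse OBO 1.2 text into an :class:`OntologyGraph`.

    Keeps non-obsolete ``[Term]`` stanzas; ``is_a`` and ``relationship:
    part_of`` become edges, every other relationship type is ignored.
    Raises :class:`OboParseError` on an empty stream, a malformed stanza,
    cross-namespace parentage or a cycle.
    """
    records: list[TermRecord] = []
    current: TermRecord | None = None
    in_term = False

    def flush() -> None:
        nonlocal current
        if current is not None:
            if not current.term_id:
                raise OboParseError("[Term] stanza without an id")
            records.append(current)
        current = None

    for raw in _iter_lines(stream):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            if in_term:
                current = TermRecord(term_id="")
            continue
        if not in_term or current is None:
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        # strip trailing " ! <label>" comments
        if " ! " in value:
            value = value.split(" ! ", 1)[0].strip()
        if key == "id":
            if not GO_ID_RE.match(value):
                raise OboParseError(f"malformed term id: {value!r}")
            current.term_id = value
        elif key == "name":
            current.name = value
        elif key == "namespace":
            if value not in NAMESPACES:
                raise OboParseError(f"unknown namespace: {value!r}")
            current.namespace = value
        elif key == "is_a":
            current.parents.append((value, "is_a"))
        elif key == "relationship":
            parts = value.split()
            if len(parts) >= 2 and parts[0] == "part_of":
                current.parents.append((parts[1], "part_of"))
            # other relationship types dropped
        elif key == "alt_id":
            current.alt_ids.append(value)
        elif key == "is_obsolete":
            current.is_obsolete = value.lower() == "true"
    flush()

    terms: dict[str, TermRecord] = {}
    for rec in records:
        if rec.is_obsolete:
            continue  # obsolete ids are not resolvable unless alt_id elsewhere
        if rec.term_id in terms:
            raise OboParseError(f"duplicate term id {rec.term_id}")
        terms[rec.term_id] = rec
    if not terms:
        raise OboParseError("no usable [Term] stanzas found")

    alt_index: dict[str, str] = {}
    for rec in terms.values():
        for alt in rec.alt_ids:
            alt_index[alt] = rec.term_id

    for rec in terms.values():
        for pid, rel in rec.parents:
            if pid not in terms:
                raise OboParseError(
                    f"{rec.term_id}: parent {pid} ({rel}) is not a usable term"
                )
            if terms[pid].namespace != rec.namespace:
                raise OboParseError(
                    f"{rec.term_id} ({rec.namespace}) has parent {pid} in "
                    f"namespace {terms[pid].namespace}"
                )

    return OntologyGraph(terms, alt_index)
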