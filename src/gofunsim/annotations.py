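"""GAF 2.x parsing, annotation closures and term usage statistics."""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .errors import (
    AmbiguousIdentifierError,
    GafParseError,
    UnknownIdentifierError,
)
from .ontology import OntologyGraph

log = logging.getLogger(__name__)

# GAF 2.x column offsets (0-based)
_COL_OBJECT_ID = 1
_COL_SYMBOL = 2
_COL_QUALIFIER = 3
_COL_GO_ID = 4
_COL_EVIDENCE = 6
_MIN_COLUMNS = 15


@dataclass
class TermUsage:
    """Per-namespace protein counts f(t) and probabilities p(t) = f(t)/f(root).

    f(t) counts proteins whose annotation closure contains t, so counts are
    monotone along edges and p(root) is exactly 1.
    """

    namespace: str
    counts: dict[str, int]
    probabilities: dict[str, float]
    n_proteins: int


class AnnotationCorpus:
    """Per-protein direct GO term sets and their ancestor closures."""

    def __init__(self, graph: OntologyGraph):
        self.graph = graph
        self._direct: dict[tuple[str, str], set[str]] = {}
        self.gene_names: dict[str, set[str]] = {}
        self.skipped: dict[str, int] = {
            "not_qualified": 0,
            "evidence_excluded": 0,
            "unknown_term": 0,
            "malformed": 0,
        }
        self._closures: dict[tuple[str, str], frozenset[str]] = {}
        self._usage: dict[str, TermUsage] = {}

    # -- population (used by parse_gaf) --------------------------------------

    def _add(self, protein: str, symbol: str, term: str) -> None:
        ns = self.graph.namespace_of(term)
        self._direct.setdefault((protein, ns), set()).add(self.graph.resolve(term))
        if symbol:
            self.gene_names.setdefault(symbol.lower(), set()).add(protein)

    # -- queries --------------------------------------------------------------

    def namespaces(self) -> list[str]:
        return sorted({ns for _, ns in self._direct})

    def proteins(self, namespace: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, ns in self._direct if ns == namespace))

    def n_proteins(self, namespace: str) -> int:
        return sum(1 for _, ns in self._direct if ns == namespace)

    def direct(self, protein: str, namespace: str) -> frozenset[str]:
        return frozenset(self._direct.get((protein, namespace), frozenset()))

    def closure(self, protein: str, namespace: str) -> frozenset[str]:
        """Direct terms plus all their ancestors (true-path closure)."""
        key = (protein, namespace)
        if key not in self._closures:
            acc: set[str] = set()
            for t in self._direct.get(key, ()):
                acc.add(t)
                acc |= self.graph.ancestors(t)
            self._closures[key] = frozenset(acc)
        return self._closures[key]

    def usage(self, namespace: str) -> TermUsage:
        if namespace not in self._usage:
            counts: dict[str, int] = {}
            proteins = self.proteins(namespace)
            for p in proteins:
                for t in self.closure(p, namespace):
                    counts[t] = counts.get(t, 0) + 1
            n = len(proteins)
            probs = {t: c / n for t, c in counts.items()} if n else {}
            self._usage[namespace] = TermUsage(namespace, counts, probs, n)
        return self._usage[namespace]

    def resolve(self, identifier: str) -> str:
        """Canonical protein id for an accession or (case-insensitive) gene symbol."""
        if any(identifier == p for p, _ in self._direct):
            return identifier
        hits = self.gene_names.get(identifier.lower())
        if hits:
            if len(hits) > 1:
                raise AmbiguousIdentifierError(
                    f"gene symbol {identifier!r} is ambiguous: "
                    + ", ".join(sorted(hits))
                )
            return next(iter(hits))
        known = sorted({p for p, _ in self._direct} | set(self.gene_names))
        near = difflib.get_close_matches(identifier, known, n=3)
        hint = f" (did you mean: {', '.join(near)}?)" if near else ""
        raise UnknownIdentifierError(f"unknown protein or gene: {identifier!r}{hint}")


def _iter_lines(stream: str | TextIO | Iterable[str]) -> Iterable[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream


def parse_gaf(
    stream: str | TextIO | Iterable[str],
    graph: OntologyGraph,
    exclude_evidence: frozenset[str] | set[str] = frozenset(),
    strict: bool = False,
) -> AnnotationCorpus:
    """Parse a GAF 2.x stream into an :class:`AnnotationCorpus`.

    NOT-qualified rows and rows with excluded evidence codes are dropped.
    Term ids are resolved through alt_id; unknown or obsolete terms are
    skipped with a logged count.  Malformed lines are logged and skipped, or
    raise :class:`GafParseError` in strict mode.  A corpus with zero usable
    annotations is a hard error.
    """
    corpus = AnnotationCorpus(graph)
    n_rows = 0
    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < _MIN_COLUMNS:
            if strict:
                raise GafParseError(
                    f"line {lineno}: expected >= {_MIN_COLUMNS} columns, "
                    f"got {len(cols)}"
                )
            log.warning("skipping malformed GAF line %d", lineno)
            corpus.skipped["malformed"] += 1
            continue
        qualifier = cols[_COL_QUALIFIER]
        if "NOT" in qualifier.split("|"):
            corpus.skipped["not_qualified"] += 1
            continue
        if cols[_COL_EVIDENCE] in exclude_evidence:
            corpus.skipped["evidence_excluded"] += 1
            continue
        term = cols[_COL_GO_ID]
        if term not in graph:
            log.warning("line %d: unknown or obsolete term %s", lineno, term)
            corpus.skipped["unknown_term"] += 1
            continue
        corpus._add(cols[_COL_OBJECT_ID], cols[_COL_SYMBOL], term)
        n_rows += 1
    if n_rows == 0:
        raise GafParseError("no usable annotation rows found")
    return corpus


def term_usage(corpus: AnnotationCorpus, namespace: str) -> TermUsage:
    return corpus.usage(namespace)


def resolve_protein(corpus: AnnotationCorpus, identifier: str) -> str:
    return corpus.resolve(identifier)
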