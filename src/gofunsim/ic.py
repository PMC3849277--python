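"""Term information content: annotation model and three topology models.

All ICs are in natural-log units.  The annotation model is defined only on
terms used in the corpus; the Zhang and GO-universal models cover every term
of a namespace.  Wang semantic values are per-anchor contributions, not a
global table, and live in :class:`WangSValues`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TextIO

from .annotations import TermUsage
from .errors import ParameterError, TermUnusedError
from .ontology import OntologyGraph

IC_MODELS = ("annotation", "zhang", "universal")

DEFAULT_W_IS_A = 0.8
DEFAULT_W_PART_OF = 0.6


@dataclass
class ICTable:
    """One term -> IC map for a single model and namespace."""

    model: str
    namespace: str
    values: dict[str, float]
    ic_max: float = field(init=False)

    def __post_init__(self) -> None:
        if self.model not in IC_MODELS:
            raise ParameterError(f"unknown IC model: {self.model!r}")
        self.ic_max = max(self.values.values(), default=0.0)

    def __contains__(self, term: str) -> bool:
        return term in self.values

    def __getitem__(self, term: str) -> float:
        try:
            return self.values[term]
        except KeyError:
            raise TermUnusedError(
                f"term {term} has no {self.model} IC "
                f"(unused in corpus or outside namespace)"
            ) from None

    def uniformized(self, term: str) -> float:
        """IC scaled into [0,1] by the namespace maximum."""
        if self.ic_max == 0.0:
            return 0.0
        return self[term] / self.ic_max


@dataclass
class WangSValues:
    """Semantic contributions of one anchor term to its inclusive ancestors."""

    anchor: str
    svalues: dict[str, float]
    sv_total: float


def annotation_ic(usage: TermUsage) -> ICTable:
    """IC(t) = -ln p(t) over corpus usage probabilities."""
    if not usage.probabilities:
        raise ParameterError("empty term usage: cannot build annotation IC")
    values: dict[str, float] = {}
    for t, p in usage.probabilities.items():
        if not 0.0 < p <= 1.0:
            raise ParameterError(f"invalid usage probability p({t}) = {p}")
        values[t] = -math.log(p) + 0.0  # avoid -0.0 at the root
    return ICTable("annotation", usage.namespace, values)


def zhang_ic(graph: OntologyGraph, namespace: str) -> ICTable:
    """Descendant-leaf count model: D(leaf)=1, D(t)=sum over children,
    IC(t) = -ln(D(t)/D(root))."""
    order = graph.terms_in(namespace)
    if not order:
        raise ParameterError(f"namespace {namespace!r} not present in graph")
    d: dict[str, float] = {}
    for t in reversed(order):  # children before parents
        kids = graph.children_index[t]
        d[t] = sum(d[c] for c, _ in kids) if kids else 1.0
    d_root = d[graph.roots[namespace]]
    values = {t: -math.log(d[t] / d_root) + 0.0 for t in order}
    return ICTable("zhang", namespace, values)


def universal_ic(graph: OntologyGraph, namespace: str) -> ICTable:
    """Topological-position model: A(root)=1,
    A(t) = prod over parents p of A(p)/|children(p)|, IC(t) = -ln A(t)."""
    order = graph.terms_in(namespace)
    if not order:
        raise ParameterError(f"namespace {namespace!r} not present in graph")
    a: dict[str, float] = {}
    for t in order:  # parents before children
        parents = graph.terms[t].parents
        if not parents:
            a[t] = 1.0
        else:
            val = 1.0
            for p, _ in parents:
                val *= a[p] / len(graph.children_index[p])
            a[t] = val
    values = {t: -math.log(a[t]) + 0.0 for t in order}
    return ICTable("universal", namespace, values)


def wang_svalues(
    graph: OntologyGraph,
    term: str,
    w_is_a: float = DEFAULT_W_IS_A,
    w_part_of: float = DEFAULT_W_PART_OF,
) -> WangSValues:
    """S-value propagation from an anchor to its ancestors.

    S(anchor)=1 and S(a) = max over children c of a (within the anchor's
    ancestor graph) of w(c->a) * S(c).
    """
    for w in (w_is_a, w_part_of):
        if not 0.0 < w < 1.0:
            raise ParameterError(f"Wang edge weight {w} outside (0,1)")
    anchor = graph.resolve(term)
    inside = graph.ancestors(anchor, inclusive=True)
    weight = {"is_a": w_is_a, "part_of": w_part_of}
    s: dict[str, float] = {anchor: 1.0}
    # walk ancestors in children-before-parents order
    order = [t for t in reversed(graph._order) if t in inside]
    for t in order:
        if t == anchor:
            continue
        best = 0.0
        for c, rel in graph.children_index[t]:
            if c in s:
                best = max(best, weight[rel] * s[c])
        s[t] = best
    return WangSValues(anchor, s, sum(s.values()))


# -- TSV round trip -----------------------------------------------------------


def write_ic_table(table: ICTable, stream: TextIO) -> None:
    """3-column TSV: term_id, model, ic (12 significant digits)."""
    for t in sorted(table.values):
        stream.write(f"{t}\t{table.model}\t{table.values[t]:.12g}\n")


def read_ic_table(stream: TextIO | str, namespace: str) -> ICTable:
    lines = stream.splitlines() if isinstance(stream, str) else stream
    values: dict[str, float] = {}
    model = None
    for line in lines:
        line = line.strip()
        if not line:
            continue
        term, m, ic = line.split("\t")
        if model is None:
            model = m
        elif m != model:
            raise ParameterError(f"mixed IC models in table: {model} vs {m}")
        values[term] = float(ic)
    if model is None:
        raise ParameterError("empty IC table")
    return ICTable(model, namespace, values)
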