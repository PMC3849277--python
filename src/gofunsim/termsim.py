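"""Pairwise GO-term semantic similarity, all scores normalized to [0,1].

Approaches and the IC model they consume:

========================  ==============================================
resnik, lin, relevance,   annotation IC (corpus frequencies); resnik is
li, xgrasm[_resnik|_lin]  normalized by the corpus-wide IC maximum
zhang                     Zhang IC (Lin form)
universal                 GO-universal IC
wang                      none (per-anchor S-values)
========================  ==============================================

``xgrasm`` is an alias for the Lin-flavored variant; both flavors replace
the MICA IC with the mean IC over all informative common ancestors.
A term's similarity to itself is 1 for every approach.
"""

from __future__ import annotations

import math

from .errors import ParameterError, TermUnusedError
from .ic import DEFAULT_W_IS_A, DEFAULT_W_PART_OF, ICTable, wang_svalues
from .ontology import OntologyGraph

#: approach name -> required ICTable.model (None = topology-only, no table)
APPROACH_IC_MODEL: dict[str, str | None] = {
    "resnik": "annotation",
    "lin": "annotation",
    "relevance": "annotation",
    "li": "annotation",
    "xgrasm": "annotation",
    "xgrasm_lin": "annotation",
    "xgrasm_resnik": "annotation",
    "zhang": "zhang",
    "universal": "universal",
    "wang": None,
}

APPROACHES = tuple(APPROACH_IC_MODEL)


def _clamp(x: float) -> float:
    return min(1.0, max(0.0, x))


def mica(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str
) -> tuple[str, float]:
    """Most informative common ancestor; ties broken by smallest term id."""
    candidates = graph.common_ancestors(t1, t2)
    best_term = None
    best_ic = -1.0
    for t in sorted(candidates):
        v = ic.values.get(t)
        if v is not None and v > best_ic:
            best_term, best_ic = t, v
    if best_term is None:
        raise TermUnusedError(
            f"no common ancestor of {t1} and {t2} has a defined {ic.model} IC"
        )
    return best_term, best_ic


def informative_common_ancestors(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str
) -> list[str]:
    """Common ancestors with strictly positive IC (the XGraSM ICA set)."""
    return sorted(
        t for t in graph.common_ancestors(t1, t2) if ic.values.get(t, 0.0) > 0.0
    )


def _check_model(approach: str, ic: ICTable | None) -> None:
    need = APPROACH_IC_MODEL[approach]
    if need is None:
        return
    if ic is None:
        raise ParameterError(f"approach {approach!r} requires a {need} IC table")
    if ic.model != need:
        raise ParameterError(
            f"approach {approach!r} requires {need} IC, got {ic.model}"
        )


def term_sim(
    approach: str,
    graph: OntologyGraph,
    ic: ICTable | None,
    t1: str,
    t2: str,
    w_is_a: float = DEFAULT_W_IS_A,
    w_part_of: float = DEFAULT_W_PART_OF,
) -> float:
    """Semantic similarity of two same-namespace terms under one approach."""
    if approach not in APPROACH_IC_MODEL:
        raise ParameterError(f"unknown term similarity approach: {approach!r}")
    _check_model(approach, ic)
    a, b = graph.resolve(t1), graph.resolve(t2)
    if graph.namespace_of(a) != graph.namespace_of(b):
        # delegate to common_ancestors for the canonical error message
        graph.common_ancestors(a, b)
    if a == b:
        if ic is not None and a not in ic:
            raise TermUnusedError(f"term {a} unused in corpus")
        return 1.0

    if approach == "wang":
        sa = wang_svalues(graph, a, w_is_a, w_part_of)
        sb = wang_svalues(graph, b, w_is_a, w_part_of)
        common = set(sa.svalues) & set(sb.svalues)
        if not common:
            return 0.0
        num = sum(sa.svalues[t] + sb.svalues[t] for t in common)
        return _clamp(num / (sa.sv_total + sb.sv_total))

    assert ic is not None
    ic1, ic2 = ic[a], ic[b]

    if approach in ("xgrasm", "xgrasm_lin", "xgrasm_resnik"):
        ica = informative_common_ancestors(graph, ic, a, b)
        if not ica:
            return 0.0
        mean_ic = sum(ic.values[t] for t in ica) / len(ica)
        if approach == "xgrasm_resnik":
            return _clamp(mean_ic / ic.ic_max) if ic.ic_max > 0 else 0.0
        denom = ic1 + ic2
        return _clamp(2.0 * mean_ic / denom) if denom > 0 else 0.0

    _mica_term, mica_ic = mica(graph, ic, a, b)

    if approach == "resnik":
        return _clamp(mica_ic / ic.ic_max) if ic.ic_max > 0 else 0.0
    if approach == "universal":
        denom = max(ic1, ic2)
        return _clamp(mica_ic / denom) if denom > 0 else 0.0

    # Lin form and its corrections
    denom = ic1 + ic2
    lin = 2.0 * mica_ic / denom if denom > 0 else 0.0
    if approach in ("lin", "zhang"):
        return _clamp(lin)
    if approach == "relevance":
        return _clamp(lin * (1.0 - math.exp(-mica_ic)))
    if approach == "li":
        return _clamp(lin * (1.0 - 1.0 / (1.0 + mica_ic)))
    raise AssertionError(approach)
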