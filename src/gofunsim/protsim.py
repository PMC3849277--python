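"""Protein functional similarity: combiners, direct-IC measures and the
registry of the 27 canonical measure configurations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotations import AnnotationCorpus
from .errors import (
    MissingAnnotationError,
    ParameterError,
    UndefinedSimilarityError,
)
from .ic import ICTable
from .ontology import OntologyGraph
from .termsim import APPROACH_IC_MODEL, term_sim

COMBINERS = ("avg", "max", "bma", "abm")
DIRECT_MEASURES = ("simgic", "simdic", "simuic", "simui")

#: topology approaches bound to the combiner their authors suggest
TOPOLOGY_BINDINGS = {"universal": "bma", "wang": "abm", "zhang": "abm"}

_REGISTRY_LABELS = {
    "simgic": "SimGIC",
    "simdic": "SimDIC",
    "simuic": "SimUIC",
    "simui": "SimUI",
    "xgrasm": "XGraSM",
    "resnik": "Resnik",
    "lin": "Lin",
    "li": "Li",
    "relevance": "Relevance",
    "zhang": "Zhang",
    "wang": "Wang",
    "universal": "GO-universal",
}


@dataclass(frozen=True)
class MeasureConfig:
    """One named functional-similarity configuration."""

    family: str  # "annotation" | "topology"
    approach: str  # term approach or direct-measure name
    combiner: str | None  # None iff approach is a direct measure
    label: str

    def __post_init__(self) -> None:
        if self.family not in ("annotation", "topology"):
            raise ParameterError(f"unknown family {self.family!r}")
        if self.approach in DIRECT_MEASURES:
            if self.combiner is not None:
                raise ParameterError(
                    f"direct measure {self.approach!r} takes no combiner"
                )
        else:
            if self.approach not in APPROACH_IC_MODEL:
                raise ParameterError(f"unknown approach {self.approach!r}")
            if self.combiner not in COMBINERS:
                raise ParameterError(
                    f"approach {self.approach!r} needs a combiner from "
                    f"{COMBINERS}, got {self.combiner!r}"
                )


def make_measure(
    family: str, approach: str, combiner: str | None = None
) -> MeasureConfig:
    if approach in DIRECT_MEASURES:
        label = _REGISTRY_LABELS[approach]
        return MeasureConfig(family, approach, None, label)
    if combiner is None:
        combiner = TOPOLOGY_BINDINGS.get(approach, "bma")
    label = f"{_REGISTRY_LABELS.get(approach, approach)}-{combiner.upper()}"
    return MeasureConfig(family, approach, combiner, label)


def registry() -> list[MeasureConfig]:
    """The 27 canonical configurations of the measure grid.

    {SimGIC, SimDIC, SimUIC} on annotation IC; {XGraSM, Resnik, Lin, Li,
    Relevance} crossed with {BMA, ABM, Avg, Max}; SimUI; Zhang+ABM,
    Wang+ABM, GO-universal+BMA.
    """
    out = [make_measure("annotation", m) for m in ("simgic", "simdic", "simuic")]
    for approach in ("xgrasm", "resnik", "lin", "li", "relevance"):
        for combiner in ("bma", "abm", "avg", "max"):
            out.append(make_measure("annotation", approach, combiner))
    out.append(make_measure("topology", "simui"))
    out.append(make_measure("topology", "zhang", "abm"))
    out.append(make_measure("topology", "wang", "abm"))
    out.append(make_measure("topology", "universal", "bma"))
    return out


def combine(combiner: str, sim_matrix: Sequence[Sequence[float]]) -> float:
    """Collapse an n x m term-similarity matrix into one protein score.

    avg: mean of all entries.  max: maximum entry.
    abm: (sum of row maxima + sum of column maxima) / (n + m).
    bma: mean of (mean of row maxima, mean of column maxima).
    """
    m = np.asarray(sim_matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise UndefinedSimilarityError("empty term-similarity matrix")
    if combiner == "avg":
        return float(m.mean())
    if combiner == "max":
        return float(m.max())
    row_max = m.max(axis=1)
    col_max = m.max(axis=0)
    if combiner == "abm":
        return float((row_max.sum() + col_max.sum()) / (m.shape[0] + m.shape[1]))
    if combiner == "bma":
        return float(0.5 * (row_max.mean() + col_max.mean()))
    raise ParameterError(f"unknown combiner {combiner!r}")


def direct_sim(
    measure: str,
    ic: ICTable | None,
    closure_p: frozenset[str] | set[str],
    closure_q: frozenset[str] | set[str],
) -> float:
    """Set-overlap measures over annotation closures.

    simgic: IC-weighted Jaccard; simdic: IC-weighted Dice;
    simuic: IC-weighted universal index; simui: plain Jaccard (no IC).
    """
    if not closure_p or not closure_q:
        raise UndefinedSimilarityError("empty annotation closure")
    inter = closure_p & closure_q
    if measure == "simui":
        return len(inter) / len(closure_p | closure_q)
    if ic is None:
        raise ParameterError(f"measure {measure!r} requires an IC table")
    s_int = sum(ic[t] for t in inter)
    s_p = sum(ic[t] for t in closure_p)
    s_q = sum(ic[t] for t in closure_q)
    if measure == "simgic":
        s_union = sum(ic[t] for t in closure_p | closure_q)
        if s_union == 0.0:
            raise UndefinedSimilarityError("zero total IC over the union")
        return s_int / s_union
    if measure == "simdic":
        if s_p + s_q == 0.0:
            raise UndefinedSimilarityError("zero total IC over both closures")
        return 2.0 * s_int / (s_p + s_q)
    if measure == "simuic":
        denom = max(s_p, s_q)
        if denom == 0.0:
            raise UndefinedSimilarityError("zero total IC over both closures")
        return s_int / denom
    raise ParameterError(f"unknown direct measure {measure!r}")


@dataclass(frozen=True)
class ProteinSimilarity:
    p: str
    q: str
    measure: MeasureConfig
    score: float
    n_terms: tuple[int, int]


def protein_sim(
    measure: MeasureConfig,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    ic: ICTable | None,
    p: str,
    q: str,
    namespace: str,
) -> ProteinSimilarity:
    """Score one protein pair under one measure configuration."""
    pid, qid = corpus.resolve(p), corpus.resolve(q)
    tp = sorted(corpus.direct(pid, namespace))
    tq = sorted(corpus.direct(qid, namespace))
    if not tp or not tq:
        missing = pid if not tp else qid
        raise MissingAnnotationError(
            f"protein {missing} has no annotation in {namespace}"
        )
    if pid == qid:
        return ProteinSimilarity(pid, qid, measure, 1.0, (len(tp), len(tq)))
    if measure.approach in DIRECT_MEASURES:
        score = direct_sim(
            measure.approach,
            None if measure.approach == "simui" else ic,
            corpus.closure(pid, namespace),
            corpus.closure(qid, namespace),
        )
    else:
        matrix = [
            [term_sim(measure.approach, graph, ic, t, s) for s in tq] for t in tp
        ]
        score = combine(measure.combiner, matrix)
    return ProteinSimilarity(pid, qid, measure, min(1.0, max(0.0, score)),
                             (len(tp), len(tq)))
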