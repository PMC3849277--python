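"""Fuzzy agreement-level term statistics: fuzzy scores and frequencies,
hypergeometric / binomial upper-tail p-values with Bonferroni correction,
and the two applications built on them — gene retrieval by GO term
(``gospfit``) and term enrichment (``gossfeat``)."""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom, hypergeom

from .annotations import AnnotationCorpus
from .errors import (
    InputLimitError,
    MissingAnnotationError,
    NamespaceMismatchError,
    ParameterError,
)
from .ic import ICTable
from .ontology import OntologyGraph
from .termsim import term_sim

#: preset agreement levels: moderate (default), high, perfect
AGREEMENT_PRESETS = {"moderate": 0.3, "high": 0.7, "perfect": 1.0}

DEFAULT_AGREEMENT = 0.3

RETRIEVAL_TERM_LIMIT = 20
ENRICHMENT_PROTEIN_LIMIT = 2000


def agreement_level(c: float | str) -> float:
    """Validate an agreement level; accepts preset names."""
    if isinstance(c, str):
        try:
            c = AGREEMENT_PRESETS[c]
        except KeyError:
            raise ParameterError(
                f"unknown agreement preset {c!r}; "
                f"use one of {sorted(AGREEMENT_PRESETS)}"
            ) from None
    if not 0.0 < c <= 1.0:
        raise ParameterError(f"agreement level {c} outside (0, 1]")
    return float(c)


def fuzzy_score(
    approach: str,
    graph: OntologyGraph,
    ic: ICTable | None,
    term: str,
    protein: str,
    corpus: AnnotationCorpus,
    namespace: str,
) -> float:
    """A_g(t): max term similarity of t to the protein's direct term set."""
    direct = corpus.direct(protein, namespace)
    if not direct:
        raise MissingAnnotationError(
            f"protein {protein} has no annotation in {namespace}"
        )
    return max(term_sim(approach, graph, ic, term, s) for s in direct)


def fuzzy_frequency(
    approach: str,
    graph: OntologyGraph,
    ic: ICTable | None,
    term: str,
    proteins,
    corpus: AnnotationCorpus,
    namespace: str,
    c: float,
) -> int:
    """ff(t): number of proteins with A_g(t) >= c."""
    c = agreement_level(c)
    return sum(
        1
        for g in proteins
        if fuzzy_score(approach, graph, ic, term, g, corpus, namespace) >= c
    )


# -- tail probabilities -------------------------------------------------------


def hypergeom_pvalue(ell: int, n: int, m: int, N: int) -> float:
    """P(X >= ell) drawing n from N with m marked (upper hypergeometric tail)."""
    if not (0 <= ell <= n <= N and 0 <= m <= N):
        raise ParameterError(
            f"inconsistent hypergeometric counts: ell={ell}, n={n}, m={m}, N={N}"
        )
    if ell == 0:
        return 1.0
    return float(hypergeom.sf(ell - 1, N, m, n))


def binomial_pvalue(ell: int, n: int, p: float) -> float:
    """P(X >= ell) for X ~ Binomial(n, p)."""
    if not (0 <= ell <= n) or not (0.0 <= p <= 1.0):
        raise ParameterError(
            f"inconsistent binomial parameters: ell={ell}, n={n}, p={p}"
        )
    if ell == 0:
        return 1.0
    return float(binom.sf(ell - 1, n, p))


def bonferroni(p_values, k: int) -> list[float]:
    """min(1, p * k) for each p; k = number of tests performed."""
    p_values = list(p_values)
    if k <= 0 or k < len(p_values):
        raise ParameterError(f"invalid Bonferroni test count k={k}")
    return [min(1.0, p * k) for p in p_values]


# -- applications -------------------------------------------------------------


@dataclass(frozen=True)
class RetrievalRow:
    """One query term of a gene-retrieval run."""

    term: str
    name: str
    level: int
    detected: tuple[tuple[str, float], ...]  # (protein, A_g) ranked descending
    p_value: float
    corrected_p: float


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    name: str
    level: int
    reference_ff: int
    target_ff: int
    p_value: float
    corrected_p: float


def gospfit(
    query_terms,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    ic: ICTable | None,
    approach: str,
    c: float = DEFAULT_AGREEMENT,
    reference: AnnotationCorpus | None = None,
    limit: int = RETRIEVAL_TERM_LIMIT,
    force: bool = False,
) -> list[RetrievalRow]:
    """Retrieve proteins fuzzily annotated with each query term.

    For each term t: detected = {g : A_g(t) >= c}; a binomial upper tail
    with n = number of annotated proteins in the target corpus, ell =
    |detected| and success probability p = relative fuzzy frequency of t in
    the reference corpus (the target corpus itself by default).  Bonferroni
    k = number of query terms.
    """
    terms = [graph.resolve(t) for t in query_terms]
    if not terms:
        raise ParameterError("empty query term list")
    if len(terms) > limit and not force:
        raise InputLimitError(
            f"{len(terms)} query terms exceed the limit of {limit}"
        )
    c = agreement_level(c)
    namespaces = {graph.namespace_of(t) for t in terms}
    if len(namespaces) > 1:
        raise NamespaceMismatchError(
            f"query terms span several namespaces: {sorted(namespaces)}"
        )
    ns = namespaces.pop()
    reference = reference if reference is not None else corpus
    proteins = corpus.proteins(ns)
    n = len(proteins)
    ref_proteins = reference.proteins(ns)
    n_ref = len(ref_proteins)
    if n == 0 or n_ref == 0:
        raise ParameterError(f"no annotated proteins in namespace {ns}")

    rows: list[RetrievalRow] = []
    for t in terms:
        scores = {
            g: fuzzy_score(approach, graph, ic, t, g, corpus, ns)
            for g in proteins
        }
        detected = sorted(
            ((g, s) for g, s in scores.items() if s >= c),
            key=lambda gs: (-gs[1], gs[0]),
        )
        if reference is corpus:
            ff_ref = len(detected)
        else:
            ff_ref = fuzzy_frequency(
                approach, graph, ic, t, ref_proteins, reference, ns, c
            )
        p_success = ff_ref / n_ref
        p_value = binomial_pvalue(len(detected), n, p_success)
        rows.append(
            RetrievalRow(
                t, graph.name_of(t), graph.level(t), tuple(detected), p_value, 0.0
            )
        )
    corrected = bonferroni([r.p_value for r in rows], len(terms))
    return [
        RetrievalRow(r.term, r.name, r.level, r.detected, r.p_value, cp)
        for r, cp in zip(rows, corrected)
    ]


def gossfeat(
    target,
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    ic: ICTable | None,
    approach: str,
    c: float = DEFAULT_AGREEMENT,
    namespace: str | None = None,
    candidate_terms=None,
    limit: int = ENRICHMENT_PROTEIN_LIMIT,
    force: bool = False,
    strict: bool = True,
) -> list[EnrichmentRow]:
    """Fuzzy term-enrichment of a target protein set against the corpus.

    Every candidate term with target fuzzy frequency >= 1 is tested with the
    hypergeometric upper tail (N = reference size, m = reference fuzzy
    frequency, n = target size, ell = target fuzzy frequency); Bonferroni
    k = number of terms actually tested.  Candidate terms default to all
    corpus-used terms of the namespace.  Rows sorted by corrected then raw
    p-value.
    """
    if not target:
        raise ParameterError("empty target protein list")
    c = agreement_level(c)
    resolved: list[str] = []
    for ident in target:
        try:
            resolved.append(corpus.resolve(ident))
        except Exception:
            if strict:
                raise
    if len(resolved) > limit and not force:
        raise InputLimitError(
            f"{len(resolved)} target proteins exceed the limit of {limit}"
        )
    if namespace is None:
        namespaces = corpus.namespaces()
        if len(namespaces) != 1:
            raise ParameterError(
                "namespace must be given for a multi-namespace corpus"
            )
        namespace = namespaces[0]
    reference_proteins = corpus.proteins(namespace)
    N = len(reference_proteins)
    target_set = sorted(set(resolved))
    unannotated = [g for g in target_set if not corpus.direct(g, namespace)]
    if unannotated:
        raise ParameterError(
            f"target proteins without {namespace} annotation: {unannotated}"
        )
    n = len(target_set)
    if candidate_terms is None:
        candidate_terms = sorted(corpus.usage(namespace).counts)
    else:
        candidate_terms = sorted(graph.resolve(t) for t in candidate_terms)

    tested: list[tuple[str, int, int, float]] = []
    for t in candidate_terms:
        scores = {
            g: fuzzy_score(approach, graph, ic, t, g, corpus, namespace)
            for g in reference_proteins
        }
        ell = sum(1 for g in target_set if scores[g] >= c)
        if ell == 0:
            continue
        m = sum(1 for s in scores.values() if s >= c)
        tested.append((t, m, ell, hypergeom_pvalue(ell, n, m, N)))

    k = len(tested)
    rows = [
        EnrichmentRow(
            t,
            graph.name_of(t),
            graph.level(t),
            m,
            ell,
            p,
            min(1.0, p * k),
        )
        for t, m, ell, p in tested
    ]
    rows.sort(key=lambda r: (r.corrected_p, r.p_value, r.term))
    return rows
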