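import pytest

from gofunsim import annotation_ic, parse_gaf, parse_obo, universal_ic, zhang_ic
from gofunsim.simulate import TOY_TERMS, RandomDagSpec, random_instance, toy

NS = "biological_process"

#: shorthand Gk -> GO:000000k used by the hand-derived expectations
G = TOY_TERMS


@pytest.fixture(scope="session")
def fix():
    return toy()


@pytest.fixture(scope="session")
def graph(fix):
    return parse_obo(fix.obo_text)


@pytest.fixture(scope="session")
def corpus(fix, graph):
    return parse_gaf(fix.gaf_text, graph)


@pytest.fixture(scope="session")
def usage(corpus):
    return corpus.usage(NS)


@pytest.fixture(scope="session")
def ann_ic(usage):
    return annotation_ic(usage)


@pytest.fixture(scope="session")
def zh_ic(graph):
    return zhang_ic(graph, NS)


@pytest.fixture(scope="session")
def un_ic(graph):
    return universal_ic(graph, NS)


def make_random(seed, n_terms=15, n_proteins=6, annotations_per_protein=2,
                max_parents=3, part_of_fraction=0.2):
    """Parse a seeded random OBO/GAF instance into (graph, corpus)."""
    obo, gaf = random_instance(
        RandomDagSpec(
            n_terms=n_terms,
            max_parents=max_parents,
            part_of_fraction=part_of_fraction,
            n_proteins=n_proteins,
            annotations_per_protein=annotations_per_protein,
            seed=seed,
        )
    )
    g = parse_obo(obo)
    c = parse_gaf(gaf, g) if n_proteins else None
    return g, c


def brute_force_ancestors(graph):
    """Transitive closure of the parent relation by repeated edge expansion.

    Independent of OntologyGraph.ancestors: only the raw parent lists of the
    parsed records are used, iterated to a fixpoint.
    """
    parents = {t: {p for p, _ in rec.parents} for t, rec in graph.terms.items()}
    closure = {t: set(ps) for t, ps in parents.items()}
    changed = True
    while changed:
        changed = False
        for t in closure:
            extra = set()
            for a in closure[t]:
                extra |= parents[a]
            if not extra <= closure[t]:
                closure[t] |= extra
                changed = True
    return closure
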