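"""Deterministic toy fixtures and seeded random OBO/GAF generators.

Everything is emitted as real OBO/GAF text so the parsers are exercised on
every test run; nothing here requires a network or a GO release.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import ParameterError

_ASPECT = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}

#: toy term ids; Gk is shorthand for GO:000000k in tests and docs
TOY_TERMS = {f"G{i}": f"GO:{i:07d}" for i in range(1, 7)}


@dataclass(frozen=True)
class ToyFixture:
    obo_text: str
    gaf_text: str
    expected: dict


@dataclass(frozen=True)
class RandomDagSpec:
    n_terms: int
    max_parents: int = 3
    part_of_fraction: float = 0.2
    n_proteins: int = 0
    annotations_per_protein: int = 2
    seed: int = 0
    namespace: str = "biological_process"


def _obo_header() -> str:
    return "format-version: 1.2\nontology: go\n"


def _term_stanza(
    term_id: str,
    name: str,
    namespace: str,
    parents: list[tuple[str, str]],
    alt_ids: list[str] = (),
) -> str:
    lines = [
        "",
        "[Term]",
        f"id: {term_id}",
        f"name: {name}",
        f"namespace: {namespace}",
    ]
    for alt in alt_ids:
        lines.append(f"alt_id: {alt}")
    for pid, rel in parents:
        if rel == "is_a":
            lines.append(f"is_a: {pid}")
        else:
            lines.append(f"relationship: part_of {pid}")
    return "\n".join(lines) + "\n"


def _gaf_row(
    protein: str, symbol: str, term: str, namespace: str, evidence: str = "IEA",
    qualifier: str = "",
) -> str:
    cols = [
        "UniProtKB",  # DB
        protein,  # DB_Object_ID
        symbol,  # Symbol
        qualifier,  # Qualifier
        term,  # GO_ID
        "GO_REF:0000001",  # DB:Reference
        evidence,  # Evidence
        "",  # With/From
        _ASPECT[namespace],  # Aspect
        "",  # DB_Object_Name
        "",  # Synonym
        "protein",  # DB_Object_Type
        "taxon:1",  # Taxon
        "20130101",  # Date
        "GO_Central",  # Assigned_by
        "",  # Annotation_Extension
        "",  # Gene_Product_Form_ID
    ]
    return "\t".join(cols) + "\n"


def toy() -> ToyFixture:
    """The 6-term / 5-protein hand fixture used throughout the test suite.

    Terms G1..G6 (GO:0000001..GO:0000006) in biological_process with edges
    G2 is_a G1, G3 is_a G1, G4 is_a G2, G5 is_a G2, G5 part_of G3,
    G6 is_a G4.  Proteins P1:{G6}, P2:{G5}, P3:{G4}, P4:{G3}, P5:{G2,G5}.
    """
    g = TOY_TERMS
    ns = "biological_process"
    obo = _obo_header()
    obo += _term_stanza(g["G1"], "G1", ns, [])
    obo += _term_stanza(g["G2"], "G2", ns, [(g["G1"], "is_a")])
    obo += _term_stanza(g["G3"], "G3", ns, [(g["G1"], "is_a")])
    obo += _term_stanza(g["G4"], "G4", ns, [(g["G2"], "is_a")])
    obo += _term_stanza(
        g["G5"], "G5", ns, [(g["G2"], "is_a"), (g["G3"], "part_of")],
        alt_ids=["GO:0000055"],
    )
    obo += _term_stanza(g["G6"], "G6", ns, [(g["G4"], "is_a")])

    annotations = [
        ("P1", "katG", "G6"),
        ("P2", "gene2", "G5"),
        ("P3", "gene3", "G4"),
        ("P4", "gene4", "G3"),
        ("P5", "gene5", "G2"),
        ("P5", "gene5", "G5"),
    ]
    gaf = "!gaf-version: 2.1\n"
    for protein, symbol, short in annotations:
        gaf += _gaf_row(protein, symbol, g[short], ns)

    expected = {
        "levels": {"G1": 0, "G2": 1, "G3": 1, "G4": 2, "G5": 2, "G6": 3},
        "usage_counts": {"G1": 5, "G2": 4, "G3": 3, "G4": 2, "G5": 2, "G6": 1},
        "closures": {
            "P1": {"G1", "G2", "G4", "G6"},
            "P2": {"G1", "G2", "G3", "G5"},
            "P3": {"G1", "G2", "G4"},
            "P4": {"G1", "G3"},
            "P5": {"G1", "G2", "G3", "G5"},
        },
    }
    return ToyFixture(obo, gaf, expected)


def random_instance(spec: RandomDagSpec) -> tuple[str, str]:
    """Seeded random (obo_text, gaf_text) pair.

    Term i >= 2 attaches to 1..max_parents uniformly chosen earlier terms,
    so the construction is topologically ordered and acyclic by design.
    Proteins are annotated with uniformly chosen non-root terms.
    """
    if spec.n_terms < 2:
        raise ParameterError("need at least 2 terms")
    if spec.max_parents < 1:
        raise ParameterError("max_parents must be >= 1")
    if not 0.0 <= spec.part_of_fraction <= 1.0:
        raise ParameterError("part_of_fraction outside [0, 1]")
    if spec.n_proteins and spec.annotations_per_protein < 1:
        raise ParameterError("annotations_per_protein must be >= 1")
    rng = random.Random(spec.seed)
    ids = [f"GO:{i:07d}" for i in range(1, spec.n_terms + 1)]
    obo = _obo_header()
    obo += _term_stanza(ids[0], "term1", spec.namespace, [])
    for i in range(1, spec.n_terms):
        k = rng.randint(1, min(spec.max_parents, i))
        parent_idx = rng.sample(range(i), k)
        parents = [
            (
                ids[j],
                "part_of" if rng.random() < spec.part_of_fraction else "is_a",
            )
            for j in sorted(parent_idx)
        ]
        obo += _term_stanza(ids[i], f"term{i + 1}", spec.namespace, parents)

    gaf = "!gaf-version: 2.1\n"
    non_root = ids[1:]
    for j in range(spec.n_proteins):
        protein = f"P{j + 1:06d}"
        n_ann = min(spec.annotations_per_protein, len(non_root))
        for t in sorted(rng.sample(non_root, n_ann)):
            gaf += _gaf_row(protein, f"gene{j + 1}", t, spec.namespace)
    return obo, gaf
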