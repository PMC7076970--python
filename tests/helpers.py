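"""In-memory random DAG/annotation generators and naive oracles for tests."""

from __future__ import annotations

import numpy as np

from enrichkit.annotations import GeneAnnotation, GeneInfoRecord
from enrichkit.ontology import Ontology, OntologyTerm


def random_ontology(rng: np.random.Generator, n_terms: int) -> Ontology:
    """A random single-root DAG: term i may have parents among terms < i."""
    terms = {}
    ids = [f"T:{i:03d}" for i in range(n_terms)]
    for i, tid in enumerate(ids):
        term = OntologyTerm(term_id=tid, name=f"term {i}", namespace="biological_process")
        if i > 0:
            n_parents = int(rng.integers(1, min(3, i) + 1))
            for j in rng.choice(i, size=n_parents, replace=False):
                parent = ids[int(j)]
                if rng.random() < 0.2:
                    term.part_of_parents.add(parent)
                else:
                    term.is_a_parents.add(parent)
        terms[tid] = term
    return Ontology(terms)


def random_annotations(
    rng: np.random.Generator, ontology: Ontology, genes: list[str], n_annotations: int
) -> list[GeneAnnotation]:
    ids = sorted(ontology.terms)
    return [
        GeneAnnotation(
            gene_key=genes[int(rng.integers(len(genes)))],
            term_id=ids[int(rng.integers(len(ids)))],
        )
        for _ in range(n_annotations)
    ]


def gene_info_for(genes: list[str], taxon: int = 9001) -> list[GeneInfoRecord]:
    return [
        GeneInfoRecord(taxon=taxon, gene_id=1000 + i, symbol=sym)
        for i, sym in enumerate(genes)
    ]


def naive_ancestors(ontology: Ontology, term_id: str, relations=("is_a", "part_of")) -> set[str]:
    """Fresh recursive DFS without memoization — the propagation oracle."""
    out: set[str] = set()
    for parent in ontology.terms[term_id].parents(set(relations)):
        out.add(parent)
        out |= naive_ancestors(ontology, parent, relations)
    return out


def naive_go_construction(
    ontology: Ontology, annotations, relations=("is_a", "part_of")
) -> dict[str, set[str]]:
    """Per-gene brute-force propagation: term plus naive-DFS ancestors."""
    term_genes: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.excluded:
            continue
        terms = {ann.term_id} | naive_ancestors(ontology, ann.term_id, relations)
        for tid in terms:
            term_genes.setdefault(tid, set()).add(ann.gene_key)
    return term_genes


def stepup_bh(p: list[float]) -> list[float]:
    """Independent Benjamini–Hochberg step-up, written longhand."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(1.0, p[i] * m / rank)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def stepup_by(p: list[float]) -> list[float]:
    m = len(p)
    c = sum(1.0 / i for i in range(1, m + 1))
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(1.0, p[i] * c * m / rank)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted
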