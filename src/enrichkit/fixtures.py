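"""Deterministic synthetic annotation universe.

Real library builds consume downloads (OBO releases, GOA GAF files, NCBI
tables, pathway exports).  This module writes a miniature, fully seeded
stand-in for all of them: a random DAG ontology with a single root, a gene
universe with symbols and synonyms, GO annotations rendered consistently as
both GAF (symbol-keyed) and gene2go (numeric-id-keyed) files, flat
pathway/disease tables, a query gene list, a background list, a build
manifest wired to the generated files, and a machine-readable truth file.

Ground truth is *planted*: a chosen leaf term (and a mirrored pathway)
receives a block of member genes, and the generated query draws a fraction
``effect`` of its genes from that block, the rest uniformly from the
universe.  With the defaults (200 genes, 30 terms, query of 25 at effect
0.5) the planted term carries a strong but not degenerate signal, the scale
at which end-to-end recovery is checked.  Everything is a pure function of
the seed: identical specs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError

FIXTURE_TAXON = 9001
_OTHER_TAXON = 9002
_EVIDENCE_CODES = ["IEA", "EXP", "IDA", "ISS"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic mini-universe."""

    seed: int
    n_genes: int = 200
    n_terms: int = 30
    dag_depth: int = 4
    planted_terms: int = 1
    effect: float = 0.5
    query_size: int = 25

    def __post_init__(self):
        if self.n_genes < 10:
            raise ValidationError("n_genes must be >= 10")
        if self.n_terms < self.dag_depth + self.planted_terms:
            raise ValidationError("n_terms too small for dag_depth and planted_terms")
        if self.dag_depth < 2:
            raise ValidationError("dag_depth must be >= 2")
        if not 0 <= self.planted_terms <= self.n_terms:
            raise ValidationError("require 0 <= planted_terms <= n_terms")
        if not 0 < self.effect <= 1:
            raise ValidationError("require 0 < effect <= 1")
        if not 0 < self.query_size <= self.n_genes:
            raise ValidationError("require 0 < query_size <= n_genes")


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def generate_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Write the full fixture set into ``out_dir``; return paths and truth."""
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    symbols = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    gene_ids = {sym: 1000 + i for i, sym in enumerate(symbols, start=1)}

    # ---- ontology: single-root DAG over `dag_depth` levels -----------------
    root = _term_id(1)
    term_ids = [_term_id(i) for i in range(1, spec.n_terms + 1)]
    levels: dict[str, int] = {root: 0}
    n_inner = spec.n_terms - 1 - spec.planted_terms
    inner = term_ids[1 : 1 + n_inner]
    planted = term_ids[1 + n_inner :]
    for j, tid in enumerate(inner):
        # spread inner terms over levels 1..dag_depth-1, keeping each level populated
        levels[tid] = 1 + j % max(1, spec.dag_depth - 1)

    parents: dict[str, list[tuple[str, str]]] = {root: []}
    for tid in inner:
        shallower = [t for t in [root] + inner if levels[t] < levels[tid]]
        n_parents = 1 if len(shallower) == 1 else int(rng.integers(1, 3))
        chosen = rng.choice(shallower, size=min(n_parents, len(shallower)), replace=False)
        rels = []
        for parent in sorted(chosen.tolist()):
            relation = "part_of" if rng.random() < 0.1 else "is_a"
            rels.append((relation, parent))
        parents[tid] = rels
    # planted terms are leaves directly under the root: their only ancestor is
    # the (untestably broad) root, so the planted signal is not absorbed by
    # intermediate ancestors
    for tid in planted:
        levels[tid] = 1
        parents[tid] = [("is_a", root)]

    obsolete_id = _term_id(spec.n_terms + 1)
    alt_of_root = _term_id(999999)
    obo_lines = ["format-version: 1.2", ""]
    for tid in term_ids:
        obo_lines.append("[Term]")
        obo_lines.append(f"id: {tid}")
        obo_lines.append(f"name: synthetic process {tid[3:].lstrip('0') or '0'}")
        obo_lines.append("namespace: biological_process")
        if tid == root:
            obo_lines.append(f"alt_id: {alt_of_root}")
        for relation, parent in parents[tid]:
            if relation == "is_a":
                obo_lines.append(f"is_a: {parent}")
            else:
                obo_lines.append(f"relationship: part_of {parent}")
        obo_lines.append("")
    obo_lines += [
        "[Term]",
        f"id: {obsolete_id}",
        "name: retired synthetic process",
        "namespace: biological_process",
        "is_obsolete: true",
        "",
    ]

    # ---- GO annotation truth ----------------------------------------------
    # background annotations avoid the planted terms so their membership (and
    # hence the planted effect size) is exactly the planted block
    annotatable = [t for t in term_ids if t != root and t not in set(planted)]
    truth_pairs: set[tuple[str, str]] = set()  # (symbol, term)
    for sym in symbols:
        n_direct = int(rng.integers(1, 4))
        for tid in rng.choice(annotatable, size=n_direct, replace=False):
            truth_pairs.add((sym, str(tid)))
    planted_size = min(max(30, spec.query_size), spec.n_genes)
    planted_gene_sets: dict[str, list[str]] = {}
    for tid in planted:
        members = rng.choice(symbols, size=planted_size, replace=False)
        members = sorted(members.tolist())
        planted_gene_sets[tid] = members
        for sym in members:
            truth_pairs.add((sym, tid))

    pair_list = sorted(truth_pairs)
    evidence = {
        pair: _EVIDENCE_CODES[int(rng.integers(0, len(_EVIDENCE_CODES)))]
        for pair in pair_list
    }
    # a few NOT-qualified lines and release-drift references, beyond the truth
    not_pairs = [
        (symbols[int(i)], str(rng.choice(annotatable)))
        for i in rng.choice(len(symbols), size=3, replace=False)
    ]

    def gaf_line(sym: str, tid: str, qualifier: str, ev: str) -> str:
        return "\t".join([
            "EK", sym, sym, qualifier, tid, "EK:ref", ev, "", "P",
            "", "", "gene", f"taxon:{FIXTURE_TAXON}", "20200101", "EK",
        ])

    gaf_lines = ["!gaf-version: 2.1", "! synthetic annotation fixture"]
    for sym, tid in pair_list:
        gaf_lines.append(gaf_line(sym, tid, "", evidence[(sym, tid)]))
    for sym, tid in not_pairs:
        gaf_lines.append(gaf_line(sym, tid, "NOT|involved_in", "IEA"))
    gaf_lines.append(gaf_line(symbols[0], alt_of_root, "", "IEA"))  # alt id use
    gaf_lines.append(gaf_line(symbols[1], obsolete_id, "", "IEA"))  # obsolete ref

    g2g_lines = ["#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier"]
    for sym, tid in pair_list:
        g2g_lines.append(
            f"{FIXTURE_TAXON}\t{gene_ids[sym]}\t{tid}\t{evidence[(sym, tid)]}\t-"
        )
    for sym, tid in not_pairs:
        g2g_lines.append(f"{FIXTURE_TAXON}\t{gene_ids[sym]}\t{tid}\tIEA\tNOT")
    g2g_lines.append(f"{FIXTURE_TAXON}\t{gene_ids[symbols[0]]}\t{alt_of_root}\tIEA\t-")
    g2g_lines.append(f"{FIXTURE_TAXON}\t{gene_ids[symbols[1]]}\t{obsolete_id}\tIEA\t-")
    g2g_lines.append(f"{_OTHER_TAXON}\t99901\t{root}\tIEA\t-")  # other-taxon row

    gi_lines = ["#tax_id\tGeneID\tSymbol\tLocusTag\tSynonyms"]
    for i, sym in enumerate(symbols):
        syn = f"{sym}alt" if i % 5 == 0 else "-"
        gi_lines.append(f"{FIXTURE_TAXON}\t{gene_ids[sym]}\t{sym}\t-\t{syn}")
    for j in range(3):
        gi_lines.append(f"{_OTHER_TAXON}\t{99901 + j}\tX{j + 1}\t-\t-")

    # ---- flat pathway / disease tables ------------------------------------
    def flat_table(prefix: str, label: str, n_sets: int, planted_set: list[str] | None):
        lines = []
        for i in range(1, n_sets + 1):
            tid = f"{prefix}:{i:04d}"
            name = f"synthetic {label} {i}"
            if i == 1 and planted_set is not None:
                members = planted_set
            else:
                size = int(rng.integers(10, 26))
                members = sorted(rng.choice(symbols, size=size, replace=False).tolist())
            for sym in members:
                lines.append(f"{tid}\t{name}\t{sym}")
        return lines

    planted_block = planted_gene_sets[planted[0]] if planted else None
    kegg_lines = flat_table("PW", "pathway", 10, planted_block)
    reactome_lines = flat_table("RX", "reaction pathway", 8, None)
    do_text_lines = flat_table("DIS", "disease", 6, None)
    do_know_lines = flat_table("DIS", "disease", 4, None)
    disgenet_lines = flat_table("DG", "gene-disease set", 6, None)

    # ---- query / background -----------------------------------------------
    n_from_planted = int(round(spec.effect * spec.query_size))
    query: list[str] = []
    for tid in planted:
        take = min(n_from_planted, spec.query_size - len(query))
        picked = rng.choice(planted_gene_sets[tid], size=take, replace=False)
        query.extend(s for s in picked.tolist() if s not in query)
    remaining = [s for s in symbols if s not in set(query)]
    filler = rng.choice(remaining, size=spec.query_size - len(query), replace=False)
    query.extend(filler.tolist())
    query = [query[int(i)] for i in rng.permutation(len(query))]

    truth = {
        "taxon": FIXTURE_TAXON,
        "planted_go_terms": list(planted),
        "planted_pathways": ["PW:0001"] if planted else [],
        "planted_term_size": planted_size,
        "query": query,
        "spec": asdict(spec),
    }

    files = {
        "obo": ("fixture.obo", "\n".join(obo_lines) + "\n"),
        "gaf": ("fixture.gaf", "\n".join(gaf_lines) + "\n"),
        "gene2go": ("gene2go.tsv", "\n".join(g2g_lines) + "\n"),
        "gene_info": ("gene_info.tsv", "\n".join(gi_lines) + "\n"),
        "kegg": ("kegg.tsv", "\n".join(kegg_lines) + "\n"),
        "reactome": ("reactome.tsv", "\n".join(reactome_lines) + "\n"),
        "do_textmining": ("do.textmining.tsv", "\n".join(do_text_lines) + "\n"),
        "do_knowledge": ("do.knowledge.tsv", "\n".join(do_know_lines) + "\n"),
        "disgenet": ("disgenet.tsv", "\n".join(disgenet_lines) + "\n"),
        "query": ("query.txt", "\n".join(query) + "\n"),
        "background": ("background.txt", "\n".join(symbols) + "\n"),
        "truth": ("truth.json", json.dumps(truth, indent=2, sort_keys=True) + "\n"),
    }
    manifest = "\n".join([
        "[species]",
        f"taxon = {FIXTURE_TAXON}",
        "gene_info = gene_info.tsv",
        "",
        "[go]",
        "obo = fixture.obo",
        "gaf = fixture.gaf",
        "",
        "[kegg]",
        "table = kegg.tsv",
        "",
        "[reactome]",
        "table = reactome.tsv",
        "",
        "[do]",
        "channel.textmining = do.textmining.tsv",
        "channel.knowledge = do.knowledge.tsv",
        "",
        "[disgenet]",
        "table = disgenet.tsv",
    ]) + "\n"
    files["manifest"] = ("species_db.ini", manifest)

    paths: dict[str, Path] = {}
    for key, (name, content) in files.items():
        path = out_dir / name
        path.write_text(content, encoding="utf-8")
        paths[key] = path
    return {"paths": paths, "truth": truth}
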