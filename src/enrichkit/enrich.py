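"""Over-representation analysis of a gene set against a species library.

The query is intersected with the background (the species universe by
default, or a user-supplied background list — e.g. the genes actually
expressed in the assayed tissue).  Term gene sets are likewise restricted to
the background before counting, so K and N are background-consistent: a
custom background changes not only N but every term's K, which is the
statistically coherent reading of a user-defined universe.

One exact upper-tail test is run per term whose background-restricted size
falls inside the size filters; q-values are computed across exactly that
tested family.  All tested rows are returned, sorted by (p, term_id), with a
significance flag at the q cutoff — the cutoff selects what is plotted, it
never truncates the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .library import SpeciesLibrary
from .stats import (
    ContingencyCounts,
    adjust_pvalues,
    fisher_exact_greater,
    fold_enrichment,
    hypergeom_upper_tail,
)

_METHODS = {
    "fisher": fisher_exact_greater,
    "hypergeom": hypergeom_upper_tail,
    "hypergeometric": hypergeom_upper_tail,
}

RESULT_COLUMNS = [
    "category", "term_id", "term_name", "k", "n", "K", "N",
    "fold_enrichment", "p_value", "q_value", "genes",
]


@dataclass(frozen=True)
class ResolvedBackground:
    """Outcome of background resolution."""

    genes: frozenset[str]
    n_unrecognized: int
    source: str  # "default" or "user"

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    category: str
    counts: ContingencyCounts
    fold: float
    p_value: float
    q_value: float
    genes: list[str]
    significant: bool


@dataclass
class EnrichmentTable:
    """All tested terms, ranked by p-value (ties broken by term id)."""

    rows: list[EnrichmentRow]
    background_size: int
    query_used: int
    query_dropped: list[str]
    settings: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def significant_rows(self) -> list[EnrichmentRow]:
        return [r for r in self.rows if r.significant]

    def to_frame(self):
        """The results as a pandas DataFrame with the output columns."""
        import pandas as pd

        records = [
            {
                "category": r.category,
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.counts.k,
                "n": r.counts.n,
                "K": r.counts.K,
                "N": r.counts.N,
                "fold_enrichment": r.fold,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "genes": ";".join(r.genes),
            }
            for r in self.rows
        ]
        return pd.DataFrame.from_records(records, columns=RESULT_COLUMNS)

    def write(self, path) -> None:
        """Write the results TSV with a ``#`` header echoing all settings."""
        lines = ["# enrichkit results v1"]
        for key in sorted(self.settings):
            lines.append(f"# {key}: {self.settings[key]}")
        lines.append(f"# background_size: {self.background_size}")
        lines.append(f"# query_used: {self.query_used}")
        lines.append(f"# query_dropped: {len(self.query_dropped)}")
        lines.append("\t".join(RESULT_COLUMNS))
        for r in self.rows:
            lines.append(
                "\t".join(
                    [
                        r.category,
                        r.term_id,
                        r.term_name,
                        str(r.counts.k),
                        str(r.counts.n),
                        str(r.counts.K),
                        str(r.counts.N),
                        format(r.fold, ".6g"),
                        format(r.p_value, ".6e"),
                        format(r.q_value, ".6e"),
                        ";".join(r.genes),
                    ]
                )
            )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def clean_gene_list(genes: Iterable[str]) -> tuple[list[str], int]:
    """Trim whitespace, drop blanks/comments, collapse duplicates.

    Matching is case-sensitive (gene symbols are case-meaningful across
    species).  Returns the unique list in first-seen order and the number of
    duplicates collapsed.
    """
    seen: set[str] = set()
    out: list[str] = []
    duplicates = 0
    for gene in genes:
        gene = gene.strip()
        if not gene or gene.startswith("#"):
            continue
        if gene in seen:
            duplicates += 1
            continue
        seen.add(gene)
        out.append(gene)
    return out, duplicates


def resolve_background(
    library: SpeciesLibrary, user_background: Sequence[str] | None = None
) -> ResolvedBackground:
    """Resolve the enrichment background.

    Default: the species universe from the NCBI gene table.  With a user
    list: its intersection with the universe, reporting how many supplied
    symbols were unrecognized.  A user background with zero recognized genes
    is an error.
    """
    if user_background is None:
        return ResolvedBackground(
            genes=frozenset(library.universe), n_unrecognized=0, source="default"
        )
    cleaned, _ = clean_gene_list(user_background)
    if not cleaned:
        raise ValidationError("user background is empty after de-duplication")
    recognized = frozenset(g for g in cleaned if g in library.universe)
    if not recognized:
        raise ValidationError(
            "no gene of the user background is in the species universe"
        )
    return ResolvedBackground(
        genes=recognized,
        n_unrecognized=len(cleaned) - len(recognized),
        source="user",
    )


def enrich(
    query: Sequence[str],
    library: SpeciesLibrary,
    background: ResolvedBackground | Iterable[str] | None = None,
    method: str = "fisher",
    adjust: str = "BH",
    min_term_size: int = 3,
    max_term_size: int = 5000,
    q_cutoff: float = 0.05,
) -> EnrichmentTable:
    """Test every eligible library term for over-representation in ``query``.

    Parameters mirror the command line: ``method`` is ``fisher`` or
    ``hypergeom`` (numerically identical one-sided), ``adjust`` one of BH
    (default; ``FDR`` is an alias), BY, bonferroni.  Term sizes are measured
    after background restriction; terms outside [min_term_size,
    max_term_size] are excluded from testing *and* from the correction
    family.  Raises if the query does not intersect the background or if no
    term is eligible.
    """
    if method not in _METHODS:
        raise ValidationError(
            f"unknown test method {method!r}; choose from fisher, hypergeom"
        )
    test = _METHODS[method]
    if min_term_size < 1 or max_term_size < min_term_size:
        raise ValidationError("require 1 <= min_term_size <= max_term_size")
    if not 0 < q_cutoff <= 1:
        raise ValidationError("q_cutoff must lie in (0, 1]")

    if background is None:
        background = resolve_background(library)
    elif not isinstance(background, ResolvedBackground):
        bg = frozenset(background)
        if not bg:
            raise ValidationError("background is empty")
        background = ResolvedBackground(genes=bg, n_unrecognized=0, source="user")

    cleaned, _ = clean_gene_list(query)
    if not cleaned:
        raise ValidationError("query is empty after de-duplication")
    bg = background.genes
    query_in = [g for g in cleaned if g in bg]
    query_dropped = [g for g in cleaned if g not in bg]
    if not query_in:
        raise ValidationError("no query gene is in the background")
    query_set = set(query_in)
    n = len(query_set)
    N = len(bg)

    tested: list[tuple[str, ContingencyCounts, set[str]]] = []
    for term_id in sorted(library.term_genes):
        genes_bg = library.term_genes[term_id] & bg
        K = len(genes_bg)
        if K < min_term_size or K > max_term_size:
            continue
        overlap = genes_bg & query_set
        tested.append((term_id, ContingencyCounts(k=len(overlap), n=n, K=K, N=N), overlap))
    if not tested:
        raise ValidationError(
            f"no term eligible for testing with min_term_size={min_term_size}, "
            f"max_term_size={max_term_size}"
        )

    p_values = np.array([test(counts) for _, counts, _ in tested])
    q_values = adjust_pvalues(p_values, method=adjust)

    rows = [
        EnrichmentRow(
            term_id=term_id,
            term_name=library.term_names.get(term_id, ""),
            category=library.term_category.get(term_id, library.database),
            counts=counts,
            fold=fold_enrichment(counts),
            p_value=float(p),
            q_value=float(q),
            genes=sorted(overlap),
            significant=bool(q <= q_cutoff),
        )
        for (term_id, counts, overlap), p, q in zip(tested, p_values, q_values)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return EnrichmentTable(
        rows=rows,
        background_size=N,
        query_used=n,
        query_dropped=query_dropped,
        settings={
            "database": library.database,
            "taxon": library.taxon,
            "method": method,
            "adjust": adjust,
            "min_term_size": min_term_size,
            "max_term_size": max_term_size,
            "q_cutoff": q_cutoff,
            "background_source": background.source,
        },
    )
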