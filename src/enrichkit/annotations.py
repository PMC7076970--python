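"""Readers for the standard annotation dialects and the library file format.

Four input dialects are supported, matching what GO-style annotation pipelines
actually consume:

* **GAF 2.x** — the Gene Association File distributed by GOA: tab-separated,
  ``!``-prefixed headers, object symbol in column 3, qualifier in column 4,
  term id in column 5, evidence code in column 7, ``taxon:<id>`` in column 13.
* **gene2go** — NCBI's per-taxon gene→GO table keyed by numeric GeneID.
* **gene_info** — NCBI's gene table mapping numeric GeneID to official symbol
  and ``|``-separated synonyms (``-`` meaning none).
* **term–gene tables** — generic three-column TSV (term id, term name, gene)
  standing in for flat exports of KEGG, Reactome, DISEASES channels and
  DisGeNET.

All parsers are lossless up to documented filters (header skipping and an
optional taxon filter): de-duplication and qualifier/evidence filtering are
the library builder's job.

The module also reads and writes this package's own on-disk library format: a
deterministic sorted TSV with a ``#``-commented header carrying provenance
(database, taxon, build timestamp, source checksums).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable

from .errors import LibraryFormatError, ParseError
from .library import SpeciesLibrary

LIBRARY_FORMAT_MARKER = "# enrichkit-library v1"
#: pseudo-category under which the species gene universe is stored on disk
_UNIVERSE_CATEGORY = "__universe__"


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene↔term assignment as read from an annotation file.

    ``gene_key`` is the identifier as given — an official symbol (GAF, flat
    tables) or a numeric NCBI GeneID rendered as a string (gene2go).
    Annotations whose qualifier contains ``NOT`` assert *absence* of function
    and are flagged for exclusion downstream via :attr:`excluded`.
    """

    gene_key: str
    term_id: str
    qualifier: str | None = None
    evidence_code: str | None = None
    taxon: int | None = None

    def __post_init__(self):
        if not self.gene_key:
            raise ParseError("annotation with empty gene key")
        if not self.term_id:
            raise ParseError("annotation with empty term id")

    @property
    def excluded(self) -> bool:
        """True when the qualifier carries a NOT token."""
        if not self.qualifier:
            return False
        return "NOT" in self.qualifier.split("|")


@dataclass(frozen=True)
class GeneInfoRecord:
    """One row of an NCBI gene_info-style table."""

    taxon: int
    gene_id: int
    symbol: str
    synonyms: frozenset[str] = frozenset()


def _open_lines(stream) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def parse_gaf(stream) -> list[GeneAnnotation]:
    """Parse GAF 2.x lines into annotations.

    Lines starting with ``!`` are headers.  Data lines must carry at least 15
    tab-separated columns; the taxon is taken from the first ``taxon:`` token
    of column 13.
    """
    annotations: list[GeneAnnotation] = []
    for lineno, raw in enumerate(_open_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            raise ParseError(
                f"GAF data line has {len(cols)} columns, expected >= 15", lineno
            )
        symbol, qualifier, term_id, evidence = cols[2], cols[3], cols[4], cols[6]
        if not term_id:
            raise ParseError("GAF data line with empty term id", lineno)
        taxon: int | None = None
        for token in cols[12].split("|"):
            if token.startswith("taxon:"):
                taxon = int(token[len("taxon:"):])
                break
        annotations.append(
            GeneAnnotation(
                gene_key=symbol,
                term_id=term_id,
                qualifier=qualifier or None,
                evidence_code=evidence or None,
                taxon=taxon,
            )
        )
    return annotations


def parse_gene2go(stream, taxon: int | None = None) -> list[GeneAnnotation]:
    """Parse an NCBI gene2go-style table.

    Columns: tax_id, GeneID, GO_ID, Evidence, Qualifier, ...; ``#``-prefixed
    header.  ``taxon`` filters rows to one species; rows for other taxa are
    skipped (an absent taxon yields an empty list, not an error).  Duplicate
    (gene, term) rows with different evidence codes are all kept.
    """
    annotations: list[GeneAnnotation] = []
    for lineno, raw in enumerate(_open_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError("gene2go line with fewer than 3 columns", lineno)
        try:
            tax_id = int(cols[0])
            gene_id = int(cols[1])
        except ValueError:
            raise ParseError(
                f"non-numeric tax_id/GeneID: {cols[0]!r}, {cols[1]!r}", lineno
            ) from None
        if taxon is not None and tax_id != taxon:
            continue
        qualifier = cols[4] if len(cols) > 4 and cols[4] not in ("", "-") else None
        evidence = cols[3] if len(cols) > 3 and cols[3] not in ("", "-") else None
        annotations.append(
            GeneAnnotation(
                gene_key=str(gene_id),
                term_id=cols[2],
                qualifier=qualifier,
                evidence_code=evidence,
                taxon=tax_id,
            )
        )
    return annotations


def parse_gene_info(stream, taxon: int | None = None) -> list[GeneInfoRecord]:
    """Parse an NCBI gene_info-style table.

    Columns: tax_id, GeneID, Symbol, ..., with ``|``-separated synonyms in
    column 5 (``-`` meaning none).  A duplicated (taxon, gene_id) pair is an
    error naming the gene id.
    """
    records: list[GeneInfoRecord] = []
    seen: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(_open_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError("gene_info line with fewer than 3 columns", lineno)
        try:
            tax_id = int(cols[0])
            gene_id = int(cols[1])
        except ValueError:
            raise ParseError(
                f"non-numeric tax_id/GeneID: {cols[0]!r}, {cols[1]!r}", lineno
            ) from None
        if taxon is not None and tax_id != taxon:
            continue
        if (tax_id, gene_id) in seen:
            raise ParseError(f"duplicate gene_info entry for gene id {gene_id}", lineno)
        seen.add((tax_id, gene_id))
        symbol = cols[2]
        if not symbol:
            raise ParseError("gene_info row with empty symbol", lineno)
        synonyms: frozenset[str] = frozenset()
        if len(cols) > 4 and cols[4] and cols[4] != "-":
            synonyms = frozenset(s for s in cols[4].split("|") if s)
        records.append(
            GeneInfoRecord(taxon=tax_id, gene_id=gene_id, symbol=symbol, synonyms=synonyms)
        )
    return records


def parse_term_gene_table(stream) -> tuple[list[GeneAnnotation], dict[str, str]]:
    """Parse a generic three-column term–gene table.

    Columns: term_id, term_name, gene.  Returns the (possibly duplicated)
    annotations and a term_id→name map; a later name for the same term
    overwrites an earlier one.
    """
    annotations: list[GeneAnnotation] = []
    names: dict[str, str] = {}
    for lineno, raw in enumerate(_open_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError("term-gene table row with fewer than 3 columns", lineno)
        term_id, term_name, gene = cols[0], cols[1], cols[2]
        if not term_id or not term_name or not gene:
            raise ParseError("term-gene table row with an empty column", lineno)
        names[term_id] = term_name
        annotations.append(GeneAnnotation(gene_key=gene, term_id=term_id))
    return annotations, names


# ---------------------------------------------------------------------------
# on-disk library format


def write_library(library: SpeciesLibrary, path) -> None:
    """Write a library as a deterministic sorted TSV.

    Layout: a format-marker line, ``#``-commented provenance (database, taxon,
    build timestamp, source checksums), then one row per (term, gene) pair —
    columns category, term_id, term_name, gene_symbol — followed by the
    species gene universe under the pseudo-category ``__universe__``.  Apart
    from the timestamp line, two writes of the same library are
    byte-identical.
    """
    lines = [LIBRARY_FORMAT_MARKER]
    lines.append(f"# database: {library.database}")
    lines.append(f"# taxon: {library.taxon}")
    lines.append(f"# built: {datetime.now(timezone.utc).isoformat(timespec='seconds')}")
    for key in sorted(library.version_info):
        lines.append(f"# source: {key}={library.version_info[key]}")
    lines.append("# columns: category\tterm_id\tterm_name\tgene_symbol")
    for term_id in sorted(library.term_genes):
        category = library.term_category.get(term_id, library.database)
        name = library.term_names.get(term_id, "")
        for gene in sorted(library.term_genes[term_id]):
            lines.append(f"{category}\t{term_id}\t{name}\t{gene}")
    for gene in sorted(library.universe):
        lines.append(f"{_UNIVERSE_CATEGORY}\t-\t-\t{gene}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_library(path) -> SpeciesLibrary:
    """Read a library file written by :func:`write_library`.

    Refuses files whose first line is not the expected format marker.
    """
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != LIBRARY_FORMAT_MARKER:
            raise LibraryFormatError(
                f"{path}: unknown library format marker {first!r}; "
                f"expected {LIBRARY_FORMAT_MARKER!r}"
            )
        database = "custom"
        taxon = 0
        version_info: dict[str, str] = {}
        term_genes: dict[str, set[str]] = {}
        term_names: dict[str, str] = {}
        term_category: dict[str, str] = {}
        universe: set[str] = set()
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("database:"):
                    database = body.split(":", 1)[1].strip()
                elif body.startswith("taxon:"):
                    taxon = int(body.split(":", 1)[1].strip())
                elif body.startswith("source:"):
                    key, _, value = body.split(":", 1)[1].strip().partition("=")
                    version_info[key] = value
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(f"library row with {len(cols)} columns, expected 4", lineno)
            category, term_id, name, gene = cols
            if category == _UNIVERSE_CATEGORY:
                universe.add(gene)
                continue
            term_genes.setdefault(term_id, set()).add(gene)
            term_names[term_id] = name
            term_category[term_id] = category
    return SpeciesLibrary(
        database=database,
        taxon=taxon,
        term_genes=term_genes,
        term_names=term_names,
        term_category=term_category,
        universe=universe,
        version_info=version_info,
    )
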