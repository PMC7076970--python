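"""Per-species, per-database gene-function library construction.

A *library* is the object enrichment runs against: for one species and one
database it maps each functional term to the set of genes carrying it, plus
term names, category labels (GO namespace, or the database label for flat
sources) and the species gene *universe* — every official symbol the NCBI
gene table knows for the taxon, which is the default enrichment background.

Two construction paths exist.  The GO path consumes an ontology plus GAF or
gene2go annotations and applies the true-path rule: each annotation assigns
its gene to the annotated term and to every ancestor over is_a/part_of.
Gene identity is normalized to the official symbol at build time (numeric
gene ids via the gene table; synonyms resolved when unambiguous; unresolved
symbols kept verbatim and counted).  The flat path consumes generic
term–gene tables (KEGG, Reactome, DISEASES channels, DisGeNET) and simply
de-duplicates and restricts them to the species universe.
"""

from __future__ import annotations

import configparser
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from .errors import BuildError, ValidationError
from .ontology import DEFAULT_RELATIONS, Ontology, parse_obo

if TYPE_CHECKING:  # circular at runtime: annotations imports SpeciesLibrary
    from .annotations import GeneAnnotation, GeneInfoRecord

KNOWN_DATABASES = ("GO", "KEGG", "Reactome", "DISEASES", "DisGeNET", "custom")


@dataclass
class SpeciesLibrary:
    """A versioned term→gene-set mapping for one species and one database."""

    database: str
    taxon: int
    term_genes: dict[str, set[str]]
    term_names: dict[str, str]
    term_category: dict[str, str]
    universe: set[str]
    version_info: dict[str, str] = field(default_factory=dict)

    def __eq__(self, other) -> bool:
        """Data equality; provenance text (timestamps, checksums) is ignored."""
        if not isinstance(other, SpeciesLibrary):
            return NotImplemented
        return (
            self.database == other.database
            and self.taxon == other.taxon
            and self.term_genes == other.term_genes
            and self.term_names == other.term_names
            and self.term_category == other.term_category
            and self.universe == other.universe
        )

    def n_terms(self) -> int:
        return len(self.term_genes)

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.term_genes.values():
            out |= genes
        return out


@dataclass
class BuildReport:
    """Counts emitted by a library build: what went in and what was dropped."""

    database: str
    n_annotations_in: int = 0
    n_not_excluded: int = 0
    n_evidence_excluded: int = 0
    n_unknown_terms: int = 0
    n_obsolete_terms: int = 0
    n_unresolved_genes: int = 0
    n_off_universe_dropped: int = 0
    n_terms: int = 0
    n_genes: int = 0

    def lines(self) -> list[str]:
        return [
            f"[{self.database}]",
            f"annotations read: {self.n_annotations_in}",
            f"NOT-qualified excluded: {self.n_not_excluded}",
            f"evidence-code excluded: {self.n_evidence_excluded}",
            f"unknown terms dropped: {self.n_unknown_terms}",
            f"obsolete terms dropped: {self.n_obsolete_terms}",
            f"unresolved gene ids kept verbatim: {self.n_unresolved_genes}",
            f"off-universe genes dropped: {self.n_off_universe_dropped}",
            f"library terms: {self.n_terms}",
            f"library genes: {self.n_genes}",
        ]


class SymbolResolver:
    """Normalize gene identifiers to official symbols for one taxon.

    Numeric gene ids map through the gene table; strings match an official
    symbol directly or, failing that, a synonym that points to exactly one
    official symbol (ambiguous synonyms stay unresolved).
    """

    def __init__(self, gene_info: Sequence["GeneInfoRecord"], taxon: int):
        self.taxon = taxon
        self.by_gene_id: dict[int, str] = {}
        self.symbols: set[str] = set()
        synonym_hits: dict[str, set[str]] = {}
        for rec in gene_info:
            if rec.taxon != taxon:
                continue
            self.by_gene_id[rec.gene_id] = rec.symbol
            self.symbols.add(rec.symbol)
            for syn in rec.synonyms:
                synonym_hits.setdefault(syn, set()).add(rec.symbol)
        self.by_synonym: dict[str, str] = {
            syn: next(iter(targets))
            for syn, targets in synonym_hits.items()
            if len(targets) == 1 and syn not in self.symbols
        }

    def resolve(self, gene_key: str) -> tuple[str, bool]:
        """Return (symbol, resolved).  Unresolvable keys come back verbatim."""
        if gene_key.isdigit():
            gene_id = int(gene_key)
            if gene_id in self.by_gene_id:
                return self.by_gene_id[gene_id], True
            return gene_key, False
        if gene_key in self.symbols:
            return gene_key, True
        if gene_key in self.by_synonym:
            return self.by_synonym[gene_key], True
        return gene_key, False


def build_go_library(
    ontology: Ontology,
    annotations: Sequence["GeneAnnotation"],
    gene_info: Sequence["GeneInfoRecord"],
    taxon: int,
    relations: Iterable[str] = DEFAULT_RELATIONS,
    evidence_exclude: Iterable[str] = (),
) -> tuple[SpeciesLibrary, BuildReport]:
    """Build a GO library with true-path-rule propagation.

    Each surviving annotation assigns its gene to the annotated term and to
    every ancestor under ``relations``.  NOT-qualified annotations and those
    with an excluded evidence code are dropped; annotations to terms absent
    from the ontology (release drift) or obsolete are counted and skipped,
    not fatal.  Raises :class:`BuildError` if nothing survives.
    """
    relations = frozenset(relations)
    evidence_exclude = frozenset(evidence_exclude)
    resolver = SymbolResolver(gene_info, taxon)
    report = BuildReport(database="GO")
    term_genes: dict[str, set[str]] = {}
    universe = set(resolver.symbols)

    for ann in annotations:
        if ann.taxon is not None and ann.taxon != taxon:
            continue
        report.n_annotations_in += 1
        if ann.excluded:
            report.n_not_excluded += 1
            continue
        if ann.evidence_code in evidence_exclude:
            report.n_evidence_excluded += 1
            continue
        if ann.term_id not in ontology:
            report.n_unknown_terms += 1
            continue
        primary = ontology.resolve(ann.term_id)
        if ontology.terms[primary].obsolete:
            report.n_obsolete_terms += 1
            continue
        symbol, resolved = resolver.resolve(ann.gene_key)
        if not resolved:
            report.n_unresolved_genes += 1
            universe.add(symbol)  # keep verbatim; universe must cover it
        term_genes.setdefault(primary, set()).add(symbol)
        for anc in ontology.ancestors(primary, relations):
            term_genes.setdefault(anc, set()).add(symbol)

    if not term_genes:
        raise BuildError("GO build: zero annotations survived filtering")

    term_names = {t: ontology.terms[t].name for t in term_genes}
    term_category = {t: ontology.terms[t].namespace or "GO" for t in term_genes}
    library = SpeciesLibrary(
        database="GO",
        taxon=taxon,
        term_genes=term_genes,
        term_names=term_names,
        term_category=term_category,
        universe=universe,
    )
    report.n_terms = len(term_genes)
    report.n_genes = len(library.annotated_genes())
    return library, report


def build_flat_library(
    pairs: Sequence["GeneAnnotation"],
    term_names: dict[str, str],
    database: str,
    gene_info: Sequence["GeneInfoRecord"],
    taxon: int,
) -> tuple[SpeciesLibrary, BuildReport]:
    """Build a library from a flat term–gene table (KEGG/Reactome/disease).

    Pairs are de-duplicated; genes outside the species universe are dropped
    and counted; terms left empty are pruned.  Every term must have a name.
    """
    resolver = SymbolResolver(gene_info, taxon)
    report = BuildReport(database=database)
    term_genes: dict[str, set[str]] = {}
    seen: set[tuple[str, str]] = set()
    for ann in pairs:
        report.n_annotations_in += 1
        if ann.excluded:
            report.n_not_excluded += 1
            continue
        symbol, resolved = resolver.resolve(ann.gene_key)
        if not resolved or symbol not in resolver.symbols:
            report.n_off_universe_dropped += 1
            continue
        key = (ann.term_id, symbol)
        if key in seen:
            continue
        seen.add(key)
        term_genes.setdefault(ann.term_id, set()).add(symbol)

    term_genes = {t: genes for t, genes in term_genes.items() if genes}
    for term_id in term_genes:
        if term_id not in term_names or not term_names[term_id]:
            raise BuildError(f"{database} build: term {term_id} has no name")
    if not term_genes:
        raise BuildError(f"{database} build: zero annotations survived filtering")

    library = SpeciesLibrary(
        database=database,
        taxon=taxon,
        term_genes=term_genes,
        term_names={t: term_names[t] for t in term_genes},
        term_category={t: database for t in term_genes},
        universe=set(resolver.symbols),
    )
    report.n_terms = len(term_genes)
    report.n_genes = len(library.annotated_genes())
    return library, report


def merge_disease_channels(
    channels: Sequence[tuple[str, Sequence["GeneAnnotation"]]],
) -> tuple[list["GeneAnnotation"], dict[tuple[str, str], list[str]]]:
    """Union (term, gene) pairs across disease evidence channels.

    The DISEASES resource ships separate text-mining, knowledge and
    experiment channels; the merged, non-redundant union of their pairs makes
    up the disease library.  Each pair appears once; its supporting channel
    labels are preserved in the returned provenance map.
    """
    from .annotations import GeneAnnotation

    provenance: dict[tuple[str, str], list[str]] = {}
    for label, anns in channels:
        for ann in anns:
            key = (ann.term_id, ann.gene_key)
            labels = provenance.setdefault(key, [])
            if label not in labels:
                labels.append(label)
    merged = [
        GeneAnnotation(gene_key=gene, term_id=term)
        for term, gene in sorted(provenance)
    ]
    return merged, provenance


# ---------------------------------------------------------------------------
# whole-species builds from a manifest

#: manifest section name → canonical database label
_SECTION_DATABASES = {
    "go": "GO",
    "kegg": "KEGG",
    "reactome": "Reactome",
    "do": "DISEASES",
    "disgenet": "DisGeNET",
    "custom": "custom",
}


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def read_manifest(path) -> configparser.ConfigParser:
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise BuildError(f"manifest not found: {path}")
    return parser


def make_species_db(manifest_path, out_dir) -> tuple[list[Path], list[BuildReport]]:
    """Build every library a manifest requests and write them to ``out_dir``.

    The manifest is an INI-style key–value file: a ``[species]`` section with
    ``taxon`` and ``gene_info``, then one section per database (``[go]`` with
    ``obo`` plus ``gaf`` and/or ``gene2go`` and optional ``relations`` /
    ``evidence_exclude``; ``[kegg]``/``[reactome]``/``[disgenet]``/``[custom]``
    with ``table``; ``[do]`` with one ``channel.<label>`` entry per evidence
    channel).  Input files are checked before anything is written, so a
    missing file aborts the build with no partial output.  Library files are
    named ``<taxon>.<section>.library.tsv`` and a ``build_report.txt``
    summarizes counts.  Rebuilding from identical inputs reproduces identical
    libraries (timestamp line aside).
    """
    from . import annotations as ann_io

    manifest = read_manifest(manifest_path)
    if "species" not in manifest:
        raise BuildError("manifest missing [species] section")
    species = manifest["species"]
    if "taxon" not in species or "gene_info" not in species:
        raise BuildError("[species] section must define 'taxon' and 'gene_info'")
    taxon = int(species["taxon"])
    base = Path(manifest_path).parent

    def resolve_path(value: str) -> Path:
        p = Path(value)
        return p if p.is_absolute() else base / p

    gene_info_path = resolve_path(species["gene_info"])
    requested = [s for s in manifest.sections() if s in _SECTION_DATABASES]
    if not requested:
        raise BuildError(
            "manifest requests no databases; known sections: "
            + ", ".join(sorted(_SECTION_DATABASES))
        )

    # validate all inputs up front: all-or-nothing per build
    needed: list[Path] = [gene_info_path]
    for section in requested:
        cfg = manifest[section]
        if section == "go":
            for key in ("obo",):
                if key not in cfg:
                    raise BuildError("[go] section must define 'obo'")
            if "gaf" not in cfg and "gene2go" not in cfg:
                raise BuildError("[go] section must define 'gaf' and/or 'gene2go'")
            needed.append(resolve_path(cfg["obo"]))
            for key in ("gaf", "gene2go"):
                if key in cfg:
                    needed.append(resolve_path(cfg[key]))
        elif section == "do":
            channel_keys = [k for k in cfg if k.startswith("channel.")]
            if not channel_keys:
                raise BuildError("[do] section must define at least one 'channel.<label>'")
            needed.extend(resolve_path(cfg[k]) for k in channel_keys)
        else:
            if "table" not in cfg:
                raise BuildError(f"[{section}] section must define 'table'")
            needed.append(resolve_path(cfg["table"]))
    missing = [str(p) for p in needed if not p.is_file()]
    if missing:
        raise BuildError("missing input file(s): " + ", ".join(missing))

    with open(gene_info_path, encoding="utf-8") as fh:
        gene_info = ann_io.parse_gene_info(fh, taxon=taxon)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    reports: list[BuildReport] = []
    for section in requested:
        cfg = manifest[section]
        sources = {"gene_info": _sha256(gene_info_path)}
        if section == "go":
            obo_path = resolve_path(cfg["obo"])
            with open(obo_path, encoding="utf-8") as fh:
                ontology = parse_obo(fh)
            sources["obo"] = _sha256(obo_path)
            anns: list = []
            if "gaf" in cfg:
                gaf_path = resolve_path(cfg["gaf"])
                with open(gaf_path, encoding="utf-8") as fh:
                    anns.extend(ann_io.parse_gaf(fh))
                sources["gaf"] = _sha256(gaf_path)
            if "gene2go" in cfg:
                g2g_path = resolve_path(cfg["gene2go"])
                with open(g2g_path, encoding="utf-8") as fh:
                    anns.extend(ann_io.parse_gene2go(fh, taxon=taxon))
                sources["gene2go"] = _sha256(g2g_path)
            relations = frozenset(
                r.strip() for r in cfg.get("relations", "is_a,part_of").split(",") if r.strip()
            )
            evidence_exclude = frozenset(
                e.strip() for e in cfg.get("evidence_exclude", "").split(",") if e.strip()
            )
            library, report = build_go_library(
                ontology, anns, gene_info, taxon,
                relations=relations, evidence_exclude=evidence_exclude,
            )
        elif section == "do":
            channels = []
            for key in sorted(k for k in cfg if k.startswith("channel.")):
                label = key.split(".", 1)[1]
                channel_path = resolve_path(cfg[key])
                with open(channel_path, encoding="utf-8") as fh:
                    pairs, names = ann_io.parse_term_gene_table(fh)
                channels.append((label, pairs, names))
                sources[f"channel.{label}"] = _sha256(channel_path)
            merged, _ = merge_disease_channels([(lab, prs) for lab, prs, _ in channels])
            names: dict[str, str] = {}
            for _, _, channel_names in channels:
                names.update(channel_names)
            library, report = build_flat_library(
                merged, names, _SECTION_DATABASES[section], gene_info, taxon
            )
        else:
            table_path = resolve_path(cfg["table"])
            with open(table_path, encoding="utf-8") as fh:
                pairs, names = ann_io.parse_term_gene_table(fh)
            sources["table"] = _sha256(table_path)
            library, report = build_flat_library(
                pairs, names, _SECTION_DATABASES[section], gene_info, taxon
            )
        library.version_info = {k: sources[k] for k in sorted(sources)}
        out_path = out_dir / f"{taxon}.{section}.library.tsv"
        ann_io.write_library(library, out_path)
        written.append(out_path)
        reports.append(report)

    report_path = out_dir / "build_report.txt"
    with open(report_path, "w", encoding="utf-8") as fh:
        for report in reports:
            fh.write("\n".join(report.lines()) + "\n\n")
    return written, reports


def library_path(library_dir, taxon: int, database_key: str) -> Path:
    """Canonical on-disk location of one species/database library."""
    key = database_key.lower()
    if key not in _SECTION_DATABASES:
        raise ValidationError(
            f"unknown database {database_key!r}; valid: "
            + ", ".join(sorted(_SECTION_DATABASES))
        )
    return Path(library_dir) / f"{taxon}.{key}.library.tsv"
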