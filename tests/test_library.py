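"""Library construction: propagation, flat builds, channel merges, manifests."""

import numpy as np
import pytest

import enrichkit as ek
from enrichkit.annotations import GeneAnnotation, GeneInfoRecord
from enrichkit.errors import BuildError

from .helpers import (
    gene_info_for,
    naive_go_construction,
    random_annotations,
    random_ontology,
)

TAXON = 9001


class TestBuildGoLibrary:
    def test_chain_propagates_to_all_ancestors(self, chain_ontology):
        anns = [GeneAnnotation(gene_key="g", term_id="GO:0000003", taxon=TAXON)]
        lib, _ = ek.build_go_library(chain_ontology, anns, gene_info_for(["g"]), TAXON)
        assert lib.term_genes == {
            "GO:0000001": {"g"},
            "GO:0000002": {"g"},
            "GO:0000003": {"g"},
        }

    def test_sibling_union_at_root(self, diamond_ontology):
        anns = [
            GeneAnnotation(gene_key="g1", term_id="T:B"),
            GeneAnnotation(gene_key="g2", term_id="T:C"),
        ]
        lib, _ = ek.build_go_library(
            diamond_ontology, anns, gene_info_for(["g1", "g2"]), TAXON
        )
        assert lib.term_genes["T:A"] == {"g1", "g2"}

    def test_matches_naive_dfs_oracle_on_random_fixture(self):
        rng = np.random.default_rng(99)
        genes = [f"g{i}" for i in range(20)]
        onto = random_ontology(rng, 7)
        anns = random_annotations(rng, onto, genes, 30)
        lib, _ = ek.build_go_library(onto, anns, gene_info_for(genes), TAXON)
        assert lib.term_genes == naive_go_construction(onto, anns)

    def test_parent_superset_monotonicity_and_root_union(self, go_library, fixture_universe):
        with open(fixture_universe["paths"]["obo"]) as fh:
            onto = ek.parse_obo(fh)
        annotated = set()
        for term_id, genes in go_library.term_genes.items():
            annotated |= genes
            for parent in onto.terms[term_id].parents():
                assert go_library.term_genes[parent] >= genes
        (root,) = onto.roots()
        assert go_library.term_genes[root] == annotated

    def test_not_and_evidence_filters(self, chain_ontology):
        anns = [
            GeneAnnotation(gene_key="g1", term_id="GO:0000003", qualifier="NOT"),
            GeneAnnotation(gene_key="g2", term_id="GO:0000003", evidence_code="IEA"),
            GeneAnnotation(gene_key="g3", term_id="GO:0000003", evidence_code="EXP"),
        ]
        lib, report = ek.build_go_library(
            chain_ontology, anns, gene_info_for(["g1", "g2", "g3"]), TAXON,
            evidence_exclude={"IEA"},
        )
        assert lib.term_genes["GO:0000003"] == {"g3"}
        assert report.n_not_excluded == 1 and report.n_evidence_excluded == 1

    def test_unknown_and_obsolete_terms_counted_not_fatal(self):
        onto = ek.parse_obo("[Term]\nid: A\n\n[Term]\nid: B\nis_obsolete: true\n")
        anns = [
            GeneAnnotation(gene_key="g1", term_id="A"),
            GeneAnnotation(gene_key="g1", term_id="GHOST"),
            GeneAnnotation(gene_key="g1", term_id="B"),
        ]
        lib, report = ek.build_go_library(onto, anns, gene_info_for(["g1"]), TAXON)
        assert report.n_unknown_terms == 1 and report.n_obsolete_terms == 1
        assert set(lib.term_genes) == {"A"}

    def test_numeric_ids_and_synonyms_resolved_to_symbols(self, chain_ontology):
        info = [
            GeneInfoRecord(taxon=TAXON, gene_id=5, symbol="ALPHA", synonyms=frozenset({"old"})),
        ]
        anns = [
            GeneAnnotation(gene_key="5", term_id="GO:0000003", taxon=TAXON),
            GeneAnnotation(gene_key="old", term_id="GO:0000002", taxon=TAXON),
            GeneAnnotation(gene_key="STRANGER", term_id="GO:0000002", taxon=TAXON),
        ]
        lib, report = ek.build_go_library(chain_ontology, anns, info, TAXON)
        assert lib.term_genes["GO:0000003"] == {"ALPHA"}
        assert "ALPHA" in lib.term_genes["GO:0000002"]
        # unresolved symbol kept verbatim, counted, and covered by the universe
        assert "STRANGER" in lib.term_genes["GO:0000002"]
        assert "STRANGER" in lib.universe
        assert report.n_unresolved_genes == 1

    def test_zero_surviving_annotations_is_error(self, chain_ontology):
        anns = [GeneAnnotation(gene_key="g", term_id="GO:0000003", qualifier="NOT")]
        with pytest.raises(BuildError):
            ek.build_go_library(chain_ontology, anns, gene_info_for(["g"]), TAXON)

    def test_idempotence(self, chain_ontology):
        anns = [GeneAnnotation(gene_key="g", term_id="GO:0000002")]
        info = gene_info_for(["g"])
        lib1, _ = ek.build_go_library(chain_ontology, anns, info, TAXON)
        lib2, _ = ek.build_go_library(chain_ontology, anns, info, TAXON)
        assert lib1 == lib2


class TestBuildFlatLibrary:
    NAMES = {"T1": "one", "T2": "two"}

    def test_duplicate_pair_collapsed(self):
        pairs = [
            GeneAnnotation(gene_key="A", term_id="T1"),
            GeneAnnotation(gene_key="A", term_id="T1"),
            GeneAnnotation(gene_key="B", term_id="T1"),
            GeneAnnotation(gene_key="A", term_id="T2"),
        ]
        lib, _ = ek.build_flat_library(pairs, self.NAMES, "KEGG", gene_info_for(["A", "B"]), TAXON)
        assert sum(len(g) for g in lib.term_genes.values()) == 3

    def test_off_universe_gene_dropped_and_counted(self):
        pairs = [
            GeneAnnotation(gene_key="A", term_id="T1"),
            GeneAnnotation(gene_key="NOPE", term_id="T1"),
        ]
        lib, report = ek.build_flat_library(pairs, self.NAMES, "KEGG", gene_info_for(["A"]), TAXON)
        assert lib.term_genes["T1"] == {"A"}
        assert report.n_off_universe_dropped == 1

    def test_totals_match_hand_construction(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(20)]
        off = [f"x{i}" for i in range(5)]
        terms = [f"T{i}" for i in range(10)]
        pairs = [
            GeneAnnotation(
                gene_key=(genes + off)[int(rng.integers(25))],
                term_id=terms[int(rng.integers(10))],
            )
            for _ in range(50)
        ]
        names = {t: t.lower() for t in terms}
        lib, _ = ek.build_flat_library(pairs, names, "Reactome", gene_info_for(genes), TAXON)
        expected: dict[str, set[str]] = {}
        for p in pairs:
            if p.gene_key in genes:
                expected.setdefault(p.term_id, set()).add(p.gene_key)
        assert lib.term_genes == {t: g for t, g in expected.items() if g}

    def test_empty_terms_pruned_and_nameless_term_fatal(self):
        pairs = [GeneAnnotation(gene_key="A", term_id="T1"),
                 GeneAnnotation(gene_key="NOPE", term_id="T2")]
        lib, _ = ek.build_flat_library(pairs, self.NAMES, "KEGG", gene_info_for(["A"]), TAXON)
        assert "T2" not in lib.term_genes
        with pytest.raises(BuildError, match="T1"):
            ek.build_flat_library(pairs, {}, "KEGG", gene_info_for(["A"]), TAXON)


class TestMergeDiseaseChannels:
    def test_shared_pair_keeps_both_labels(self):
        a = [GeneAnnotation(gene_key="g", term_id="D1")]
        merged, prov = ek.merge_disease_channels([("text", a), ("knowledge", a)])
        assert len(merged) == 1
        assert prov[("D1", "g")] == ["text", "knowledge"]

    def test_disjoint_channels_sum(self):
        channels = [
            (f"c{j}", [GeneAnnotation(gene_key=f"g{j}_{i}", term_id="D1") for i in range(n)])
            for j, n in enumerate([2, 3, 4])
        ]
        merged, _ = ek.merge_disease_channels(channels)
        assert len(merged) == 9

    def test_inclusion_exclusion_on_overlapping_channels(self):
        base = [GeneAnnotation(gene_key=f"g{i}", term_id="D1") for i in range(6)]
        a, b = base[:4], base[2:]  # |a|=4, |b|=4, |a∩b|=2
        merged, _ = ek.merge_disease_channels([("a", a), ("b", b)])
        assert len(merged) == 4 + 4 - 2

    def test_empty_channels_allowed(self):
        merged, _ = ek.merge_disease_channels([("a", [])])
        assert merged == []


class TestMakeSpeciesDb:
    def test_full_manifest_builds_five_libraries(self, fixture_universe):
        assert len(fixture_universe["written"]) == 5
        assert len(fixture_universe["reports"]) == 5
        report_text = (fixture_universe["db_dir"] / "build_report.txt").read_text()
        for label in ("GO", "KEGG", "Reactome", "DISEASES", "DisGeNET"):
            assert f"[{label}]" in report_text

    def test_go_only_manifest_builds_one_file(self, fixture_universe, tmp_path):
        fx = fixture_universe["fixture_dir"]
        manifest = tmp_path / "go_only.ini"
        manifest.write_text(
            f"[species]\ntaxon = 9001\ngene_info = {fx / 'gene_info.tsv'}\n"
            f"[go]\nobo = {fx / 'fixture.obo'}\ngaf = {fx / 'fixture.gaf'}\n"
        )
        written, _ = ek.make_species_db(manifest, tmp_path / "db")
        assert [p.name for p in written] == ["9001.go.library.tsv"]

    def test_rebuild_is_deterministic(self, fixture_universe, tmp_path):
        fx = fixture_universe["fixture_dir"]
        written, _ = ek.make_species_db(fx / "species_db.ini", tmp_path / "again")
        for path in written:
            fresh = [l for l in path.read_text().splitlines() if not l.startswith("# built:")]
            orig_path = fixture_universe["db_dir"] / path.name
            orig = [l for l in orig_path.read_text().splitlines() if not l.startswith("# built:")]
            assert fresh == orig

    def test_missing_input_aborts_before_writing(self, fixture_universe, tmp_path):
        fx = fixture_universe["fixture_dir"]
        manifest = tmp_path / "bad.ini"
        manifest.write_text(
            f"[species]\ntaxon = 9001\ngene_info = {fx / 'gene_info.tsv'}\n"
            f"[go]\nobo = {fx / 'fixture.obo'}\ngaf = {tmp_path / 'missing.gaf'}\n"
        )
        out = tmp_path / "out"
        with pytest.raises(BuildError, match="missing input"):
            ek.make_species_db(manifest, out)
        assert not out.exists() or not any(out.iterdir())

    def test_gaf_and_gene2go_renderings_build_identical_go_sets(self, fixture_universe, tmp_path):
        """The two annotation dialects encode the same truth, so the built
        term→gene sets must coincide."""
        fx = fixture_universe["fixture_dir"]
        m1 = tmp_path / "via_gaf.ini"
        m1.write_text(
            f"[species]\ntaxon = 9001\ngene_info = {fx / 'gene_info.tsv'}\n"
            f"[go]\nobo = {fx / 'fixture.obo'}\ngaf = {fx / 'fixture.gaf'}\n"
        )
        m2 = tmp_path / "via_g2g.ini"
        m2.write_text(
            f"[species]\ntaxon = 9001\ngene_info = {fx / 'gene_info.tsv'}\n"
            f"[go]\nobo = {fx / 'fixture.obo'}\ngene2go = {fx / 'gene2go.tsv'}\n"
        )
        (w1,), _ = ek.make_species_db(m1, tmp_path / "d1")
        (w2,), _ = ek.make_species_db(m2, tmp_path / "d2")
        assert ek.read_library(w1).term_genes == ek.read_library(w2).term_genes
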