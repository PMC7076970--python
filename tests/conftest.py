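"""Shared fixtures: tiny hand-written inputs plus one generated mini-universe."""

import pytest

import enrichkit as ek

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: A
namespace: biological_process
alt_id: GO:0000099

[Term]
id: GO:0000002
name: B
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: C
namespace: biological_process
is_a: GO:0000002
"""

DIAMOND_OBO = """\
[Term]
id: T:A
[Term]
id: T:B
is_a: T:A
[Term]
id: T:C
is_a: T:A
[Term]
id: T:D
is_a: T:B
is_a: T:C
"""


@pytest.fixture
def chain_ontology():
    return ek.parse_obo(CHAIN_OBO)


@pytest.fixture
def diamond_ontology():
    return ek.parse_obo(DIAMOND_OBO)


@pytest.fixture(scope="session")
def fixture_universe(tmp_path_factory):
    """One generated mini-universe with all five libraries built from it."""
    root = tmp_path_factory.mktemp("universe")
    fx_dir = root / "fx"
    result = ek.generate_fixture(ek.FixtureSpec(seed=11), fx_dir)
    db_dir = root / "db"
    written, reports = ek.make_species_db(fx_dir / "species_db.ini", db_dir)
    return {
        "fixture_dir": fx_dir,
        "db_dir": db_dir,
        "truth": result["truth"],
        "paths": result["paths"],
        "written": written,
        "reports": reports,
    }


@pytest.fixture(scope="session")
def go_library(fixture_universe):
    return ek.read_library(fixture_universe["db_dir"] / "9001.go.library.tsv")
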