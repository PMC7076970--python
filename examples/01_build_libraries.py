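"""Build species-specific gene-function libraries from annotation files.

Generates a miniature annotation universe (OBO ontology, GAF annotations,
NCBI-style gene tables, flat pathway/disease tables), then assembles one
library per database the way a real species build would, and prints what
each library contains.
"""

from pathlib import Path

import enrichkit as ek

workdir = Path("scratch_example_build")
fixture = ek.generate_fixture(ek.FixtureSpec(seed=1), workdir / "inputs")
written, reports = ek.make_species_db(workdir / "inputs" / "species_db.ini", workdir / "db")

for path, report in zip(written, reports):
    lib = ek.read_library(path)
    print(
        f"{lib.database:>8}: {lib.n_terms():3d} terms, "
        f"{len(lib.annotated_genes()):3d} annotated genes, "
        f"universe {len(lib.universe)} -> {path.name}"
    )
print()
print("Each line is one built library: the number of functional terms that")
print("survived filtering, how many genes carry at least one of them, and the")
print("species universe (all official symbols from the gene table) that will")
print("serve as the default enrichment background.")
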