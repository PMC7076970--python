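"""Over-representation analysis of a gene list against a GO library.

Builds the example libraries, runs the exact one-sided test on the fixture
query (which carries a planted enriched term), and prints the top of the
ranked result table.
"""

from pathlib import Path

import enrichkit as ek

workdir = Path("scratch_example_enrich")
fixture = ek.generate_fixture(ek.FixtureSpec(seed=1), workdir / "inputs")
ek.make_species_db(workdir / "inputs" / "species_db.ini", workdir / "db")

library = ek.read_library(workdir / "db" / "9001.go.library.tsv")
query = (workdir / "inputs" / "query.txt").read_text().split()

table = ek.enrich(query, library, method="fisher", adjust="BH", q_cutoff=0.05)
print(f"background N = {table.background_size}, query n = {table.query_used}\n")
print(f"{'term':<12} {'k':>3} {'K':>3} {'fold':>6} {'p':>10} {'q':>10}  sig")
for row in table.rows[:5]:
    print(
        f"{row.term_id:<12} {row.counts.k:>3} {row.counts.K:>3} "
        f"{row.fold:>6.2f} {row.p_value:>10.2e} {row.q_value:>10.2e}  "
        f"{'*' if row.significant else ''}"
    )
print()
print("k of the n query genes fall in a term carried by K of the N background")
print("genes; fold is (k/n)/(K/N); p is the hypergeometric upper tail and q its")
print("Benjamini-Hochberg adjustment. The planted term",
      fixture["truth"]["planted_go_terms"][0], "should rank first.")
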