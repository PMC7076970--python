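"""Bar and bubble plots of an enrichment table.

Renders both figure types for the example enrichment and prints where the
files went.
"""

from pathlib import Path

import enrichkit as ek

workdir = Path("scratch_example_plots")
ek.generate_fixture(ek.FixtureSpec(seed=1), workdir / "inputs")
ek.make_species_db(workdir / "inputs" / "species_db.ini", workdir / "db")
library = ek.read_library(workdir / "db" / "9001.go.library.tsv")
query = (workdir / "inputs" / "query.txt").read_text().split()
table = ek.enrich(query, library)

spec = ek.PlotSpec(top_n=10, rank_by="q_value")
bar = workdir / "example.GO.barplot.png"
bubble = workdir / "example.GO.bubbleplot.png"
ek.bar_plot(table, spec, bar)
ek.bubble_plot(table, spec, bubble)
print(f"bar plot    -> {bar}   (bar length = -log10 q)")
print(f"bubble plot -> {bubble} (x = fold enrichment, area ~ k, color = q)")
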