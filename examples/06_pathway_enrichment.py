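"""Pathway over-representation analysis with topology impact scores.

For each pathway: Total (pathway size), Expected (size x query/background),
Hits, the upper-tail hypergeometric Raw p, BH (FDR) and Holm adjusted
p-values, and a betweenness-centrality Impact in [0, 1].  Only pathways with
at least three hits are reported.
"""

import metabomark as mm

library = mm.generate_pathway_library(n_pathways=12, background_size=80,
                                      size_range=(6, 25), seed=9)
# query: the compounds of one pathway plus some random background
query = sorted(library.pathways[2].compounds)[:8] + sorted(library.background)[:6]

rows = mm.report_pathways(mm.ora(query, library), min_hits=3)
print(mm.ora_table(rows).to_string(index=False,
                                   float_format=lambda v: f"{v:.3f}"))
# Expected/Total is the same constant (mapped query size / background size)
# on every row; the planted pathway should top the table with a small raw p,
# and Holm is always >= the BH value for the same row.
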