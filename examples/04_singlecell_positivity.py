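"""Marker-positive cell fractions before and after treatment.

Simulates sparse single-cell counts for two biopsy conditions with
different marker detection fractions and reports the positive-cell
percentage per condition — the per-condition tally a pre/post
treatment-resistance comparison reports.
"""

import numpy as np

import coexnet as cx

pre = cx.generate_single_cell(
    cx.SingleCellSpec(n_cells=112, n_genes=20, detection_fraction={"CD276": 0.18}, seed=1)
)
post = cx.generate_single_cell(
    cx.SingleCellSpec(n_cells=83, n_genes=20, detection_fraction={"CD276": 0.39}, seed=2)
)
counts = cx.SingleCellCounts(
    matrix=np.vstack([np.asarray(pre.matrix), np.asarray(post.matrix)]),
    cell_ids=[f"pre_{c}" for c in pre.cell_ids] + [f"post_{c}" for c in post.cell_ids],
    genes=pre.genes,
    conditions=["pre"] * pre.n_cells + ["post"] * post.n_cells,
)

for r in cx.positivity_fraction(counts, "CD276", by_condition=True):
    print(
        f"{r.condition}: {r.n_positive}/{r.n_cells} cells positive "
        f"({r.percent_1dp}%)"
    )
# A cell is positive iff its raw count is > 0; the percentage is exact
# integer arithmetic rounded to one decimal.
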