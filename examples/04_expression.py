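"""RPKM normalization and 2-fold regulation calls.

RPKM = reads / (gene length in kb x library size in millions).  A gene is
called up-regulated when the mutant/control ratio of mean replicate RPKM
is >= 2, down-regulated when <= 0.5.
"""

import pandas as pd

import splicedm as sp

print("single value: 10 reads, 1 kb gene, 1 M mapped reads ->",
      sp.compute_rpkm(10, 1000, 1_000_000), "RPKM")

counts = pd.DataFrame(
    {
        "mut_1": [800, 150, 40], "mut_2": [820, 140, 35],
        "ctrl_1": [200, 145, 160], "ctrl_2": [210, 150, 150],
    },
    index=["gene_up", "gene_flat", "gene_down"],
)
res = sp.expression_table(
    counts,
    lengths={"gene_up": 2000, "gene_flat": 1000, "gene_down": 1500},
    condition_map={"mut_1": "mutant", "mut_2": "mutant",
                   "ctrl_1": "control", "ctrl_2": "control"},
    library_totals={s: 1_000_000 for s in counts.columns},
)
print()
print(res[["gene_id", "mean_mut", "mean_ctrl", "fold_change", "regulation"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
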