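"""The statistical layer: Dunnett, Tukey, ΔΔCt, and fold-change screening.

Dunnett compares each patient group to the shared control with an
equicorrelated multivariate-t adjustment; Tukey compares all pairs via the
studentized range. The qRT-PCR table is analyzed with the comparative
ΔΔCt method (RQ = 2^-ΔΔCt, geometric summaries, calibrator = 1), and an
expression matrix is screened at the strict >2-fold cut with a planted
Venn intersection.
"""

import numpy as np

from neurophenotyper.stats import ddct, deg_filter_and_venn, dunnett_test, tukey_hsd
from neurophenotyper.synth import generate_ct_table, generate_expression_matrix

rng = np.random.default_rng(0)
control = rng.normal(100, 12, 6)
bp = rng.normal(75, 12, 6)          # true 25% deficit
scz = rng.normal(80, 12, 6)

res = dunnett_test([control, bp, scz], labels=["control", "BP", "SCZ"])
print("Dunnett vs control:")
print(res.to_frame().to_string(index=False))
print("\nTukey all pairs:")
print(tukey_hsd([control, bp, scz], labels=["control", "BP", "SCZ"])
      .to_frame().to_string(index=False))

ct = generate_ct_table(
    {"control": 3, "BP": 3},
    fold_changes={"BP": {"PCDH15": 0.5}},
    target_genes=["PCDH15"],
    seed=1,
)
rel = ddct(ct, reference_gene="GAPDH", calibrator_group="control",
           target_gene="PCDH15")
print("\nPCDH15 relative expression (RQ, geometric mean x/ geometric SD):")
print(rel.group_summary.to_string(index=False))

both = {f"G{i:05d}": 3.0 for i in range(30)}
mat, groups, _ = generate_expression_matrix(
    n_genes=500, groups={"control": 3, "BP": 3, "SCZ": 3},
    planted={"BP": {**both, **{f"G{i:05d}": 3.0 for i in range(30, 50)}},
             "SCZ": both},
    seed=2,
)
deg = deg_filter_and_venn(mat, groups, [("BP", "control"), ("SCZ", "control")])
print(f"\nDEGs >2-fold: {deg.counts()}, Venn intersection: {len(deg.intersection())}")
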