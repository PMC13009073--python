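"""Differential abundance with planted effects, then pathway enrichment.

Plants a log-scale shift of 1.0 on 20 of 389 features (so the true L2FC is
1/ln 2 ~ 1.44), runs per-feature ANOVA with BH FDR, and tests the pathway
holding 40% of the shifted features for over-representation. Also recomputes
the printed nine-pathway enrichment summary from its count triples.
"""

import numpy as np
import pandas as pd

import thyromet as tm

cohort = tm.generate_cohort(19, 16, seed=1)
table, truth = tm.generate_metabolome(
    cohort, 389, effects=[(j, 1.0) for j in range(20)],
    enriched_pathway=3, seed=2,
)
pareto, _ = tm.pareto_scale(tm.log_transform(table))
res = tm.differential_analysis(pareto, cohort, alpha=0.05)

planted = res.iloc[:20]
print(f"significant features (q < 0.05): {int(res['significant'].sum())} of 389")
print(f"mean L2FC on planted features: {planted['l2fc'].mean():.3f} "
      f"(true value {1 / np.log(2):.3f})")

sig = pd.Series(res["significant"].to_numpy(), index=res["feature_id"])
rows = tm.fisher_enrichment(sig, truth.pathway_label)
p3 = {str(r.pathway): r.p_fisher for r in rows}["3"]
print(f"enriched pathway Fisher p: {p3:.4f}  (it holds 40% of the planted effects)")

print("\nprinted-counts reproduction:")
print(tm.table2_report(tm.reproduce_table2()))
# Most planted features are recovered at FDR 0.05, the planted pathway tests
# significant, and the printed table's raw p (lipid 0.018) and BH value
# (0.160) come back exactly from its count triples.
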