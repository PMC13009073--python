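"""Weighted sub-network analysis on planted correlation modules.

Simulates five 20-feature modules with within-module correlation 0.8 and a
group shift on the first module's features, builds the signed soft-power
network and TOM dissimilarity, cuts five Ward modules, and associates each
module eigenmetabolite with the outcome.
"""

from sklearn.metrics import adjusted_rand_score

import thyromet as tm

cohort = tm.generate_cohort(19, 16, seed=1)
table, truth = tm.generate_metabolome(
    cohort, 100, modules=[(20, 0.8)] * 5,
    effects=[(j, 0.8) for j in range(20)], seed=2,
)
pareto, _ = tm.pareto_scale(tm.log_transform(table))

net = tm.build_network(pareto, beta=6.0, tau=0.1)
labels = tm.cluster_modules(net.diss, k=5)
mods = tm.eigenmetabolites(pareto, labels)
assoc = tm.module_outcome_association(mods, cohort)

ari = adjusted_rand_score(truth.module_label.to_numpy(), labels.to_numpy())
print(f"module recovery ARI vs planted truth: {ari:.3f}")
for a in assoc:
    lo, hi = a.ci95
    print(f"module {a.module}: r = {a.pearson_r:+.2f} (p = {a.pearson_p:.3f}), "
          f"OR = {a.or_:.2f} [{lo:.2f}, {hi:.2f}], Wald chi2 = {a.wald_chi2:.2f}")
# ARI near 1 means the TOM + Ward cut recovered the planted blocks; the
# module carrying the planted group shift shows the strongest eigenmetabolite
# association (|r| largest, CI for its per-SD odds ratio away from 1).
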