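"""Group-level comparison of full- and partial-correlation networks.

Simulates a small cohort of subjects sharing one true network, estimates a
full-correlation and a partial-correlation matrix per subject, then runs
the group comparison toolkit: Fisher-z edge effect sizes, the four-way
significance categories (A: partial-only, B: full-only, C: both, D:
neither), per-category sign consistency, and module-wise Spearman agreement
between the two averaged networks.
"""

import numpy as np

from climenet import (
    SubjectStack,
    categorize_edges,
    clime_estimate,
    edge_effect_size,
    full_correlation,
    group_average,
    modulewise_spearman,
    precision_to_parcorr,
    sample_covariance,
)
from climenet.compare import ModulePartition
from climenet.simulate import NetworkSpec, generate_precision, generate_timeseries

M, T, n_subjects = 12, 120, 12
omega_true = generate_precision(NetworkSpec(M, sparsity_level=0.3, seed=1))

full_mats, partial_mats = [], []
for s in range(n_subjects):
    ds = generate_timeseries(omega_true, T=T, gamma=0.3, seed=100 + s)
    full_mats.append(full_correlation(ds.Y).values)
    est = clime_estimate(sample_covariance(ds.Y), lam=0.05)
    partial_mats.append(precision_to_parcorr(est).values)

es_full = edge_effect_size(SubjectStack(full_mats, kind="full"))
es_partial = edge_effect_size(SubjectStack(partial_mats, kind="partial"))
cats = categorize_edges(es_full, es_partial, threshold=0.5)
print("edge category proportions (threshold |effect| > 0.5):")
for k in "ABCD":
    sc = cats.sign_consistency[k]
    note = f"(sign consistency {sc:.2%})" if np.isfinite(sc) else "(empty)"
    print(f"  {k}: {cats.proportions[k]:.2%}  {note}")

partition = ModulePartition([f"mod{k % 3}" for k in range(M)])
res = modulewise_spearman(group_average(full_mats),
                          group_average(partial_mats), partition)
print(f"\nmodule-wise Spearman over {len(res['blocks'])} blocks:")
print(f"  within-module  mean rho = {res['within_mean']:.3f}")
print(f"  between-module mean rho = {res['between_mean']:.3f}")
print(f"  rank-sum p (within vs between) = {res['p_value']:.3f}")
print("""
category B collects edges the marginal correlation calls significant but
the partial correlation does not — shared-neighbor effects the
conditioning removes.  The module labels here are arbitrary groupings of a
random network, so within- and between-module agreement are similar and
the rank-sum test finds no difference; on real cohort data with genuine
functional modules the within-module blocks agree more strongly.""")
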