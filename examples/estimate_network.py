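"""Full estimation pipeline on one synthetic dataset.

Generates a 10-node network with 29% of possible edges, simulates T = 50
time points with AR(1) temporal noise, sweeps the density criterion over
the tuning grid, selects the tuning parameter both at the density plateau
(minimum sparsity) and at 45% of the maximum density, and reports how well
each estimate recovers the true edges.
"""

import numpy as np

from climenet import (
    dens_profile,
    make_lambda_grid,
    precision_to_parcorr,
    sample_covariance,
    select_lambda_p,
    select_lambda_platu,
    support_metrics,
)
from climenet.simulate import NetworkSpec, generate_precision, generate_timeseries

omega_true = generate_precision(NetworkSpec(n_nodes=10, sparsity_level=0.29, seed=4))
ds = generate_timeseries(omega_true, T=50, gamma=0.3, seed=5)
print(f"simulated T={ds.T}, M=10, tau^2={ds.tau2:.3f}, gamma={ds.gamma}")

sigma = sample_covariance(ds.Y)
profile = dens_profile(sigma, make_lambda_grid())
print(f"density profile: Dens rises from {profile.dens[0]:.2f} at lambda=0.4 "
      f"to {profile.dens_max:.2f} at the small-lambda plateau")

truth = precision_to_parcorr(omega_true)
for sel in (select_lambda_platu(profile), select_lambda_p(profile, 0.45)):
    est = profile.estimates[sel.index]
    pcorr = precision_to_parcorr(est)
    sens, spec = support_metrics(pcorr, truth)
    n_edges = int((np.abs(est.values[np.triu_indices(10, 1)]) > est.zero_tol).sum())
    print(f"\n{sel.method}: lambda = {sel.lam_selected:.3g}, "
          f"{n_edges}/45 possible edges kept")
    print(f"  sensitivity {sens:.2f} (true edges found), "
          f"specificity {spec:.2f} (true zeros kept)")
print("\nthe plateau estimate is denser (high sensitivity, low specificity);"
      "\nthe 45%-density estimate trades recall for far fewer false edges")
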