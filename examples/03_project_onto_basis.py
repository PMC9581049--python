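"""Project a clustered pattern onto the shipped universal SNPCA basis.

The basis was trained once on completely spatially random points, so the
origin of (SNPC1, SNPC2) is "spatial randomness": the radius r measures
how structured a localisation's neighbourhood is, and the angle theta
what kind of structure it is.  Here ground truth shows r tracking
cluster isolation (D_BNN), theta separating noise from signal, and
within-cluster SNPC1 tracking the distance to the parent molecule.
"""

import numpy as np
from scipy import stats

from kna import analyse_image, default_basis, simulate_clustered_pattern

basis = default_basis()
pattern = simulate_clustered_pattern(seed=7)
features = analyse_image(pattern.table, basis, K=100)

ok = features["valid"].to_numpy()
sig = ~pattern.is_noise & ok
noise = pattern.is_noise & ok

rho, _ = stats.spearmanr(features["r"][sig], pattern.D_BNN[sig])
ks = stats.ks_2samp(features["theta"][sig], features["theta"][noise]).statistic
print(f"basis: K={basis.K}, first two components carry "
      f"{100 * basis.variance_share.sum():.1f}% of CSR training variance")
print(f"localisations analysed: {len(features)} ({int(noise.sum())} noise)")
print(f"Spearman rho(r, D_BNN) over signal:  {rho:.3f}  (isolation is radial)")
print(f"KS(theta | signal vs noise):         {ks:.3f}  (noise is angular)")
print(f"mean SNPC1 signal vs noise:          "
      f"{features['pc1'][sig].mean():.2f} vs {features['pc1'][noise].mean():.2f}")
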