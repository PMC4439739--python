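"""Quantify cristae-junction enrichment of immunogold label.

Simulates two annotated micrographs over the same cristae geometry: one
protein concentrated at cristae junctions (half-normal displacement,
sigma = 30 nm, like a CJ-resident complex subunit) and one distributed
uniformly along the membranes (like a respiratory-chain subunit).  For
each, it reports the distance histogram and a Monte-Carlo p-value against
the uniform-along-membrane null.
"""

import numpy as np

from micoskit.goldmap import distance_histogram, enrichment_test, nearest_cj_distance
from micoskit.simulate import GoldSimConfig, simulate_micrograph

paths = [np.array([[0.0, 0.0], [1500.0, 0.0]]),
         np.array([[0.0, 400.0], [1200.0, 1000.0]])]
cjs = np.array([[150.0, 0.0], [1200.0, 0.0], [400.0, 600.0]])

for placement in ("cj_concentrated", "uniform"):
    cfg = GoldSimConfig(cristae_paths=paths, cj_points=cjs, n_particles=231,
                        placement=placement, sigma_nm=30.0, seed=13)
    annotation, _ = simulate_micrograph(cfg)
    distances = nearest_cj_distance(annotation)
    hist = distance_histogram(distances, bin_width=50.0)
    result = enrichment_test(annotation, n_draws=999, seed=7)

    print(f"\n{placement} (n = {hist.n_particles} gold particles)")
    print(f"  fraction within 50 nm of a CJ: {hist.fractions[0]:.2f}")
    print(f"  mean nearest-CJ distance: {result.observed:.0f} nm "
          f"(null mean {result.null_mean:.0f} nm)")
    print(f"  enrichment p-value: {result.p_value:.4g}")
# The CJ-concentrated protein puts ~90% of its label within 50 nm and gets
# the minimal achievable p (0.001 at 999 draws); the uniform protein's
# histogram is flat by arc length and its p-value is not significant.
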