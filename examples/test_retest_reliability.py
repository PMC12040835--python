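"""Test-retest reproducibility of recovered networks across two sessions.

Two synthetic sessions share the planted spatial truth but have independent
dynamics and noise.  Networks recovered in session 1 are matched one-to-one
to session 2 by the intensity-weighted overlap ("Hausdorff") metric; the
matched mean is compared with the mean over random pairings.  Matched pairs
scoring far above the permuted baseline indicates the recovered maps are
reproducible features of the data, not noise.
"""

import numpy as np

from delmar import (
    AdmmConfig,
    BrainMask,
    fit_hierarchy,
    layer_maps,
    make_ground_truth,
    make_two_sessions,
    test_retest_matrix,
)

mask = BrainMask.from_array(np.ones((16, 16, 16), dtype=bool))
truth = make_ground_truth(n_canonical=6, n_meta=2, n_timepoints=120,
                          mask=mask, seed=11)
s1, s2 = make_two_sessions(truth, seed_pair=(5, 6))

cfg = AdmmConfig(max_iter=30)
maps1 = layer_maps(fit_hierarchy(s1, cfg, layer_sizes=[6]), 1)
maps2 = layer_maps(fit_hierarchy(s2, cfg, layer_sizes=[6]), 1)

trt = test_retest_matrix(maps1, maps2, metric="hausdorff")
rng = np.random.default_rng(0)
null = np.mean([trt.values[np.arange(6), rng.permutation(6)].mean()
                for _ in range(100)])
print(f"matched-pair Hausdorff similarity (mean over 6 networks): "
      f"{trt.mean_matched:.3f}")
print(f"mean over 100 random pairings:                            {null:.3f}")
print("matched sessions far exceed the permuted baseline: the recovered "
      "networks are reproducible")
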