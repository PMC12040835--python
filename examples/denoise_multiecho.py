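"""Integrated multi-echo denoising: the first layer separates BOLD from noise.

BOLD amplitude grows linearly with echo time while thermal noise does not,
so the low-rank part of the first layer concentrates TE-coherent signal.
This example compares voxel time series against the known clean BOLD before
and after denoising; the correlation gain is the denoising benefit.
"""

import numpy as np

from delmar import AdmmConfig, BrainMask, denoise_first_layer, make_ground_truth, make_multiecho_dataset
from delmar.hierarchy import denoised_series

mask = BrainMask.from_array(np.ones((16, 16, 16), dtype=bool))
truth = make_ground_truth(n_canonical=6, n_meta=2, n_timepoints=120,
                          mask=mask, seed=11)
signal, _ = make_multiecho_dataset(truth)

decomp, _ = denoise_first_layer(signal, AdmmConfig(max_iter=30), rank=6)

clean = (truth.timecourses * truth.te_slopes) @ truth.templates
te = np.asarray(signal.echo_times)
w = te / te.sum()
clean_comb = clean * float(w @ te)           # TE-weighted clean series
raw = np.einsum("e,tve->tv", w, signal.data)  # TE-weighted raw series
den = denoised_series(decomp, signal)


def mean_corr(a, b):
    a = a - a.mean(0)
    b = b - b.mean(0)
    return float(np.mean((a * b).sum(0) /
                         np.maximum(np.sqrt((a * a).sum(0) * (b * b).sum(0)), 1e-12)))


c_raw, c_den = mean_corr(raw, clean_comb), mean_corr(den, clean_comb)
print(f"mean voxel correlation with clean BOLD, raw:      {c_raw:.3f}")
print(f"mean voxel correlation with clean BOLD, denoised: {c_den:.3f}")
print(f"denoising gain: {c_den - c_raw:+.3f} "
      "(positive: the sparse background absorbed TE-independent noise)")
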