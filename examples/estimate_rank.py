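"""Estimate the effective rank of noisy low-rank matrices with pivoted QR.

Builds rank-5 matrices at decreasing signal-to-noise ratios and shows the
weighted-ratio diagnostics: a clear drop in the pivoted-QR diagonal marks
the rank; when the gap disappears into the noise the estimator falls back
to the full numerical rank.
"""

import numpy as np

from delmar import estimate_rank, rank_diagnostics

rng = np.random.default_rng(0)
signal = rng.standard_normal((100, 5)) @ rng.standard_normal((5, 400))

for snr in (np.inf, 10, 1, 0.1):
    noise = 0 if np.isinf(snr) else \
        rng.standard_normal(signal.shape) * np.sqrt(np.mean(signal**2) / snr)
    diag = rank_diagnostics(signal + noise)
    if diag.estimated_rank < len(diag.d):
        gap = f"{min(diag.wr[diag.estimated_rank - 1], 1e6):.2f}"
    else:
        gap = "none (full numerical rank)"
    print(f"SNR {snr!s:>4}: estimated rank = {diag.estimated_rank:3d}  "
          f"(weighted ratio at the gap: {gap})")
print("rank 5 is recovered until the noise floor swallows the QR-diagonal gap")
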