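# delmar

Multilayer ("deep linear") low-rank + sparse matrix decomposition for
multi-echo fMRI, with integrated BOLD denoising in its first layer,
automatic layer sizing by a pivoted-QR rank-reduction operator, and the
evaluation metrics used for hierarchical brain-connectivity mapping.

## The problem

Resting-state fMRI reveals brain connectivity networks (BCNs) — spatial maps
of coactivating regions.  Their organisation is hierarchical: canonical
networks (default mode, visual, auditory, ...) recombine into larger
"meta-networks" at coarser scales.  Shallow decompositions (ICA, sparse
dictionary learning) map one scale at a time and need their component counts
tuned by hand.  This package implements a stacked linear alternative for
researchers analysing multi-echo fMRI: every layer is a low-rank + sparse
matrix factorisation, layer sizes are estimated from the data, and — because
BOLD signal amplitude is linear in echo time (TE) while thermal noise is
TE-independent — the first layer doubles as a multi-echo denoiser, removing
the need for a separate ICA-based denoising step.

## The model

Each layer `k` approximates its input matrix `S_k` as

    S_k  ≈  X_k Y_k + Z_k ,      min ‖Z_k‖₁  s.t.  X_k Y_k + Z_k = S_k

where `X_k` (loadings), `Y_k` (spatial features: one voxel map per row) and
a sparse background `Z_k` that absorbs weak/sparse structure (artifacts,
thermal noise).  The augmented Lagrangian

    L = β/2 ‖X Y + Z − S‖²_F + ⟨X Y + Z − S, e⟩ + (1/β) ‖Z‖₁

is minimised by ADMM: alternating least-squares updates of `X` and `Y`,
soft-thresholding (the ℓ1 proximal operator) of `Z`, and a multiplier
ascent step on `e`.  Layer 1 consumes the echo-unfolded signal
`T × (M·nTE)`; its feature matrix is collapsed across echoes by TE-weighted
averaging, and every deeper layer factorises the previous feature matrix
`Y_{k−1}` at a strictly smaller rank, so all layers' feature rows remain
voxel maps.  Layer sizes come from the rank-reduction operator (RRO): the
magnitudes `d_i = |R_ii|` of the column-pivoted QR are non-increasing, and
the largest weighted ratio `wr_i = d_i / d_{i+1}` marks the boundary between
structure and noise.  The hierarchy terminates when the estimated rank
reaches 1.

Recovered maps are scored against templates by top-5% spatial overlap
(`|C ∩ T| / |T|`), voxelwise intensity agreement, and an intensity-weighted
overlap ("Hausdorff" metric, `Σ 2·min(x,y) / Σ (x+y)` over the thresholded
sets); test-retest reliability is summarised by matched-pair similarity and
the intraclass correlation coefficient ICC(1,1).

## Worked example

`examples/fit_synthetic_hierarchy.py` plants a two-level hierarchy
(6 canonical networks grouped into 2 meta-networks) in noisy 3-echo data and
fits a two-layer model:

```
synthetic signal: T=120, M=4096, nTE=3, SNR 2
fitted layer sizes: [6, 2] (layer 1 doubles as the multi-echo denoiser)
layer 1 vs planted canonical networks: mean matched spatial similarity = 0.847
layer 2 vs planted meta-networks:      mean matched spatial similarity = 0.834
```

The similarities are top-5% overlaps between each recovered map and its
best-matched planted template (1 = identical active sets; chance ≈ 0.05):
both the canonical level and the meta level are recovered from data at
signal-to-noise ratio 2.  The other examples show rank estimation under
noise (`estimate_rank.py`), the denoising benefit of the first layer
(`denoise_multiecho.py`, correlation gain +0.171 over the raw TE-weighted
series), and test-retest reproducibility (`test_retest_reliability.py`,
matched-pair similarity 0.898 vs 0.151 for random pairings).

## Command line

```bash
delmar simulate --out-dir sim/ --seed 7            # NIfTI echoes + mask + truth
delmar fit --echo-series sim/session1_echo1.nii.gz,sim/session1_echo2.nii.gz,sim/session1_echo3.nii.gz \
           --mask sim/mask.nii.gz --echo-times 11,30,49 --out-dir fit/ --layer-sizes auto
delmar evaluate --model fit/model.h5 --layer 1 --templates t1.nii.gz,t2.nii.gz --out-dir eval/
```

Layer-size presets `mbme-whole-brain` ([300, 72, 18, 6]) and
`meica-whole-brain` ([96, 24, 6]) are provided for whole-brain acquisitions;
the default is automatic sizing.

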