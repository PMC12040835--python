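"""Synthetic multi-echo fMRI with a planted two-level network hierarchy.

The generator emulates the structure the decomposition is designed to
recover, with full ground truth for every ingredient:

* **Canonical networks** — smooth, compact, peak-normalised Gaussian blobs on
  the masked grid, spread by farthest-point placement.  With
  ``overlap_fraction = 0`` each blob is truncated to its own Voronoi cell, so
  distinct templates are exactly disjoint.
* **Two-level temporal hierarchy** — meta-networks group canonical networks
  (each combining at least three, with Dirichlet-drawn nonnegative weights).
  A canonical network's time course mixes a shared meta time course (variance
  fraction ``meta_coherence``) with an idiosyncratic smooth series; the
  planted meta-network maps are the mixing-weighted sums of their member
  templates.  Canonical amplitudes are drawn in stratified tiers (one
  strong, one medium, one weak member per meta group) so the planted sources
  have distinct variances.
* **TE-linear BOLD** — the signal amplitude of every network scales linearly
  with echo time through zero, the premise that lets a multi-echo model
  separate BOLD from thermal noise.  (A full mono-exponential T2* decay model
  is deliberately avoided: linear-in-TE keeps the clean signal exactly
  low-rank per echo.)
* **TE-independent noise** — i.i.d. Gaussian thermal noise plus sparse
  large-amplitude artifacts, neither scaling with TE.

Everything is reproducible bitwise from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_mask import BrainMask, MultiEchoSignal

__all__ = [
    "SyntheticGroundTruth",
    "default_mask",
    "make_templates",
    "make_ground_truth",
    "make_multiecho_dataset",
    "make_two_sessions",
    "DEFAULT_ECHO_TIMES",
]

#: Echo times (ms) of a typical 3-echo MBME acquisition.
DEFAULT_ECHO_TIMES = (11.0, 30.0, 49.0)


@dataclass
class SyntheticGroundTruth:
    """Planted templates, mixing, time courses and noise parameters."""

    templates: np.ndarray        # n_canonical x M, unit peak
    meta_mixing: np.ndarray      # n_meta x n_canonical, nonnegative, >= 3 per row
    timecourses: np.ndarray      # T x n_canonical, ~unit-variance smooth series
    te_slopes: np.ndarray        # per-network amplitude slope vs TE (1/ms)
    noise_sigma: float           # thermal noise SD (TE-independent)
    artifact_density: float      # fraction of entries with sparse artifacts
    seed: int
    mask: BrainMask
    meta_coherence: float        # shared-variance fraction within meta groups
    meta_amplitudes: np.ndarray  # n_meta relative strengths of meta drives
    membership: np.ndarray       # amplitude-free meta weights; meta_mixing = membership * amplitude

    @property
    def n_canonical(self) -> int:
        return self.templates.shape[0]

    @property
    def n_meta(self) -> int:
        return self.meta_mixing.shape[0]

    @property
    def meta_maps(self) -> np.ndarray:
        """Planted meta-network maps: mixing-weighted sums of member templates."""
        return self.meta_mixing @ self.templates


def default_mask(grid: int = 20) -> BrainMask:
    """Full cubic mask of ``grid**3`` voxels (8000 at the default size)."""
    return BrainMask.from_array(np.ones((grid,) * 3, dtype=bool))


def _gaussian_blob(shape: tuple[int, int, int], center: np.ndarray, sigma: float) -> np.ndarray:
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2.0 * sigma**2))


def make_templates(
    n_canonical: int,
    mask: BrainMask,
    overlap_fraction: float = 0.25,
    seed: int = 0,
    sigma_base: float = 1.6,
) -> np.ndarray:
    """Smooth compact blob templates with controlled pairwise overlap.

    Centres are chosen by farthest-point sampling over in-mask voxels (first
    centre seeded), blob width is ``sigma_base * (1 + overlap_fraction)``, and
    each map is normalised to unit peak.  ``overlap_fraction = 0`` truncates
    every blob to the Voronoi cell of its centre, making templates disjoint.
    """
    if n_canonical < 2:
        raise ValueError("need at least two canonical networks")
    if overlap_fraction < 0:
        raise ValueError("overlap_fraction must be nonnegative")
    M = mask.n_voxels
    if M < 20 * n_canonical:
        raise ValueError(f"mask with {M} voxels is too small for {n_canonical} templates")
    rng = np.random.default_rng(seed)
    sigma = sigma_base * (1.0 + overlap_fraction)
    coords = np.column_stack(np.unravel_index(mask.indices, mask.shape)).astype(float)

    # candidate centres stay clear of the mask boundary so blobs are compact
    # full spheres rather than truncated fragments
    from scipy.ndimage import binary_erosion

    grid = np.zeros(mask.shape, dtype=bool)
    grid.reshape(-1)[mask.indices] = True
    margin = int(np.ceil(2 * sigma))
    interior = binary_erosion(grid, iterations=margin) if margin > 0 else grid
    cand = np.column_stack(np.nonzero(interior)).astype(float)
    if cand.shape[0] < n_canonical:
        cand = coords  # tiny masks: fall back to all in-mask voxels

    centers = [cand[rng.integers(cand.shape[0])]]
    dist = np.linalg.norm(cand - centers[0], axis=1)
    for _ in range(n_canonical - 1):
        centers.append(cand[int(np.argmax(dist))])
        dist = np.minimum(dist, np.linalg.norm(cand - centers[-1], axis=1))
    centers = np.array(centers)
    templates = np.empty((n_canonical, M))
    nearest = np.argmin(
        ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1
    )
    for i, c in enumerate(centers):
        blob = mask.flatten(_gaussian_blob(mask.shape, c, sigma))
        if overlap_fraction == 0:
            blob = np.where(nearest == i, blob, 0.0)
        templates[i] = blob / blob.max()
    return templates


def _smooth_orthogonal_series(n_time: int, n_series: int, rng: np.random.Generator,
                              n_freq: int = 40) -> np.ndarray:
    """Band-limited white series, orthogonalised and standardised to unit SD."""
    x = rng.standard_normal((n_time, n_series))
    spec = np.fft.rfft(x, axis=0)
    spec[n_freq:] = 0
    y = np.fft.irfft(spec, n_time, axis=0)
    y -= y.mean(axis=0)
    q, _ = np.linalg.qr(y)
    return q / q.std(axis=0)


def _draw_timecourses(n_time: int, meta_membership: np.ndarray, meta_coherence: float,
                      meta_amplitudes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Network time courses with planted meta-group coherence.

    Idiosyncratic and meta source series are mutually orthogonal with unit
    variance; the mixture is returned unstandardised so that the coefficient
    of every meta source on every template is exactly the stored mixing
    weight (network variances then range over roughly 1 +/- the meta drive).
    """
    n_meta, n_can = meta_membership.shape
    series = _smooth_orthogonal_series(n_time, n_can + n_meta, rng)
    idio, meta = series[:, :n_can], series[:, n_can:]
    shared = (meta * meta_amplitudes) @ meta_membership
    return np.sqrt(1.0 - meta_coherence) * idio + np.sqrt(meta_coherence) * shared


def make_ground_truth(
    n_canonical: int = 12,
    n_meta: int = 4,
    n_timepoints: int = 200,
    mask: BrainMask | None = None,
    overlap_fraction: float = 0.25,
    meta_coherence: float = 0.3,
    snr: float = 2.0,
    artifact_density: float = 0.005,
    seed: int = 7,
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES,
) -> SyntheticGroundTruth:
    """Draw a complete planted hierarchy.

    The default configuration is the desk-scale study condition: T = 200 time
    points, an 8000-voxel mask, 3 echoes, 12 canonical networks grouped into
    4 meta-networks, signal-to-noise (power) ratio 2.

    ``snr`` calibrates ``noise_sigma`` so that the clean multi-echo signal
    power divided by the thermal-noise power equals ``snr`` at the reference
    ``echo_times``.
    """
    if n_canonical < 3 * n_meta:
        raise ValueError("need at least three canonical networks per meta-network")
    if not 0 <= meta_coherence < 1:
        raise ValueError("meta_coherence must be in [0, 1)")
    mask = mask or default_mask()
    rng = np.random.default_rng(seed)
    templates = make_templates(n_canonical, mask, overlap_fraction, seed=seed)

    # partition canonical networks into meta groups with Dirichlet weights
    group_size = n_canonical // n_meta
    perm = rng.permutation(n_canonical)
    membership = np.zeros((n_meta, n_canonical))
    for m in range(n_meta):
        members = perm[group_size * m: group_size * (m + 1)]
        membership[m, members] = rng.dirichlet(np.full(group_size, 3.0)) * group_size

    # stratified amplitude tiers: every meta group gets one member per tier,
    # so planted sources have well-separated variances
    tier_centers = np.linspace(1.45, 0.6, group_size)
    amplitude = np.full(n_canonical, 1.0)
    for m in range(n_meta):
        for j in range(group_size):
            amplitude[perm[group_size * m + j]] = tier_centers[j] + rng.uniform(-0.1, 0.1)

    meta_amplitudes = np.linspace(1.3, 0.7, n_meta)
    timecourses = _draw_timecourses(n_timepoints, membership, meta_coherence,
                                    meta_amplitudes, rng)

    te = np.asarray(echo_times, dtype=float)
    te_slopes = amplitude / te.mean()

    # clean signal power at the reference echo times sets the noise scale
    clean = (timecourses * amplitude) @ templates
    clean_power = float(np.mean(clean**2)) * float(np.mean((te / te.mean()) ** 2))
    noise_sigma = float(np.sqrt(clean_power / snr)) if np.isfinite(snr) else 0.0

    return SyntheticGroundTruth(
        templates=templates,
        meta_mixing=membership * amplitude,
        timecourses=timecourses,
        te_slopes=te_slopes,
        noise_sigma=noise_sigma,
        artifact_density=artifact_density,
        seed=seed,
        mask=mask,
        meta_coherence=meta_coherence,
        meta_amplitudes=meta_amplitudes,
        membership=membership,
    )


def make_multiecho_dataset(
    truth: SyntheticGroundTruth,
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES,
    noise_seed: int | None = None,
) -> tuple[MultiEchoSignal, SyntheticGroundTruth]:
    """Render the planted truth into a noisy multi-echo signal.

    ``data[t, v, e] = sum_n tc[t, n] * te_slopes[n] * TE_e * template[n, v]``
    plus TE-independent sparse artifacts and Gaussian thermal noise.  The
    clean part is exactly rank ``<= n_canonical`` in every echo slice, and
    doubling TE doubles the BOLD amplitude exactly.
    """
    te = np.asarray(echo_times, dtype=float)
    if te.ndim != 1 or te.size < 1:
        raise ValueError("need at least one echo time")
    clean = (truth.timecourses * truth.te_slopes) @ truth.templates
    data = clean[:, :, None] * te[None, None, :]
    rng = np.random.default_rng(truth.seed + 1 if noise_seed is None else noise_seed)
    if truth.artifact_density > 0 and truth.noise_sigma > 0:
        hit = rng.random(data.shape) < truth.artifact_density
        amp = 8.0 * truth.noise_sigma
        data = data + np.where(hit, rng.choice([-amp, amp], size=data.shape), 0.0)
    if truth.noise_sigma > 0:
        data = data + rng.standard_normal(data.shape) * truth.noise_sigma
    signal = MultiEchoSignal(data=data, echo_times=te, mask=truth.mask)
    return signal, truth


def make_session(
    truth: SyntheticGroundTruth,
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES,
    seed: int = 0,
) -> MultiEchoSignal:
    """One synthetic subject/session: shared spatial truth, seeded dynamics.

    Templates and meta mixing are kept from ``truth``; time courses, noise
    and artifacts are redrawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    tc = _draw_timecourses(truth.timecourses.shape[0], truth.membership,
                           truth.meta_coherence, truth.meta_amplitudes, rng)
    session_truth = replace(truth, timecourses=tc, seed=seed)
    signal, _ = make_multiecho_dataset(session_truth, echo_times, noise_seed=seed + 1)
    return signal


def make_two_sessions(
    truth: SyntheticGroundTruth,
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES,
    seed_pair: tuple[int, int] = (101, 202),
) -> tuple[MultiEchoSignal, MultiEchoSignal]:
    """Test-retest pair: shared spatial truth, independent dynamics and noise.

    Both sessions keep the planted templates and meta mixing; time courses
    and noise are redrawn per session from the two (distinct) seeds.
    """
    s1, s2 = seed_pair
    if s1 == s2:
        raise ValueError("session seeds must be distinct")
    return make_session(truth, echo_times, s1), make_session(truth, echo_times, s2)
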