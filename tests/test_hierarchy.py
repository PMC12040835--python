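import numpy as np
import pytest

from delmar import (
    AdmmConfig,
    MultiEchoSignal,
    SpatialMapSet,
    admm_layer,
    denoise_first_layer,
    fit_hierarchy,
    group_average_bcns,
    layer_maps,
    load_model,
    save_model,
)
from delmar.hierarchy import denoised_series
from delmar.io_mask import flatten_echoes

CFG = AdmmConfig(max_iter=15)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    signal, truth = small_dataset
    return fit_hierarchy(signal, CFG, layer_sizes=[6, 2]), signal, truth


class TestDenoiseFirstLayer:
    def test_single_echo_reduces_to_plain_layer(self, small_mask):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((12, small_mask.n_voxels, 1))
        sig = MultiEchoSignal(data=data, echo_times=np.array([30.0]), mask=small_mask)
        decomp, collapsed = denoise_first_layer(sig, CFG, rank=3)
        plain = admm_layer(data[:, :, 0], 3, CFG)
        np.testing.assert_array_equal(decomp.X, plain.X)
        np.testing.assert_array_equal(collapsed, plain.Y)

    def test_clean_signal_reconstructed(self, small_truth):
        from delmar import make_multiecho_dataset
        import dataclasses
        clean_truth = dataclasses.replace(small_truth, noise_sigma=0.0,
                                          artifact_density=0.0)
        sig, _ = make_multiecho_dataset(clean_truth)
        decomp, _ = denoise_first_layer(sig, AdmmConfig(max_iter=30), rank=6)
        assert decomp.residual_history[-1] <= 1e-2

    def test_denoising_beats_raw_correlation(self, fitted):
        model, signal, truth = fitted
        clean = (truth.timecourses * truth.te_slopes) @ truth.templates
        te = np.asarray(signal.echo_times)
        w = te / te.sum()
        clean_comb = clean * float(w @ te)
        den = denoised_series(model.layers[0], signal)
        raw = np.einsum("e,tve->tv", w, signal.data)

        def mean_corr(a, b):
            a = a - a.mean(0)
            b = b - b.mean(0)
            num = (a * b).sum(0)
            den_ = np.sqrt((a * a).sum(0) * (b * b).sum(0))
            return float(np.mean(num / np.maximum(den_, 1e-12)))

        assert mean_corr(den, clean_comb) >= mean_corr(raw, clean_comb) + 0.05


class TestFitHierarchy:
    def test_explicit_sizes_obeyed(self, fitted):
        model, _, _ = fitted
        assert model.layer_sizes == [6, 2]
        assert model.n_layers == 2
        assert model.denoise_layer_index == 0

    def test_non_decreasing_sizes_rejected(self, small_dataset):
        signal, _ = small_dataset
        with pytest.raises(ValueError, match="decreasing"):
            fit_hierarchy(signal, CFG, layer_sizes=[4, 4])

    def test_auto_mode_sizes_strictly_decreasing(self, small_truth):
        # at this reduced scale the planted sources only clear the noise
        # floor at high SNR; the rank estimator then drives the layer sizes
        import dataclasses
        from delmar import make_multiecho_dataset
        clean = dataclasses.replace(small_truth,
                                    noise_sigma=small_truth.noise_sigma / 5)
        signal, _ = make_multiecho_dataset(clean)
        model = fit_hierarchy(signal, CFG)
        sizes = model.layer_sizes
        assert model.n_layers >= 2
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_layer_inputs_chain_dimensions(self, fitted):
        model, _, _ = fitted
        # layer k+1 factorises layer k's collapsed feature matrix
        assert model.layers[1].X.shape == (6, 2)
        assert model.features[1].shape[1] == model.mask.n_voxels

    def test_determinism(self, small_dataset):
        signal, _ = small_dataset
        a = fit_hierarchy(signal, CFG, layer_sizes=[5, 3])
        b = fit_hierarchy(signal, CFG, layer_sizes=[5, 3])
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.Y, lb.Y)

    def test_layer_residuals_recorded(self, fitted):
        model, signal, _ = fitted
        for layer in model.layers:
            assert len(layer.residual_history) >= 1
            assert layer.residual_history[-1] >= 0


class TestLayerMaps:
    def test_map_counts_match_layer_sizes(self, fitted):
        model, _, _ = fitted
        for k in (1, 2):
            maps = layer_maps(model, k)
            assert maps.n_maps == model.layer_sizes[k - 1]
            assert maps.maps.shape[1] == model.mask.n_voxels

    def test_maps_are_peak_normalised(self, fitted):
        model, _, _ = fitted
        maps = layer_maps(model, 1)
        np.testing.assert_allclose(maps.maps.max(axis=1), 1.0)

    def test_bad_index_rejected(self, fitted):
        model, _, _ = fitted
        with pytest.raises(ValueError, match="layer"):
            layer_maps(model, 3)


class TestGroupAverage:
    def test_identical_subjects_reproduce_single_subject(self, small_mask):
        rng = np.random.default_rng(1)
        maps = SpatialMapSet.from_rows(np.abs(rng.standard_normal((3, small_mask.n_voxels))),
                                       small_mask)
        group = group_average_bcns([maps, maps, maps], maps)
        from delmar.maps import sign_fix
        np.testing.assert_allclose(group.maps, sign_fix(maps.maps))

    def test_two_subjects_average_voxelwise(self, small_mask):
        rng = np.random.default_rng(2)
        ref = np.abs(rng.standard_normal((1, small_mask.n_voxels))) + 0.1
        a = 2.0 * ref
        b = 4.0 * ref
        ref_set = SpatialMapSet.from_rows(ref, small_mask)
        group = group_average_bcns(
            [SpatialMapSet.from_rows(a, small_mask), SpatialMapSet.from_rows(b, small_mask)],
            ref_set)
        from delmar.maps import sign_fix
        expected = (sign_fix(a) + sign_fix(b)) / 2
        np.testing.assert_allclose(group.maps, expected)

    def test_empty_subject_list_rejected(self, small_mask):
        ref = SpatialMapSet.from_rows(np.ones((1, small_mask.n_voxels)), small_mask)
        with pytest.raises(ValueError, match="at least one"):
            group_average_bcns([], ref)


class TestSerialization:
    def test_hdf5_roundtrip(self, fitted, tmp_path):
        model, _, _ = fitted
        path = tmp_path / "model.h5"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.layer_sizes == model.layer_sizes
        assert loaded.denoise_layer_index == model.denoise_layer_index
        for la, lb in zip(model.layers, loaded.layers):
            np.testing.assert_array_equal(la.Y, lb.Y)
            assert la.converged == lb.converged
        np.testing.assert_array_equal(loaded.mask.indices, model.mask.indices)
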