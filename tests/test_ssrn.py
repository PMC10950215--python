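"""Spectral-spatial residual network: architecture, training, prediction."""

import warnings

import numpy as np
import pytest

from reefscan import annotate as ann
from reefscan import preprocess, scene, ssrn
from conftest import _train_two_class


class TestBuildModel:
    def test_softmax_sums_to_one(self):
        cfg = ssrn.ModelConfig(patch_size=5, reduced_channels=8, n_classes=4)
        net = ssrn.build_model(cfg, n_bands=20)
        x = np.random.default_rng(0).random((7, 5, 5, 20))
        probs = net.forward(x)
        assert probs.shape == (7, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_seeded_init_identical(self):
        cfg = ssrn.ModelConfig(seed=11)
        a = ssrn.build_model(cfg, 30)
        b = ssrn.build_model(cfg, 30)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_parameter_count_grows_with_channels(self):
        n16 = ssrn.build_model(ssrn.ModelConfig(reduced_channels=16), 30)
        n32 = ssrn.build_model(ssrn.ModelConfig(reduced_channels=32), 30)
        assert n32.parameter_count > n16.parameter_count

    @pytest.mark.parametrize("kwargs", [
        {"patch_size": 4}, {"patch_size": 1}, {"n_classes": 1},
        {"reduced_channels": 0}, {"learning_rate": 0.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ssrn.ModelConfig(**kwargs)

    def test_gradients_match_finite_differences(self):
        """Backprop spot-check against numerical gradients."""
        cfg = ssrn.ModelConfig(patch_size=3, reduced_channels=4,
                               n_spectral_units=1, n_spatial_units=1,
                               n_classes=3, seed=2)
        net = ssrn.build_model(cfg, n_bands=6)
        rng = np.random.default_rng(0)
        x = rng.random((5, 3, 3, 6))
        y = rng.integers(0, 3, size=5)
        w = np.ones(5)

        def loss():
            p = net.forward(x)
            return float(-np.log(p[np.arange(5), y]).sum() / 5)

        probs, cache = net.forward(x, keep_cache=True)
        grads = net.backward(probs, y, w, cache)
        for name in ("head_W", "adj_W", "proj_W", "spat0_W", "spec0_W1"):
            g = grads[name]
            idx = tuple(rng.integers(0, s) for s in g.shape)
            eps = 1e-6
            net.params[name][idx] += eps
            up = loss()
            net.params[name][idx] -= 2 * eps
            down = loss()
            net.params[name][idx] += eps
            num = (up - down) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=1e-3, abs=1e-7), name


class TestTrain:
    def test_initial_loss_near_log_n_classes(self, two_class_run):
        """Near-uniform softmax at init: first-epoch loss ~ ln(n_classes)."""
        _, _, model, _ = two_class_run
        k = model.config.n_classes
        assert model.history["train_loss"][0] == pytest.approx(np.log(k), abs=0.25)

    def test_easy_regime_validation_accuracy(self, two_class_run):
        """Well-separated spectra, low noise: >= 0.95 held-out accuracy."""
        _, _, _, report = two_class_run
        assert report.overall_accuracy >= 0.95

    def test_single_class_library_rejected(self, scheme, easy_library):
        lm, refl, model, _ = None, None, None, None
        cover = {"Porifera": 100.0}
        cfg = scene.SceneConfig(target_cover=cover, transect_length_m=0.4,
                                swath_width_m=0.4, seed=0)
        lm = scene.sample_label_map(cfg, scheme)
        cube = scene.render_scan(lm, easy_library, noise_sd=0.005, seed=1,
                                 samples=None, plate=scene.PlateSpec(2, 2, 0.1))
        refl = preprocess.preprocess_cube(cube)
        rois = ann.propose_rois(lm, "t", per_group=4, size=3, seed=2)
        lib = ann.rasterize_rois(rois, refl, scheme)
        tr, va = ann.split_library(lib, 0.9, seed=3)
        mcfg = ssrn.ModelConfig(patch_size=3, reduced_channels=4, max_epochs=1)
        net = ssrn.build_model(mcfg, refl.n_bands)
        with pytest.raises(ValueError, match=">= 2 classes"):
            ssrn.train(net, tr, va, {"t": refl}, mcfg)

    def test_noise_monotonically_degrades_validation_accuracy(
            self, scheme, easy_library):
        """Three matched scenes at rising sensor noise: accuracy never rises."""
        accs = []
        for noise in (0.003, 0.12, 0.5):
            _, _, _, report = _train_two_class(scheme, easy_library, noise,
                                               seed=1, max_epochs=15)
            accs.append(report.overall_accuracy)
        assert accs[0] >= accs[1] >= accs[2]


class TestPredict:
    def test_map_shape_and_plate_code(self, two_class_run):
        _, refl, model, _ = two_class_run
        pred, probs = ssrn.predict_map(model, refl)
        assert pred.shape == refl.data.shape[:2]
        assert probs.shape == (*refl.data.shape[:2], model.config.n_classes)
        assert (pred.grid[refl.plate_mask] == scene.PLATE_CODE).all()
        assert (pred.grid[~refl.plate_mask] >= 0).all()

    def test_argmax_recomputable_from_probability_raster(self, two_class_run):
        _, refl, model, _ = two_class_run
        pred, probs = ssrn.predict_map(model, refl)
        recomputed = probs.argmax(axis=2)
        off_plate = ~refl.plate_mask
        assert np.array_equal(recomputed[off_plate], pred.grid[off_plate])

    def test_probability_rasters_are_distributions(self, two_class_run):
        _, refl, model, _ = two_class_run
        _, probs = ssrn.predict_map(model, refl)
        assert (probs >= 0).all()
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-5)

    def test_band_fingerprint_mismatch_rejected(self, two_class_run):
        _, refl, model, _ = two_class_run
        clipped = scene.SpectralCube(refl.data[:, :, :-1],
                                     refl.wavelength_nm[:-1],
                                     refl.plate_mask, units=refl.units)
        with pytest.raises(ValueError, match="fingerprint"):
            ssrn.predict_map(model, clipped)

    def test_checkpoint_roundtrip_predicts_identically(self, two_class_run, tmp_path):
        _, refl, model, _ = two_class_run
        path = tmp_path / "model.npz"
        model.save(path)
        back = ssrn.TrainedModel.load(path)
        assert back.classes == model.classes
        a, _ = ssrn.predict_map(model, refl)
        b, _ = ssrn.predict_map(back, refl)
        assert np.array_equal(a.grid, b.grid)


class TestValidationReport:
    def test_confusion_rows_sum_to_class_counts(self, two_class_run):
        _, refl, model, report = two_class_run
        lib_counts = None
        row_sums = report.confusion.sum(axis=1)
        assert row_sums.sum() > 0
        # per-class proportions are recall: diagonal / row total
        for i, cls in enumerate(report.classes):
            if row_sums[i]:
                assert report.per_class_match[cls] == pytest.approx(
                    report.confusion[i, i] / row_sums[i])
            else:
                assert np.isnan(report.per_class_match[cls])

    def test_empty_validation_rejected(self, scheme, two_class_run):
        import pandas as pd

        _, refl, model, _ = two_class_run
        empty = ann.AnnotationLibrary(
            pd.DataFrame(columns=list(ann.AnnotationLibrary.REQUIRED)), scheme)
        with pytest.raises(ValueError, match="empty"):
            ssrn.validation_report(model, empty, {"t": refl})

    def test_rare_class_recall_below_abundant(self, scheme, easy_library):
        """A class at <1% of the library is recognised worse than dominant
        classes at matched noise — the under-representation failure mode."""
        cover = {"Scleractinia": 49.5,
                 "Turf algae/Cyanobacteria/Bare substrate": 49.5,
                 "Red macroalgae": 1.0}
        cfg = scene.SceneConfig(target_cover=cover, transect_length_m=2.0,
                                swath_width_m=1.0, pixel_size_m=0.01,
                                patchiness_scale_m=0.12, seed=8)
        lm = scene.sample_label_map(cfg, scheme)
        cube = scene.render_scan(lm, easy_library, noise_sd=0.3, seed=9,
                                 samples=None, plate=scene.PlateSpec(2, 2, 0.1))
        refl = preprocess.preprocess_cube(
            cube, preprocess.PreprocessConfig(min_band_snr=0.05))
        rois = ann.propose_rois(lm, "t", per_group=12, size=3, seed=10)
        lib = ann.rasterize_rois(rois, refl, scheme)
        # ROI-level split: validation patches the model has never seen,
        # the regime where a thin, rare category actually fails
        tr, va = ann.split_library(lib, 0.75, seed=11, unit="roi")
        mcfg = ssrn.ModelConfig(patch_size=3, reduced_channels=8,
                                n_spectral_units=1, n_spatial_units=1,
                                max_epochs=12, seed=3)
        net = ssrn.build_model(mcfg, refl.n_bands)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ssrn.train(net, tr, va, {"t": refl}, mcfg)
        report = ssrn.validation_report(model, va, {"t": refl})
        rare = report.per_class_match["Red macroalgae"]
        abundant = [report.per_class_match["Scleractinia"],
                    report.per_class_match[
                        "Turf algae/Cyanobacteria/Bare substrate"]]
        assert np.isfinite(rare)
        assert rare < min(abundant)
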