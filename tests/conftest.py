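"""Shared fixtures: schemes, small scenes, and the end-to-end easy-regime world."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import reefscan as rs
from reefscan import annotate as ann
from reefscan import data, preprocess, scene, ssrn, survey


@pytest.fixture(scope="session")
def scheme():
    return rs.default_scheme()


@pytest.fixture(scope="session")
def coarse_wavelengths():
    """10 nm grid over 400-750 nm: 36 bands, fast to render and train."""
    return np.arange(400.0, 751.0, 10.0)


@pytest.fixture(scope="session")
def easy_library(scheme, coarse_wavelengths):
    """Well-separated endmembers (min group angle >= 0.15 rad)."""
    return scene.make_endmembers(scheme, coarse_wavelengths, seed=1, separation=3.0)


@pytest.fixture(scope="session")
def small_scene(scheme):
    """A 100 x 50 px (1 m x 0.5 m) 2017-like truth map."""
    cfg = scene.SceneConfig(
        target_cover=dict(data.reference_mean_covers()["2017"]),
        transect_length_m=1.0, swath_width_m=0.5, pixel_size_m=0.01, seed=42)
    return scene.sample_label_map(cfg, scheme)


def _train_two_class(scheme, lib, noise_sd, seed=0, max_epochs=30):
    """Tiny 2-class scene -> preprocessed cube, trained model, val accuracy.

    A near-zero trim threshold keeps the live-band set stable across noise
    levels (controlled noise-ladder experiments) while still dropping
    fully-absorbed dead bands.
    """
    cover = {"Scleractinia": 60.0, "Turf algae/Cyanobacteria/Bare substrate": 40.0}
    cfg = scene.SceneConfig(target_cover=cover, transect_length_m=0.8,
                            swath_width_m=0.5, pixel_size_m=0.01,
                            patchiness_scale_m=0.2, seed=seed)
    lm = scene.sample_label_map(cfg, scheme)
    cube = scene.render_scan(lm, lib, noise_sd=noise_sd, seed=seed + 1,
                             samples=None, plate=scene.PlateSpec(2, 2, 0.1, 0.35))
    refl = preprocess.preprocess_cube(
        cube, preprocess.PreprocessConfig(min_band_snr=0.05))
    rois = ann.propose_rois(lm, "t", per_group=8, size=4, seed=seed + 2)
    lib_px = ann.rasterize_rois(rois, refl, scheme)
    train_lib, val_lib = ann.split_library(lib_px, 0.9, seed=seed + 3)
    mcfg = ssrn.ModelConfig(patch_size=5, reduced_channels=12,
                            n_spectral_units=1, n_spatial_units=1,
                            max_epochs=max_epochs, early_stop_patience=8, seed=seed)
    net = ssrn.build_model(mcfg, refl.n_bands)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ssrn.train(net, train_lib, val_lib, {"t": refl}, mcfg)
    report = ssrn.validation_report(model, val_lib, {"t": refl})
    return lm, refl, model, report


@pytest.fixture(scope="session")
def two_class_run(scheme, easy_library):
    return _train_two_class(scheme, easy_library, noise_sd=0.003)


@pytest.fixture(scope="session")
def easy_world(scheme, easy_library):
    """End-to-end easy-regime survey: five 2 m x 1 m transects of a
    2019-like community, scanned, preprocessed, annotated, classified, and
    surveyed with both methods.

    Returns a dict with the survey set, per-transect truth/predicted maps,
    the trained model + validation report, and the pooled PQ/DR cover table.
    """
    means = dict(data.reference_mean_covers()["2019-PQ"])
    sset = scene.simulate_survey_set(
        {"2019": means},
        n_transects=5, seed=20, scheme=scheme,
        transect_length_m=4.0, swath_width_m=1.0, pixel_size_m=0.01,
        patchiness_scale_m=0.1,
        between_transect_sd={g: 0.25 * v for g, v in means.items()},
        lib=easy_library, render=True, noise_sd=0.003, render_samples=None,
    )
    cubes = {f"T{t}": preprocess.preprocess_cube(c)
             for (_, t), c in sset.cubes.items()}
    rois, parts = [], []
    for (_, t), lm in sset.label_maps.items():
        r = ann.propose_rois(lm, f"T{t}", per_group=10, size=4, seed=100 + t)
        rois += r
        parts.append(ann.rasterize_rois(r, cubes[f"T{t}"], scheme).entries)
    import pandas as pd

    lib_px = ann.AnnotationLibrary(pd.concat(parts, ignore_index=True), scheme)
    train_lib, val_lib = ann.split_library(lib_px, 0.9, seed=5)
    mcfg = ssrn.ModelConfig(patch_size=3, reduced_channels=16,
                            n_spectral_units=1, n_spatial_units=1,
                            max_epochs=40, early_stop_patience=10, seed=0)
    net = ssrn.build_model(mcfg, next(iter(cubes.values())).n_bands)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ssrn.train(net, train_lib, val_lib, cubes, mcfg)
    report = ssrn.validation_report(model, val_lib, cubes)

    pred_maps, cover_rows = {}, []
    for (sv, t), lm in sset.label_maps.items():
        pred, probs = ssrn.predict_map(model, cubes[f"T{t}"])
        pred_maps[t] = (pred, probs)
        cover_rows.append(survey.cover_from_map(pred, sv, t, method="DR"))
        pq = survey.photoquadrat_survey(lm, sv, t, seed=300 + t)
        cover_rows.append(survey.aggregate_cover(pq, scheme))
    covers = pd.concat(cover_rows, ignore_index=True)
    return {
        "survey_set": sset,
        "cubes": cubes,
        "model": model,
        "validation": report,
        "pred_maps": pred_maps,
        "covers": covers,
        "library": (train_lib, val_lib),
    }
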