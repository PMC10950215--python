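"""Scan preprocessing: smoothing, band trimming, plate normalization, z-scoring.

The processing chain mirrors a standard underwater hyperspectral workflow:
spectra are smoothed, low-signal bands are removed (especially the longer
wavelengths, where water absorbs most of the signal), radiance is converted
to relative reflectance against the in-scene grey reference plate, and each
pixel spectrum is standardized so classification depends on spectral shape
rather than brightness.

The composed pipeline is deterministic (no RNG) and runs in the fixed order
smooth -> trim -> normalize -> standardize.  Spatial dimensions never change;
only the band axis may shrink.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .scene import SpectralCube

__all__ = [
    "PreprocessConfig",
    "smooth_spectra",
    "trim_bands",
    "normalize_to_plate",
    "standardize_spectra",
    "preprocess_cube",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the preprocessing chain.

    ``smooth_window``/``smooth_order`` parameterize the Savitzky-Golay filter
    (odd window >= 3, order < window).  ``min_band_snr`` is the plate-pixel
    mean/SD ratio below which a band is dropped.  ``plate_albedo`` sets the
    reflectance value assigned to the plate after normalization (1.0 means
    reflectance is expressed relative to the plate).
    """

    smooth_window: int = 7
    smooth_order: int = 2
    min_band_snr: float = 3.0
    standardize: bool = True
    plate_albedo: float = 1.0

    def __post_init__(self) -> None:
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 3")
        if self.smooth_order >= self.smooth_window:
            raise ValueError("smooth_order must be < smooth_window")
        if self.min_band_snr < 0:
            raise ValueError("min_band_snr must be >= 0")
        if not (0 < self.plate_albedo <= 1):
            raise ValueError("plate_albedo must be in (0, 1]")


def smooth_spectra(cube: SpectralCube, cfg: PreprocessConfig | None = None) -> SpectralCube:
    """Savitzky-Golay smooth each pixel spectrum along the band axis.

    Constants and (for order >= 1) straight lines pass through unchanged up
    to edge handling; single-band spikes are attenuated.
    """
    cfg = cfg or PreprocessConfig()
    if cube.n_bands <= cfg.smooth_window:
        raise ValueError(
            f"smooth_window {cfg.smooth_window} must be < band count {cube.n_bands}"
        )
    data = savgol_filter(cube.data, cfg.smooth_window, cfg.smooth_order,
                         axis=-1, mode="interp")
    data = np.clip(data, 0.0, None) if cube.units == "radiance" else data
    return SpectralCube(data.astype(cube.data.dtype), cube.wavelength_nm.copy(),
                        cube.plate_mask.copy(), units=cube.units)


def band_snr(cube: SpectralCube) -> np.ndarray:
    """Per-band signal-to-noise proxy: plate-pixel mean / plate-pixel SD.

    Bands whose plate pixels have zero SD but positive mean (e.g. a
    noiseless simulation) get infinite SNR by convention, so a noiseless
    cube never loses bands at any finite threshold; a band with zero mean
    carries no signal and scores 0.
    """
    if not cube.plate_mask.any():
        raise ValueError("band_snr needs a nonempty plate_mask")
    plate = cube.data[cube.plate_mask].astype(np.float64)  # (n_plate_px, bands)
    mean = plate.mean(axis=0)
    sd = plate.std(axis=0)
    snr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0),
                   np.where(mean > 0, np.inf, 0.0))
    return snr


def trim_bands(cube: SpectralCube, cfg: PreprocessConfig | None = None) -> SpectralCube:
    """Drop bands whose plate-pixel SNR falls below ``cfg.min_band_snr``.

    Under the default water model this removes the longer wavelengths
    (above ~700 nm) where attenuation suppresses the signal.  The retained
    band list is logged.
    """
    cfg = cfg or PreprocessConfig()
    snr = band_snr(cube)
    keep = snr >= cfg.min_band_snr
    if not keep.any():
        raise ValueError("all bands fall below min_band_snr")
    kept_wl = cube.wavelength_nm[keep]
    log.info("trim_bands: retained %d/%d bands (%.1f-%.1f nm)",
             keep.sum(), cube.n_bands, kept_wl[0], kept_wl[-1])
    return SpectralCube(cube.data[:, :, keep], kept_wl,
                        cube.plate_mask.copy(), units=cube.units)


def normalize_to_plate(cube: SpectralCube, cfg: PreprocessConfig | None = None) -> SpectralCube:
    """Convert radiance to relative reflectance against the reference plate.

    reflectance(px, lam) = radiance(px, lam) / mean plate radiance(lam)
    * plate_albedo.  Illumination and water-column transmission cancel, so
    spectra become comparable between transects; plate pixels map to
    ``plate_albedo`` at every band.
    """
    cfg = cfg or PreprocessConfig()
    if cube.units != "radiance":
        raise ValueError(f"normalize_to_plate expects radiance, got {cube.units!r}")
    n_plate = int(cube.plate_mask.sum())
    if n_plate < 25:
        raise ValueError(f"plate_mask covers {n_plate} pixels; >= 25 required")
    plate_mean = cube.data[cube.plate_mask].astype(np.float64).mean(axis=0)
    if (plate_mean <= 0).any():
        bad = cube.wavelength_nm[plate_mean <= 0]
        raise ValueError(f"plate mean radiance is zero at bands {bad[:5]} nm")
    data = cube.data / plate_mean[None, None, :] * cfg.plate_albedo
    return SpectralCube(data.astype(np.float32), cube.wavelength_nm.copy(),
                        cube.plate_mask.copy(), units="reflectance")


def standardize_spectra(cube: SpectralCube) -> SpectralCube:
    """Z-score each pixel spectrum across bands (constant spectra -> zeros)."""
    if cube.n_bands < 2:
        raise ValueError("standardization needs >= 2 bands")
    data = cube.data.astype(np.float64)
    mean = data.mean(axis=-1, keepdims=True)
    sd = data.std(axis=-1, keepdims=True)
    out = np.where(sd > 0, (data - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return SpectralCube(out.astype(np.float32), cube.wavelength_nm.copy(),
                        cube.plate_mask.copy(), units="standardized")


def preprocess_cube(cube: SpectralCube, cfg: PreprocessConfig | None = None) -> SpectralCube:
    """Full chain: smooth -> trim -> normalize -> standardize (if enabled)."""
    cfg = cfg or PreprocessConfig()
    out = smooth_spectra(cube, cfg)
    out = trim_bands(out, cfg)
    out = normalize_to_plate(out, cfg)
    if cfg.standardize:
        out = standardize_spectra(out)
    return out
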