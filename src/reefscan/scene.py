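"""Synthetic reef scenes and push-broom hyperspectral scans.

Every downstream stage of the pipeline (preprocessing, annotation, the
classifier, photoquadrat sampling, community statistics) is exercised against
scenes generated here, so each scene carries exact per-pixel ground truth.

A scene is a 50 m x 1 m transect label map with spatially patchy cover of the
10 benthic groups.  A scan renders that map through a simple underwater
imaging model: flat or lamp-shaped illumination, two-way exponential water
attenuation at a fixed ~1 m altitude (with attenuation rising steeply above
~700 nm, where water absorbs most of the signal), per-category endmember
reflectance with smooth intra-class variability, an embedded 10x10 cm matte
grey reference plate, and additive sensor noise.

Patchiness is produced by smoothing white noise at a configurable correlation
length and assigning pixels to groups by cover-matching quantile thresholds,
which makes realized covers exact up to pixel-count rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .categories import CategoryScheme, default_scheme

__all__ = [
    "SceneConfig",
    "LabelMap",
    "EndmemberLibrary",
    "SpectralCube",
    "WaterModel",
    "PlateSpec",
    "PLATE_CODE",
    "default_wavelengths",
    "sample_label_map",
    "make_endmembers",
    "render_scan",
    "simulate_survey_set",
    "SurveySet",
]

#: Reserved label code for reference-plate pixels in predicted maps.
PLATE_CODE = -1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Geometry and cover targets for one simulated transect.

    ``target_cover`` maps group name -> percent cover; entries must be
    non-negative and sum to 100 within +/- 0.5.  ``patchiness_scale_m`` is the
    correlation length of benthic patches (default 0.5 m).
    """

    target_cover: Mapping[str, float]
    transect_length_m: float = 50.0
    swath_width_m: float = 1.0
    pixel_size_m: float = 0.01
    patchiness_scale_m: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transect_length_m <= 0 or self.swath_width_m <= 0:
            raise ValueError("transect dimensions must be positive")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        covers = np.asarray(list(self.target_cover.values()), dtype=float)
        if covers.size == 0:
            raise ValueError("target_cover is empty")
        if (covers < 0).any():
            raise ValueError("target_cover entries must be >= 0")
        total = covers.sum()
        if not (99.5 <= total <= 100.5):
            raise ValueError(f"target_cover must sum to ~100, got {total:.2f}")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols): row 0 is the transect start, row-major layout."""
        rows = int(round(self.transect_length_m / self.pixel_size_m))
        cols = int(round(self.swath_width_m / self.pixel_size_m))
        return rows, cols


@dataclass
class LabelMap:
    """Per-pixel category raster.

    ``grid`` holds 0-based category indices (fine categories for simulated
    ground truth, group indices for classifier predictions — see ``level``).
    ``PLATE_CODE`` (-1) marks reference-plate pixels in predictions.
    Pixel (i, j) has its center at ((i + 0.5) * resolution_m,
    (j + 0.5) * resolution_m); transect meter m covers rows
    [m / resolution_m, (m + 1) / resolution_m).
    """

    grid: np.ndarray
    resolution_m: float
    scheme: CategoryScheme
    level: str = "fine"  # "fine" | "group"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        n = self.scheme.n_fine if self.level == "fine" else self.scheme.n_groups
        valid = (self.grid >= 0) & (self.grid < n)
        valid |= self.grid == PLATE_CODE
        if not valid.all():
            raise ValueError("grid holds invalid category indices")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def group_grid(self) -> np.ndarray:
        """Grid of group indices (plate pixels keep ``PLATE_CODE``)."""
        if self.level == "group":
            return self.grid.copy()
        lut = np.asarray(self.scheme.fine_to_group_index(), dtype=self.grid.dtype)
        out = np.where(self.grid == PLATE_CODE, PLATE_CODE, lut[np.maximum(self.grid, 0)])
        return out

    def cover(self) -> pd.Series:
        """Realized percent cover per group over non-plate pixels (sums to 100)."""
        gg = self.group_grid()
        mask = gg != PLATE_CODE
        counts = np.bincount(gg[mask], minlength=self.scheme.n_groups)
        pct = 100.0 * counts / counts.sum()
        return pd.Series(pct, index=list(self.scheme.group_names), name="cover_pct")

    def fine_cover(self) -> pd.Series:
        if self.level != "fine":
            raise ValueError("fine_cover requires a fine-level map")
        mask = self.grid != PLATE_CODE
        counts = np.bincount(self.grid[mask], minlength=self.scheme.n_fine)
        return pd.Series(100.0 * counts / counts.sum(),
                         index=list(self.scheme.fine_names), name="cover_pct")


@dataclass(frozen=True)
class EndmemberLibrary:
    """Per-fine-category reflectance spectra on a common wavelength grid."""

    wavelength_nm: np.ndarray
    spectra: Mapping[str, np.ndarray]  # fine name -> reflectance in [0, 1]
    intra_class_sd: Mapping[str, float]
    scheme: CategoryScheme

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        if wl.ndim != 1 or not (np.diff(wl) > 0).all():
            raise ValueError("wavelength grid must be 1-D strictly ascending")
        for name, s in self.spectra.items():
            s = np.asarray(s)
            if s.shape != wl.shape:
                raise ValueError(f"spectrum length mismatch for {name!r}")
            if (s < 0).any() or (s > 1).any():
                raise ValueError(f"reflectance outside [0, 1] for {name!r}")

    @property
    def n_bands(self) -> int:
        return len(self.wavelength_nm)

    def group_means(self) -> dict[str, np.ndarray]:
        """Mean spectrum per group over its member fine categories."""
        out: dict[str, np.ndarray] = {}
        for g in self.scheme.group_names:
            members = [n for n in self.scheme.fines_in_group(g) if n in self.spectra]
            if members:
                out[g] = np.mean([self.spectra[n] for n in members], axis=0)
        return out

    def stack(self, fine_names: Sequence[str]) -> np.ndarray:
        return np.stack([self.spectra[n] for n in fine_names])


@dataclass
class SpectralCube:
    """Radiance or reflectance hypercube (lines x samples x bands)."""

    data: np.ndarray
    wavelength_nm: np.ndarray
    plate_mask: np.ndarray
    units: str = "radiance"  # "radiance" | "reflectance" | "standardized"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.plate_mask = np.asarray(self.plate_mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("cube data must be lines x samples x bands")
        if self.data.shape[2] != len(self.wavelength_nm):
            raise ValueError("band count must equal wavelength length")
        if self.plate_mask.shape != self.data.shape[:2]:
            raise ValueError("plate_mask shape must match spatial dimensions")
        if self.units == "radiance" and (self.data < 0).any():
            raise ValueError("radiance must be nonnegative")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_fingerprint(self) -> tuple[float, ...]:
        """Wavelength grid rounded to 0.01 nm; identifies the retained-band set."""
        return tuple(np.round(self.wavelength_nm, 2))


@dataclass(frozen=True)
class WaterModel:
    """Two-way exponential attenuation at fixed altitude.

    ``attenuation(wl)`` is piecewise linear: a gentle rise across the visible
    range, then a steep rise above ``nir_knee_nm`` emulating strong water
    absorption in the near infrared.  Units: 1/m.
    """

    altitude_m: float = 1.0
    k_blue: float = 0.06      # 1/m at 400 nm
    k_red: float = 0.45       # 1/m at the knee
    k_nir: float = 4.0        # 1/m at 750 nm
    nir_knee_nm: float = 700.0

    def __post_init__(self) -> None:
        if self.altitude_m < 0 or min(self.k_blue, self.k_red, self.k_nir) < 0:
            raise ValueError("altitude and attenuation must be nonnegative")

    def attenuation(self, wavelength_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelength_nm, dtype=float)
        k = np.interp(wl, [400.0, self.nir_knee_nm, 750.0],
                      [self.k_blue, self.k_red, self.k_nir])
        return k

    def transmission(self, wavelength_nm: np.ndarray) -> np.ndarray:
        """Round-trip (down + up) transmission exp(-2 k d)."""
        return np.exp(-2.0 * self.attenuation(wavelength_nm) * self.altitude_m)


@dataclass(frozen=True)
class PlateSpec:
    """Location and albedo of the embedded matte grey reference plate."""

    row0: int = 5
    col0: int = 5
    size_m: float = 0.10
    albedo: float = 0.35

    def __post_init__(self) -> None:
        if not (0 < self.albedo <= 1):
            raise ValueError("plate albedo must be in (0, 1]")

    def mask(self, shape: tuple[int, int], resolution_m: float) -> np.ndarray:
        size_px = max(1, int(round(self.size_m / resolution_m)))
        r1, c1 = self.row0 + size_px, self.col0 + size_px
        if self.row0 < 0 or self.col0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise ValueError("plate region outside map bounds")
        m = np.zeros(shape, dtype=bool)
        m[self.row0:r1, self.col0:c1] = True
        return m


def default_wavelengths(start: float = 400.0, stop: float = 750.0,
                        step: float = 2.9) -> np.ndarray:
    """Default spectral grid: ~2.9 nm spacing over 400-750 nm."""
    return np.arange(start, stop + 1e-9, step)


# ---------------------------------------------------------------------------
# Label map synthesis
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_px: float) -> np.ndarray:
    f = rng.standard_normal(shape)
    if sigma_px > 0:
        f = gaussian_filter(f, sigma=sigma_px, mode="wrap")
    return f


def _quota_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` pixels to fractions."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def sample_label_map(cfg: SceneConfig, scheme: CategoryScheme | None = None) -> LabelMap:
    """Draw a patchy label map whose group covers match ``cfg.target_cover``.

    One smoothed Gaussian field per group is thresholded at cover-matching
    quantiles: groups claim their exact pixel quota (largest-remainder
    rounding) from the still-unassigned pixels where their field is highest,
    in decreasing-quota order.  Realized covers are therefore exact up to
    pixel discretization.  Within each group, member fine categories are
    split along a second smoothed field so fine-scale patches stay coherent.

    Deterministic for a given config (the seed lives in ``cfg.seed``).
    """
    scheme = scheme or default_scheme()
    shape = cfg.shape
    n_px = shape[0] * shape[1]
    rng = np.random.default_rng(cfg.seed)
    sigma_px = cfg.patchiness_scale_m / cfg.pixel_size_m

    groups = [g for g in scheme.group_names if cfg.target_cover.get(g, 0.0) > 0]
    unknown = set(cfg.target_cover) - set(scheme.group_names)
    if unknown:
        raise ValueError(f"target_cover names unknown groups: {sorted(unknown)}")
    fracs = np.asarray([cfg.target_cover[g] for g in groups], dtype=float)
    fracs = fracs / fracs.sum()
    quotas = _quota_counts(fracs, n_px)

    # draw one field per group of the scheme (in scheme order) so that adding
    # or zeroing a target does not reshuffle other groups' fields
    fields = {g: _smooth_field(rng, shape, sigma_px).ravel()
              for g in scheme.group_names}
    fine_fields = {g: _smooth_field(rng, shape, sigma_px / 2 + 0.5).ravel()
                   for g in scheme.group_names}

    assign = np.full(n_px, -1, dtype=np.int16)
    order = np.argsort(-quotas, kind="stable")  # large groups claim first
    unassigned = np.ones(n_px, dtype=bool)
    for gi in order:
        g, quota = groups[gi], quotas[gi]
        if quota == 0:
            continue
        cand = np.flatnonzero(unassigned)
        take = cand[np.argsort(-fields[g][cand], kind="stable")[:quota]]
        # split the group's pixels among its fine categories by quantiles of
        # a per-group field, with random mixture weights
        members = scheme.fines_in_group(g)
        w = rng.dirichlet(np.full(len(members), 2.0)) if len(members) > 1 else [1.0]
        sub_quota = _quota_counts(np.asarray(w, dtype=float), quota)
        sub_order = np.argsort(-fine_fields[g][take], kind="stable")
        pos = 0
        for m_name, m_n in zip(members, sub_quota):
            idx = take[sub_order[pos:pos + m_n]]
            assign[idx] = scheme.fine_index(m_name)
            pos += m_n
        unassigned[take] = False

    assert (assign >= 0).all()
    return LabelMap(assign.reshape(shape), cfg.pixel_size_m, scheme)


# ---------------------------------------------------------------------------
# Endmember synthesis
# ---------------------------------------------------------------------------

# per-group spectral archetypes: (base level, slope across grid, troughs)
# troughs are (center_nm, depth, width_nm); chlorophyll-like dips near 440
# and 675 nm for photosynthetic groups, phycobilin dips near 495/565 nm for
# red algae, a flat bright baseline for bare substrate.
_GROUP_ARCHETYPES: dict[str, tuple[float, float, tuple[tuple[float, float, float], ...]]] = {
    "Acropora abrotanoides": (0.32, 0.10, ((440, 0.14, 28), (675, 0.12, 14))),
    "Scleractinia": (0.38, 0.06, ((440, 0.12, 30), (675, 0.10, 15))),
    "Green macroalgae": (0.30, 0.04, ((440, 0.16, 26), (675, 0.15, 13))),
    "Turf algae/Cyanobacteria/Bare substrate": (0.52, 0.02, ((675, 0.05, 18),)),
    "Corallinophycidae": (0.34, -0.04, ((495, 0.10, 24), (565, 0.11, 22))),
    "Porifera": (0.24, 0.12, ((600, 0.06, 40),)),
    "Peyssonneliales": (0.22, -0.02, ((495, 0.09, 22), (565, 0.10, 20), (675, 0.05, 14))),
    "Red macroalgae": (0.28, -0.06, ((495, 0.12, 22), (565, 0.13, 20))),
    "Octocorals/Hydrozoans": (0.30, 0.08, ((440, 0.08, 32),)),
    "Brown macroalgae": (0.26, 0.14, ((440, 0.13, 30), (630, 0.08, 26), (675, 0.09, 14))),
}


def _spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    cos = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return math.acos(min(1.0, max(-1.0, cos)))


def make_endmembers(
    scheme: CategoryScheme,
    wavelength_nm: np.ndarray | None = None,
    seed: int = 0,
    *,
    intra_class_sd: float = 0.02,
    min_separation_rad: float = 0.05,
    jitter: float = 0.03,
    separation: float = 1.0,
    max_retries: int = 20,
) -> EndmemberLibrary:
    """Synthesize one reflectance spectrum per fine category.

    Spectra are smooth baselines per group archetype plus Gaussian absorption
    troughs; fine categories within a group get small seeded perturbations of
    their group archetype.  ``separation`` is a contrast dial: archetypes are
    scaled away from (toward) their across-group mean for values above
    (below) 1, controlling how spectrally distinct the groups are.  The
    library is regenerated (new seed offset) until the minimum pairwise
    spectral angle between group-mean spectra reaches ``min_separation_rad``.

    Raises
    ------
    ValueError
        If the scheme is empty or separation is unattainable in ``max_retries``.
    """
    if scheme.n_fine == 0:
        raise ValueError("empty category scheme")
    wl = np.asarray(default_wavelengths() if wavelength_nm is None else wavelength_nm,
                    dtype=float)
    if wl.ndim != 1 or not (np.diff(wl) > 0).all():
        raise ValueError("wavelength grid must be strictly ascending")
    grid01 = (wl - wl[0]) / max(wl[-1] - wl[0], 1.0)

    archetypes: dict[str, np.ndarray] = {}
    for g in scheme.group_names:
        base, slope, troughs = _GROUP_ARCHETYPES.get(g, (0.3, 0.0, ()))
        arche = base + slope * grid01
        for c, depth, width in troughs:
            arche = arche - depth * np.exp(-0.5 * ((wl - c) / width) ** 2)
        archetypes[g] = arche
    if separation != 1.0:
        grand = np.mean(list(archetypes.values()), axis=0)
        archetypes = {g: np.clip(grand + separation * (a - grand), 0.01, 0.99)
                      for g, a in archetypes.items()}

    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + 1_000_003 * attempt)
        spectra: dict[str, np.ndarray] = {}
        for g in scheme.group_names:
            arche = archetypes[g]
            for name in scheme.fines_in_group(g):
                pert = gaussian_filter1d(rng.standard_normal(len(wl)), 8.0)
                pert = pert / (np.abs(pert).max() + 1e-12)
                s = arche * (1.0 + jitter * pert) + 0.01 * jitter * pert
                spectra[name] = np.clip(s, 0.005, 0.995)
        lib = EndmemberLibrary(
            wavelength_nm=wl,
            spectra=spectra,
            intra_class_sd={n: intra_class_sd for n in spectra},
            scheme=scheme,
        )
        gm = list(lib.group_means().values())
        angles = [_spectral_angle(gm[i], gm[j])
                  for i in range(len(gm)) for j in range(i + 1, len(gm))]
        if not angles or min(angles) >= min_separation_rad:
            return lib
    raise ValueError(
        f"could not reach min group-mean spectral angle {min_separation_rad} rad "
        f"after {max_retries} retries"
    )


# ---------------------------------------------------------------------------
# Scan rendering
# ---------------------------------------------------------------------------

def render_scan(
    label_map: LabelMap,
    lib: EndmemberLibrary,
    *,
    water: WaterModel | None = None,
    plate: PlateSpec | None = None,
    noise_sd: float = 0.005,
    seed: int = 0,
    illumination: np.ndarray | float = 1.0,
    samples: int | None = 680,
) -> SpectralCube:
    """Render a radiance cube from a label map and endmember library.

    radiance(px, lam) = E(lam) * exp(-2 k(lam) d) * R(px, lam) + noise, where
    R is the pixel's endmember times a smooth multiplicative intra-class
    perturbation; plate pixels use a flat spectral albedo.  ``samples``
    resamples the cross-track axis (nearest neighbour) to the sensor width
    (680 by default); pass ``None`` to keep the native map grid so cube and
    map coordinates coincide.
    """
    if label_map.level != "fine":
        raise ValueError("render_scan requires a fine-level ground-truth map")
    water = water or WaterModel()
    plate = plate or PlateSpec()
    wl = lib.wavelength_nm
    n_bands = len(wl)
    rng = np.random.default_rng(seed)

    grid = label_map.grid
    if samples is not None and samples != grid.shape[1]:
        # nearest-neighbour cross-track resampling to the sensor sample count
        src = np.floor((np.arange(samples) + 0.5) * grid.shape[1] / samples).astype(int)
        grid = grid[:, np.clip(src, 0, grid.shape[1] - 1)]
    shape = grid.shape

    plate_mask = plate.mask(shape, label_map.resolution_m)

    # per-category reflectance lookup (fine index -> spectrum)
    missing = [n for n in label_map.scheme.fine_names
               if n not in lib.spectra and (label_map.grid == label_map.scheme.fine_index(n)).any()]
    if missing:
        raise ValueError(f"library lacks spectra for scene categories: {missing}")
    table = np.zeros((label_map.scheme.n_fine, n_bands), dtype=np.float32)
    sd_table = np.zeros(label_map.scheme.n_fine, dtype=np.float32)
    for i, name in enumerate(label_map.scheme.fine_names):
        if name in lib.spectra:
            table[i] = lib.spectra[name]
            sd_table[i] = lib.intra_class_sd.get(name, 0.0)

    refl = table[grid]                          # (lines, samples, bands)
    # smooth multiplicative intra-class perturbation, per pixel and band
    sd = sd_table[grid][..., None]
    if float(np.max(sd_table)) > 0:
        eps = rng.standard_normal(refl.shape).astype(np.float32)
        eps = gaussian_filter1d(eps, sigma=5.0, axis=-1)
        eps /= max(float(eps.std()), 1e-12)
        refl = refl * (1.0 + sd * eps)
    refl[plate_mask] = plate.albedo
    refl = np.clip(refl, 0.0, None)

    illum = np.broadcast_to(np.asarray(illumination, dtype=np.float32), (n_bands,))
    trans = water.transmission(wl).astype(np.float32)
    signal = refl * (illum * trans)[None, None, :]
    if noise_sd > 0:
        signal = signal + noise_sd * rng.standard_normal(signal.shape).astype(np.float32)
    data = np.clip(signal, 0.0, None).astype(np.float32)
    return SpectralCube(data, wl.copy(), plate_mask, units="radiance")


# ---------------------------------------------------------------------------
# Survey-set simulation
# ---------------------------------------------------------------------------

@dataclass
class SurveySet:
    """Scenes, optional scans, and the ground-truth cover table of a survey set."""

    label_maps: dict[tuple[str, int], LabelMap]   # (survey, transect) -> map
    cubes: dict[tuple[str, int], SpectralCube]
    truth: pd.DataFrame                           # CoverTable rows, method "truth"
    scheme: CategoryScheme


def _perturb_targets(means: Mapping[str, float], sd: Mapping[str, float],
                     rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for g, m in means.items():
        v = rng.normal(m, sd.get(g, 0.0))
        out[g] = max(0.0, v)
    total = sum(out.values())
    if total <= 0:
        raise ValueError("all perturbed covers collapsed to zero")
    return {g: 100.0 * v / total for g, v in out.items()}


def simulate_survey_set(
    survey_targets: Mapping[str, Mapping[str, float]],
    n_transects: int = 5,
    seed: int = 0,
    *,
    scheme: CategoryScheme | None = None,
    between_transect_sd: Mapping[str, float] | float | None = None,
    transect_length_m: float = 50.0,
    swath_width_m: float = 1.0,
    pixel_size_m: float = 0.01,
    patchiness_scale_m: float = 0.5,
    lib: EndmemberLibrary | None = None,
    render: bool = False,
    noise_sd: float = 0.005,
    water: WaterModel | None = None,
    plate: PlateSpec | None = None,
    render_samples: int | None = None,
) -> SurveySet:
    """Simulate a multi-survey, multi-transect campaign with known truth.

    Per-transect cover targets are drawn around each survey's mean vector
    with ``between_transect_sd`` (a per-group mapping, a scalar in percent
    points, or ``None`` for the default of 10% of each group mean), then
    renormalized to 100.  Scans are rendered only when ``render=True``
    (statistics-only studies need just the label maps and truth table).

    Returns a :class:`SurveySet`; ``truth`` has one row per
    (survey, transect, group) with method ``"truth"``.
    """
    if n_transects < 2:
        raise ValueError("n_transects must be >= 2 (between-transect statistics "
                         "are undefined otherwise)")
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(seed)

    label_maps: dict[tuple[str, int], LabelMap] = {}
    cubes: dict[tuple[str, int], SpectralCube] = {}
    rows = []
    for survey, means in survey_targets.items():
        means = {g: float(v) for g, v in means.items() if float(v) > 0}
        if isinstance(between_transect_sd, Mapping):
            sd = {g: float(between_transect_sd.get(g, 0.0)) for g in means}
        elif between_transect_sd is None:
            sd = {g: 0.10 * m for g, m in means.items()}
        else:
            sd = {g: float(between_transect_sd) for g in means}
        for t in range(1, n_transects + 1):
            targets = _perturb_targets(means, sd, rng)
            cfg = SceneConfig(
                target_cover=targets,
                transect_length_m=transect_length_m,
                swath_width_m=swath_width_m,
                pixel_size_m=pixel_size_m,
                patchiness_scale_m=patchiness_scale_m,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            lm = sample_label_map(cfg, scheme)
            label_maps[(survey, t)] = lm
            if render:
                if lib is None:
                    raise ValueError("render=True requires an endmember library")
                cubes[(survey, t)] = render_scan(
                    lm, lib, water=water, plate=plate, noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)), samples=render_samples,
                )
            for g, pct in lm.cover().items():
                rows.append((survey, t, "truth", g, float(pct)))

    truth = pd.DataFrame(rows, columns=["survey", "transect", "method",
                                        "category", "cover_pct"])
    return SurveySet(label_maps, cubes, truth, scheme)
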