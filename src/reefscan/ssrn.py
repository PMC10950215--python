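"""Patch-based spectral-spatial residual network for per-pixel classification.

The classifier follows the spectral-spatial residual family: a patch around
each pixel is first projected along the band axis with 1x1 convolutions to a
reduced channel count, residual units then act along the spectral/feature
dimension, a feature-adjustment layer resizes the spectral features, further
residual units act spatially across the patch (3x3 convolutions), and the
head is average pooling over the window followed by a softmax layer.

Implemented directly on numpy (explicit forward, backpropagation, and Adam)
so training is lightweight, seeded, and dependency-free.  Class imbalance is
handled with inverse-frequency weights in the cross-entropy loss — the
minimal mitigation for the rare-category failure mode, where an
under-represented class leaks into the dominant background class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .annotate import AnnotationLibrary
from .categories import CategoryScheme
from .scene import PLATE_CODE, LabelMap, SpectralCube

__all__ = [
    "ModelConfig",
    "SSRN",
    "TrainedModel",
    "ValidationReport",
    "build_model",
    "train",
    "predict_map",
    "validation_report",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation hyperparameters.

    All sizes are deliberately modest defaults for CPU training and can be
    overridden freely: ``patch_size`` (odd, >= 3) sets the spatial window,
    ``reduced_channels`` the width after the 1x1 projection, and
    ``n_spectral_units``/``n_spatial_units`` the residual-unit counts.
    ``n_classes`` defaults to the 10 broad groups.
    """

    patch_size: int = 7
    reduced_channels: int = 32
    n_spectral_units: int = 2
    n_spatial_units: int = 2
    n_classes: int = 10
    learning_rate: float = 1e-3
    max_epochs: int = 60
    batch_size: int = 128
    early_stop_patience: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 3")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for name in ("reduced_channels", "n_spectral_units", "n_spatial_units",
                     "max_epochs", "batch_size", "early_stop_patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, p, p, C) -> (N, p, p, 9C) columns of the zero-padded 3x3 window."""
    n, p, _, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n, p, p, 9, c), dtype=x.dtype)
    idx = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, :, idx, :] = xp[:, di:di + p, dj:dj + p, :]
            idx += 1
    return cols.reshape(n, p, p, 9 * c)


def _col2im3(dcols: np.ndarray, p: int, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col3`: scatter column grads back to the input."""
    n = dcols.shape[0]
    dcols = dcols.reshape(n, p, p, 9, c)
    dxp = np.zeros((n, p + 2, p + 2, c), dtype=dcols.dtype)
    idx = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, di:di + p, dj:dj + p, :] += dcols[:, :, :, idx, :]
            idx += 1
    return dxp[:, 1:-1, 1:-1, :]


class SSRN:
    """The network: parameters, seeded init, forward pass and backprop."""

    def __init__(self, cfg: ModelConfig, n_bands: int):
        self.cfg = cfg
        self.n_bands = int(n_bands)
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(cfg.seed)
        c = cfg.reduced_channels

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float64)

        self.params["proj_W"] = he((n_bands, c), n_bands)
        self.params["proj_b"] = np.zeros(c)
        for i in range(cfg.n_spectral_units):
            self.params[f"spec{i}_W1"] = he((c, c), c)
            self.params[f"spec{i}_b1"] = np.zeros(c)
            self.params[f"spec{i}_W2"] = he((c, c), c)
            self.params[f"spec{i}_b2"] = np.zeros(c)
        self.params["adj_W"] = he((c, c), c)
        self.params["adj_b"] = np.zeros(c)
        for i in range(cfg.n_spatial_units):
            self.params[f"spat{i}_W"] = he((9 * c, c), 9 * c)
            self.params[f"spat{i}_b"] = np.zeros(c)
        # near-zero head so the initial softmax is ~uniform
        self.params["head_W"] = (rng.standard_normal((c, cfg.n_classes)) * 1e-3)
        self.params["head_b"] = np.zeros(cfg.n_classes)

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward ----------------------------------------------------------
    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """x: (N, patch, patch, bands) -> softmax probabilities (N, K)."""
        cfg, P = self.cfg, self.params
        cache: dict[str, np.ndarray] = {"x": x}
        h = x @ P["proj_W"] + P["proj_b"]
        for i in range(cfg.n_spectral_units):
            a = _relu(h)
            u = a @ P[f"spec{i}_W1"] + P[f"spec{i}_b1"]
            v = _relu(u)
            h2 = h + v @ P[f"spec{i}_W2"] + P[f"spec{i}_b2"]
            if keep_cache:
                cache[f"spec{i}_in"], cache[f"spec{i}_a"] = h, a
                cache[f"spec{i}_u"], cache[f"spec{i}_v"] = u, v
            h = h2
        if keep_cache:
            cache["adj_in"] = h
        h = h @ P["adj_W"] + P["adj_b"]
        for i in range(cfg.n_spatial_units):
            a = _relu(h)
            cols = _im2col3(a)
            h2 = h + cols @ P[f"spat{i}_W"] + P[f"spat{i}_b"]
            if keep_cache:
                cache[f"spat{i}_in"], cache[f"spat{i}_a"] = h, a
                cache[f"spat{i}_cols"] = cols
            h = h2
        pooled = h.mean(axis=(1, 2))
        logits = pooled @ P["head_W"] + P["head_b"]
        probs = _softmax(logits)
        if keep_cache:
            cache["pooled"], cache["pre_pool"] = pooled, h
            return probs, cache
        return probs

    # -- backward ---------------------------------------------------------
    def backward(self, probs: np.ndarray, y: np.ndarray, sample_w: np.ndarray,
                 cache: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Gradients of the weighted cross-entropy w.r.t. every parameter."""
        cfg, P = self.cfg, self.params
        n, p = probs.shape[0], cfg.patch_size
        grads: dict[str, np.ndarray] = {}
        wsum = sample_w.sum()
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (sample_w / wsum)[:, None]

        pooled = cache["pooled"]
        grads["head_W"] = pooled.T @ dlogits
        grads["head_b"] = dlogits.sum(axis=0)
        dpooled = dlogits @ P["head_W"].T
        dh = np.broadcast_to(dpooled[:, None, None, :] / (p * p),
                             cache["pre_pool"].shape).copy()

        for i in reversed(range(cfg.n_spatial_units)):
            cols, a = cache[f"spat{i}_cols"], cache[f"spat{i}_a"]
            c = a.shape[-1]
            grads[f"spat{i}_W"] = cols.reshape(-1, 9 * c).T @ dh.reshape(-1, c)
            grads[f"spat{i}_b"] = dh.sum(axis=(0, 1, 2))
            dcols = dh @ P[f"spat{i}_W"].T
            da = _col2im3(dcols, p, c)
            dh = dh + da * (a > 0)

        grads["adj_W"] = cache["adj_in"].reshape(-1, dh.shape[-1]).T @ dh.reshape(-1, dh.shape[-1])
        grads["adj_b"] = dh.sum(axis=(0, 1, 2))
        dh = dh @ P["adj_W"].T

        for i in reversed(range(cfg.n_spectral_units)):
            a, u, v = cache[f"spec{i}_a"], cache[f"spec{i}_u"], cache[f"spec{i}_v"]
            c = v.shape[-1]
            grads[f"spec{i}_W2"] = v.reshape(-1, c).T @ dh.reshape(-1, c)
            grads[f"spec{i}_b2"] = dh.sum(axis=(0, 1, 2))
            dv = dh @ P[f"spec{i}_W2"].T
            du = dv * (u > 0)
            grads[f"spec{i}_W1"] = a.reshape(-1, c).T @ du.reshape(-1, c)
            grads[f"spec{i}_b1"] = du.sum(axis=(0, 1, 2))
            da = du @ P[f"spec{i}_W1"].T
            dh = dh + da * (a > 0)

        x = cache["x"]
        grads["proj_W"] = x.reshape(-1, self.n_bands).T @ dh.reshape(-1, dh.shape[-1])
        grads["proj_b"] = dh.sum(axis=(0, 1, 2))
        return grads


def build_model(cfg: ModelConfig, n_bands: int) -> SSRN:
    """Construct an untrained network for ``n_bands`` input bands."""
    if n_bands < 1:
        raise ValueError("n_bands must be positive")
    return SSRN(cfg, n_bands)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A trained network plus everything needed to apply and audit it."""

    net: SSRN
    config: ModelConfig
    classes: tuple[str, ...]
    scheme: CategoryScheme
    band_fingerprint: tuple[float, ...]
    history: dict[str, list[float]] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: config, classes, fingerprint, weights."""
        meta = {
            "config": asdict(self.config),
            "classes": list(self.classes),
            "band_fingerprint": list(self.band_fingerprint),
            "history": self.history,
            "n_bands": self.net.n_bands,
            "scheme": self.scheme.to_frame().to_dict("records"),
        }
        np.savez(Path(path), __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.net.params)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        from .categories import build_category_scheme
        with np.load(Path(path)) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k: z[k] for k in z.files if k != "__meta__"}
        cfg = ModelConfig(**meta["config"])
        net = SSRN(cfg, meta["n_bands"])
        net.params = params
        scheme = build_category_scheme(
            [(r["fine"], r["group"]) for r in meta["scheme"]])
        return cls(net, cfg, tuple(meta["classes"]), scheme,
                   tuple(meta["band_fingerprint"]), meta["history"])


def _label_column(scheme: CategoryScheme, n_classes: int) -> tuple[str, tuple[str, ...]]:
    if n_classes == scheme.n_groups:
        return "group_label", scheme.group_names
    if n_classes == scheme.n_fine:
        return "fine_label", scheme.fine_names
    raise ValueError(
        f"n_classes={n_classes} matches neither group ({scheme.n_groups}) "
        f"nor fine ({scheme.n_fine}) resolution")


def _extract_patches(
    cubes: Mapping[str, SpectralCube],
    entries: pd.DataFrame,
    classes: Sequence[str],
    label_col: str,
    patch_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Gather reflect-padded patches and integer labels for library entries."""
    half = patch_size // 2
    cls_idx = {c: i for i, c in enumerate(classes)}
    xs, ys = [], []
    offs = np.arange(patch_size)
    for tid, grp in entries.groupby("transect_id", sort=True):
        cube = cubes[tid]
        padded = np.pad(cube.data, ((half, half), (half, half), (0, 0)),
                        mode="reflect")
        r = grp["row"].to_numpy(dtype=int)
        c = grp["col"].to_numpy(dtype=int)
        patches = padded[r[:, None, None] + offs[None, :, None],
                         c[:, None, None] + offs[None, None, :], :]
        xs.append(patches.astype(np.float64))
        ys.append(np.asarray([cls_idx[l] for l in grp[label_col]], dtype=int))
    return np.concatenate(xs), np.concatenate(ys)


def _check_fingerprints(cubes: Mapping[str, SpectralCube]) -> tuple[float, ...]:
    fps = {cube.band_fingerprint() for cube in cubes.values()}
    if len(fps) != 1:
        raise ValueError("cubes have inconsistent band sets")
    return next(iter(fps))


def train(
    model: SSRN,
    train_lib: AnnotationLibrary,
    val_lib: AnnotationLibrary,
    cubes: Mapping[str, SpectralCube],
    cfg: ModelConfig | None = None,
) -> TrainedModel:
    """Fit the network on the labeled library with Adam and early stopping.

    Minimizes inverse-frequency class-weighted cross-entropy; early-stops
    when validation accuracy has not improved for ``early_stop_patience``
    epochs (best weights are restored).  Deterministic for a given config
    seed and a fixed BLAS thread count.
    """
    cfg = cfg or model.cfg
    scheme = train_lib.scheme
    label_col, classes = _label_column(scheme, cfg.n_classes)
    fingerprint = _check_fingerprints(cubes)

    present = sorted(train_lib.entries[label_col].unique())
    if len(present) < 2:
        raise ValueError("training library must contain >= 2 classes")
    val_only = set(val_lib.entries[label_col].unique()) - set(present)
    if val_only:
        warnings.warn(
            f"classes present only in validation (scored as misses): {sorted(val_only)}",
            stacklevel=2)

    x_tr, y_tr = _extract_patches(cubes, train_lib.entries, classes,
                                  label_col, cfg.patch_size)
    if len(val_lib.entries):
        x_va, y_va = _extract_patches(cubes, val_lib.entries, classes,
                                      label_col, cfg.patch_size)
    else:
        x_va, y_va = x_tr[:0], y_tr[:0]

    counts = np.bincount(y_tr, minlength=cfg.n_classes).astype(float)
    with np.errstate(divide="ignore"):
        cls_w = np.where(counts > 0, counts.sum() / np.maximum(counts, 1), 0.0)
    cls_w = cls_w / cls_w[cls_w > 0].mean()

    rng = np.random.default_rng(cfg.seed + 1)
    m_adam = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_adam = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps_adam, step = 0.9, 0.999, 1e-8, 0

    history: dict[str, list[float]] = {"train_loss": [], "train_acc": [],
                                       "val_acc": []}
    best_acc, best_params, since_best = -1.0, None, 0

    def val_accuracy() -> float:
        if len(y_va) == 0:
            return float("nan")
        preds = []
        for i0 in range(0, len(y_va), 4096):
            preds.append(model.forward(x_va[i0:i0 + 4096]).argmax(axis=1))
        return float(np.mean(np.concatenate(preds) == y_va))

    n = len(y_tr)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses, hits, seen = [], 0, 0
        for i0 in range(0, n, cfg.batch_size):
            idx = order[i0:i0 + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            wb = cls_w[yb]
            probs, cache = model.forward(xb, keep_cache=True)
            p_true = np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
            losses.append(float((wb * -np.log(p_true)).sum() / wb.sum()))
            hits += int((probs.argmax(axis=1) == yb).sum())
            seen += len(yb)
            grads = model.backward(probs, yb, wb, cache)
            step += 1
            for k, g in grads.items():
                m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * g
                v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * g * g
                mh = m_adam[k] / (1 - beta1 ** step)
                vh = v_adam[k] / (1 - beta2 ** step)
                model.params[k] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps_adam)
        acc = val_accuracy()
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(hits / max(seen, 1))
        history["val_acc"].append(acc)
        monitor = acc if np.isfinite(acc) else history["train_acc"][-1]
        if monitor > best_acc + 1e-12:
            best_acc, since_best = monitor, 0
            best_params = {k: v.copy() for k, v in model.params.items()}
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    if best_params is not None:
        model.params = best_params

    return TrainedModel(model, cfg, tuple(classes), scheme, fingerprint, history)


# ---------------------------------------------------------------------------
# Prediction and validation
# ---------------------------------------------------------------------------

def predict_map(
    model: TrainedModel,
    cube: SpectralCube,
    batch_px: int = 8192,
) -> tuple[LabelMap, np.ndarray]:
    """Predict a label for every recorded pixel of a preprocessed cube.

    Returns the predicted label map (group level for the default 10-class
    configuration; plate pixels carry the reserved plate code and are
    excluded from cover) and the per-pixel softmax probability raster
    (lines x samples x n_classes).  Argmax ties break to the lowest class
    index.  Edge pixels use reflect-padding, so every pixel gets a label.
    """
    if cube.band_fingerprint() != model.band_fingerprint:
        raise ValueError("cube band set differs from the training fingerprint")
    cfg = model.config
    half = cfg.patch_size // 2
    lines, samples = cube.lines, cube.samples
    padded = np.pad(cube.data, ((half, half), (half, half), (0, 0)),
                    mode="reflect").astype(np.float64)
    windows = sliding_window_view(padded, (cfg.patch_size, cfg.patch_size),
                                  axis=(0, 1))   # (lines, samples, B, p, p)
    flat_probs = np.empty((lines * samples, cfg.n_classes), dtype=np.float32)
    rows_per_block = max(1, batch_px // samples)
    for i0 in range(0, lines, rows_per_block):
        i1 = min(lines, i0 + rows_per_block)
        block = windows[i0:i1].transpose(0, 1, 3, 4, 2)  # (.., p, p, B)
        x = np.ascontiguousarray(block).reshape(-1, cfg.patch_size,
                                                cfg.patch_size, cube.n_bands)
        flat_probs[i0 * samples:i1 * samples] = model.net.forward(x)
    probs = flat_probs.reshape(lines, samples, cfg.n_classes)
    labels = probs.argmax(axis=2).astype(np.int16)
    labels[cube.plate_mask] = PLATE_CODE
    level = "group" if cfg.n_classes == model.scheme.n_groups else "fine"
    lm = LabelMap(labels, resolution_m=1.0, scheme=model.scheme, level=level)
    return lm, probs


@dataclass
class ValidationReport:
    """Held-out validation outcome of a trained model.

    ``confusion`` rows are true classes, columns predicted; rows sum to the
    per-class validation counts.  ``per_class_match`` is the proportion of a
    class's validation entries predicted correctly (row-normalised diagonal,
    i.e. recall); classes with no validation entries are NaN (undefined, not
    zero).
    """

    classes: tuple[str, ...]
    confusion: np.ndarray
    per_class_match: dict[str, float]
    overall_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=list(self.classes),
                            columns=list(self.classes))


def validation_report(
    model: TrainedModel,
    val_lib: AnnotationLibrary,
    cubes: Mapping[str, SpectralCube],
) -> ValidationReport:
    """Confusion matrix and per-class match proportions on the validation set."""
    if not len(val_lib.entries):
        raise ValueError("validation library is empty")
    cfg = model.config
    label_col, classes = _label_column(val_lib.scheme, cfg.n_classes)
    x, y = _extract_patches(cubes, val_lib.entries, classes, label_col,
                            cfg.patch_size)
    preds = []
    for i0 in range(0, len(y), 4096):
        preds.append(model.net.forward(x[i0:i0 + 4096]).argmax(axis=1))
    pred = np.concatenate(preds)
    k = cfg.n_classes
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y, pred), 1)
    row = confusion.sum(axis=1)
    match = {
        cls: (confusion[i, i] / row[i]) if row[i] else float("nan")
        for i, cls in enumerate(classes)
    }
    overall = float((pred == y).mean())
    return ValidationReport(tuple(classes), confusion, match, overall)
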