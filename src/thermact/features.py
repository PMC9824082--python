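"""Feature extraction from 40x64 spatiotemporal maps.

Four representations are provided:

* **SVD subspace** — maps flattened to 2560-vectors, mean-centered, projected
  onto the top-k right singular vectors of the training matrix (default
  k=45, which on the reference data explains >95% of variance).
* **Fisher canonical variables** — supervised projection maximizing
  between-class over within-class scatter; at most Q-1 components for Q
  classes.  With ~22 samples per class against 2560 variables the
  within-class scatter is singular, so it is ridge-regularized.
* **Block 2D DCT** — the map tiled into forty 8x8 patches; per patch the
  first six zigzag coefficients of an orthonormal type-II DCT, giving 240
  features.
* **GLCM texture** — five 8x64 time-patches; per patch a symmetric normalized
  gray-level co-occurrence matrix at distances {1, 3} and angles
  {0, 45, 90} degrees, summarized by correlation, contrast, dissimilarity
  and energy: 5*2*3*4 = 120 features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.linalg
from skimage.feature import graycomatrix, graycoprops

from .preprocess import MAP_SHAPE, DatasetTensor, SpatioTemporalMap

D_FULL = MAP_SHAPE[0] * MAP_SHAPE[1]  # 2560
DCT_N_FEATURES = 240
GLCM_N_FEATURES = 120

GLCM_DISTANCES = (1, 3)
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2)  # 0 deg = pixel axis, 90 deg = time axis
GLCM_STATS = ("correlation", "contrast", "dissimilarity", "energy")


@dataclass
class FeatureMatrix:
    """Z x D feature array with aligned labels and extractor provenance."""

    X: np.ndarray
    labels: np.ndarray
    extractor: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or len(self.X) != len(self.labels):
            raise ValueError("X must be (Z, D) aligned with labels")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain non-finite values")


@dataclass
class SubspaceModel:
    """A fitted linear projection (SVD or Fisher)."""

    basis: np.ndarray  # (2560, k) columns are projection directions
    mean: np.ndarray  # (2560,) training mean used for centering
    kind: str  # "svd" | "fisher"
    explained_variance_ratio: np.ndarray | None = None  # svd only
    eigenvalues: np.ndarray | None = None  # fisher only
    ridge: float | None = None  # fisher only

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]


def svd_fit(train: DatasetTensor, k: int = 45) -> SubspaceModel:
    """Fit the top-k SVD subspace of the mean-centered training maps."""
    X = train.vectors()
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(Z, D)={min(X.shape)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: right singular vectors are the principal directions
    _, s, Vt = scipy.linalg.svd(Xc, full_matrices=False)
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return SubspaceModel(
        basis=Vt[:k].T, mean=mean, kind="svd", explained_variance_ratio=evr[:k]
    )


def svd_transform(model: SubspaceModel, data: DatasetTensor) -> FeatureMatrix:
    """Project maps onto the fitted subspace (centered with the training mean)."""
    if model.kind != "svd":
        raise ValueError("model is not an SVD subspace")
    X = data.vectors()
    if X.shape[1] != model.basis.shape[0]:
        raise ValueError("feature dimension mismatch")
    return FeatureMatrix(
        (X - model.mean) @ model.basis, data.labels, "svd",
        {"k": model.n_components},
    )


def fisher_fit(train: DatasetTensor, ridge: float = 1e-3) -> SubspaceModel:
    """Fit Fisher canonical variables with ridge-regularized within-class scatter.

    Solves the generalized eigenproblem ``Sb w = lambda (Sw + r I) w`` where
    ``r = ridge * trace(Sw) / D``, and keeps the top Q-1 eigenvectors.
    """
    X = train.vectors()
    y = train.labels
    classes, y_idx = np.unique(y, return_inverse=True)
    Q = len(classes)
    if Q < 2:
        raise ValueError("Fisher projection needs at least 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("Fisher projection needs at least 2 samples per class")
    mean = X.mean(axis=0)
    D = X.shape[1]
    class_means = np.stack([X[y_idx == c].mean(axis=0) for c in range(Q)])
    Xw = X - class_means[y_idx]
    Sw = Xw.T @ Xw
    r = ridge * np.trace(Sw) / D
    if r <= 0:  # degenerate all-duplicate data; keep the problem well posed
        r = ridge
    Sw_flat = Sw.ravel()
    Sw_flat[:: D + 1] += r  # add ridge to the diagonal in place
    # Sb = B^T B with B = sqrt(counts) * (class_means - mean) has rank <= Q-1,
    # so the generalized problem Sb w = lambda (Sw + rI) w reduces to the
    # Q x Q symmetric problem C = B Sw_reg^-1 B^T: nonzero eigenvalues agree
    # and eigenvectors are w = Sw_reg^-1 B^T u (normalized to w' Sw_reg w = 1)
    B = np.sqrt(counts)[:, None] * (class_means - mean)
    cho = scipy.linalg.cho_factor(Sw, lower=True, overwrite_a=True)
    A = scipy.linalg.cho_solve(cho, B.T)  # (D, Q)
    C = B @ A
    evals, U = scipy.linalg.eigh(C)
    order = np.argsort(evals)[::-1][: Q - 1]
    evals = evals[order]
    W = A @ U[:, order]
    scale = np.where(evals > 1e-12, np.sqrt(np.abs(evals)), np.linalg.norm(W, axis=0))
    W = W / np.where(scale > 0, scale, 1.0)
    return SubspaceModel(
        basis=W, mean=mean, kind="fisher", eigenvalues=evals, ridge=float(r),
    )


def fisher_transform(model: SubspaceModel, data: DatasetTensor) -> FeatureMatrix:
    if model.kind != "fisher":
        raise ValueError("model is not a Fisher projection")
    X = data.vectors()
    if X.shape[1] != model.basis.shape[0]:
        raise ValueError("feature dimension mismatch")
    return FeatureMatrix(
        (X - model.mean) @ model.basis, data.labels, "fisher",
        {"n_components": model.n_components},
    )


_ZIGZAG_8 = None


def _zigzag_order(n: int = 8) -> np.ndarray:
    """Standard JPEG zigzag scan order over an n x n block (DC first)."""
    global _ZIGZAG_8
    if n == 8 and _ZIGZAG_8 is not None:
        return _ZIGZAG_8
    # odd anti-diagonals are walked with ascending row, even ones descending
    idx = sorted(
        ((r, c) for r in range(n) for c in range(n)),
        key=lambda rc: (rc[0] + rc[1], rc[0] if (rc[0] + rc[1]) % 2 else -rc[0]),
    )
    out = np.array(idx)
    if n == 8:
        _ZIGZAG_8 = out
    return out


def dct_features(stmap: SpatioTemporalMap | np.ndarray) -> np.ndarray:
    """First six zigzag coefficients of the orthonormal 2D DCT of each 8x8 patch.

    The 40x64 map is tiled into 5x8 non-overlapping 8x8 patches in row-major
    patch order; six coefficients per patch give a 240-vector.
    """
    values = stmap.values if isinstance(stmap, SpatioTemporalMap) else np.asarray(stmap, float)
    if values.shape != MAP_SHAPE:
        raise ValueError(f"expected a {MAP_SHAPE} map")
    zz = _zigzag_order(8)[:6]
    feats = []
    for pr in range(5):
        for pc in range(8):
            patch = values[pr * 8 : (pr + 1) * 8, pc * 8 : (pc + 1) * 8]
            C = scipy.fft.dctn(patch, norm="ortho")
            feats.append(C[zz[:, 0], zz[:, 1]])
    return np.concatenate(feats)


def _quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Per-map min-max quantization to integer gray levels 0..levels-1."""
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return np.zeros_like(values, dtype=np.uint8)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_features(stmap: SpatioTemporalMap | np.ndarray, levels: int = 8) -> np.ndarray:
    """GLCM texture statistics of five 8x64 time-patches (120 features).

    The map is quantized per map (min-max) to ``levels`` gray levels.  For
    each patch, symmetric normalized co-occurrence matrices at distances
    {1, 3} and angles {0, 45, 90} degrees yield correlation, contrast,
    dissimilarity and energy, concatenated in (patch, distance, angle,
    statistic) order.  A constant map has a single co-occurrence cell;
    correlation is then 0 by convention.
    """
    values = stmap.values if isinstance(stmap, SpatioTemporalMap) else np.asarray(stmap, float)
    if values.shape != MAP_SHAPE:
        raise ValueError(f"expected a {MAP_SHAPE} map")
    q = _quantize(values, levels)
    feats = []
    for p in range(5):
        patch = q[p * 8 : (p + 1) * 8, :]
        glcm = graycomatrix(
            patch, distances=GLCM_DISTANCES, angles=GLCM_ANGLES,
            levels=levels, symmetric=True, normed=True,
        )
        props = {stat: graycoprops(glcm, stat) for stat in GLCM_STATS}
        # zero-variance patch: a single gray level; define correlation as 0
        flat = patch.ravel()
        if np.all(flat == flat[0]):
            props["correlation"] = np.zeros_like(props["correlation"])
        for d in range(len(GLCM_DISTANCES)):
            for a in range(len(GLCM_ANGLES)):
                for stat in GLCM_STATS:
                    feats.append(props[stat][d, a])
    return np.array(feats)


def extract_features(data: DatasetTensor, extractor: str,
                     model: SubspaceModel | None = None, **kw) -> FeatureMatrix:
    """Uniform entry point: 'svd' | 'fisher' | 'dct' | 'glcm'.

    Subspace extractors require a fitted ``model``; per-map extractors
    (dct/glcm) are stateless.
    """
    if extractor == "svd":
        if model is None:
            raise ValueError("svd extraction requires a fitted model")
        return svd_transform(model, data)
    if extractor == "fisher":
        if model is None:
            raise ValueError("fisher extraction requires a fitted model")
        return fisher_transform(model, data)
    if extractor == "dct":
        X = np.stack([dct_features(m) for m in data.maps])
        return FeatureMatrix(X, data.labels, "dct")
    if extractor == "glcm":
        X = np.stack([glcm_features(m, **kw) for m in data.maps])
        return FeatureMatrix(X, data.labels, "glcm")
    raise ValueError(f"unknown extractor {extractor!r}")


def fit_extractor(train: DatasetTensor, extractor: str, **kw) -> SubspaceModel | None:
    """Fit the trainable extractors; returns None for the stateless ones."""
    if extractor == "svd":
        return svd_fit(train, **kw)
    if extractor == "fisher":
        return fisher_fit(train, **kw)
    if extractor in ("dct", "glcm"):
        return None
    raise ValueError(f"unknown extractor {extractor!r}")
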