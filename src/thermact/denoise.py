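"""Supervised removal of periodic stripe noise from 40x64 spatiotemporal maps.

Low-resolution thermal maps built by stacking vectorized frames show periodic
noise: *vertical* stripes from pixels that never change across the 40 frames,
and *horizontal* stripes from near-identical consecutive frames.  In the
centered 2D DFT power spectrum this noise concentrates as symmetric peak
pairs on the two central stripes through DC (row 20 and column 32 of the
shifted 40x64 spectrum): peaks on the **horizontal stripe** encode vertical
stripe noise and peaks on the **vertical stripe** encode horizontal stripe
noise.

Denoising one map:

1. ``F = fftshift(fft2(X))`` and the log power spectrum ``P = log(1 + |F|)``.
2. Per-stripe statistics ``mu, sigma`` over the non-DC stripe cells give a
   per-map threshold ``T = mu + i1 * 0.5 * sigma`` for an integer ``i1``.
3. Symmetric pairs with log-power above ``T`` are candidate noise peaks; the
   ``num`` largest are rescaled (phase preserved, both mirror members) so
   their log-power equals the stripe mean ``mu``.
4. Both stripes are suppressed (they share no cells) and the spectrum is
   inverted into the denoised map.  A literal variant that averages two
   one-stripe inversions is available but amounts to half-strength
   suppression; see :func:`suppress_and_invert`.

The two global parameters per stripe, ``i1`` and ``num``, are learned by
K-fold cross-validation against a downstream classifier (by default logistic
regression on an SVD subspace), maximizing mean validation accuracy over a
candidate grid; thresholds always remain per-map statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .preprocess import MAP_SHAPE, DatasetTensor, SpatioTemporalMap

DC_ROW, DC_COL = 20, 32  # center of the shifted 40x64 spectrum
N_PAIRS_H = 31  # symmetric pairs on the horizontal stripe (row 20)
N_PAIRS_V = 19  # symmetric pairs on the vertical stripe (column 32)

Scorer = Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], tuple[float, float]]


@dataclass
class Spectrum:
    """Centered complex spectrum of a real 40x64 map (DC at row 20, col 32)."""

    F: np.ndarray  # (40, 64) complex
    source: np.ndarray  # (40, 64) float, the map it came from


@dataclass(frozen=True)
class StripeStats:
    """Mean/std of log power over each central stripe, DC excluded."""

    mu_h: float
    sigma_h: float
    mu_v: float
    sigma_v: float


@dataclass(frozen=True)
class PeakPair:
    """A mirror-symmetric pair of stripe cells with its mean log power."""

    cells: tuple[tuple[int, int], tuple[int, int]]
    value: float
    offset: int  # distance from DC in frequency bins


@dataclass
class NoiseParams:
    """Learned denoiser parameters.

    ``i1_h``/``num_h`` govern the horizontal stripe (vertical noise),
    ``i1_v``/``num_v`` the vertical stripe (horizontal noise).  Thresholds
    are always recomputed per map from its own stripe statistics;
    ``threshold_h``/``threshold_v`` record the training-set mean thresholds
    for reporting only.
    """

    i1_h: int
    num_h: int
    i1_v: int
    num_v: int
    threshold_h: float = float("nan")
    threshold_v: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in
             ("i1_h", "num_h", "i1_v", "num_v", "threshold_h", "threshold_v")}
        d["provenance"] = self.provenance
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NoiseParams":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class PerformanceTensor:
    """CV accuracy tensors of one stripe's parameter search.

    ``validation``/``training`` have shape (K, len(i1_grid), len(num_cand));
    infeasible or unevaluated cells hold NaN and are excluded from fold
    averages.
    """

    validation: np.ndarray
    training: np.ndarray
    i1_grid: np.ndarray
    num_cand: np.ndarray
    direction: str

    def mean_validation(self) -> np.ndarray:
        """Fold-averaged validation accuracy (NaN where no fold was feasible)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.validation, axis=0)


def dft2(stmap: SpatioTemporalMap | np.ndarray) -> Spectrum:
    """Centered 2D DFT of a map; DC lands at (20, 32) and equals the map sum."""
    X = stmap.values if isinstance(stmap, SpatioTemporalMap) else np.asarray(stmap, float)
    if X.shape != MAP_SHAPE:
        raise ValueError(f"expected a {MAP_SHAPE} map, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("map contains non-finite values")
    return Spectrum(np.fft.fftshift(np.fft.fft2(X)), X)


def idft2(spec: Spectrum | np.ndarray) -> np.ndarray:
    """Inverse of :func:`dft2`; guards that the result is numerically real."""
    F = spec.F if isinstance(spec, Spectrum) else np.asarray(spec)
    x = np.fft.ifft2(np.fft.ifftshift(F))
    scale = max(np.abs(x).max(), 1.0)
    if np.abs(x.imag).max() > 1e-8 * scale:
        raise ValueError("inverse transform is not real; spectrum lost Hermitian symmetry")
    return x.real


def power_spectrum(spec: Spectrum) -> np.ndarray:
    """Log power ``log(1 + |F|)`` (log1p avoids -inf at exact zeros)."""
    return np.log1p(np.abs(spec.F))


def stripe_stats(P: np.ndarray) -> StripeStats:
    """Mean/std over the central horizontal (row 20) and vertical (col 32)
    stripes, excluding the DC cell from all four statistics."""
    if P.shape != MAP_SHAPE:
        raise ValueError(f"expected {MAP_SHAPE} power spectrum")
    h = np.delete(P[DC_ROW, :], DC_COL)  # 63 cells
    v = np.delete(P[:, DC_COL], DC_ROW)  # 39 cells
    return StripeStats(float(h.mean()), float(h.std()), float(v.mean()), float(v.std()))


def _pair_cells(direction: str) -> list[tuple[tuple[int, int], tuple[int, int], int]]:
    """Mirror cell pairs on one stripe: (cell, mirror cell, offset from DC).

    The self-conjugate Nyquist cell (index 0 of the stripe) and DC are never
    part of a pair.
    """
    if direction == "horizontal":
        return [((DC_ROW, DC_COL + d), (DC_ROW, DC_COL - d), d) for d in range(1, N_PAIRS_H + 1)]
    if direction == "vertical":
        return [((DC_ROW + d, DC_COL), (DC_ROW - d, DC_COL), d) for d in range(1, N_PAIRS_V + 1)]
    raise ValueError("direction must be 'horizontal' or 'vertical'")


def _all_pairs_sorted(P: np.ndarray, direction: str) -> list[PeakPair]:
    pairs = [
        PeakPair((a, b), float(0.5 * (P[a] + P[b])), d)
        for a, b, d in _pair_cells(direction)
    ]
    pairs.sort(key=lambda p: (-p.value, p.offset))
    return pairs


def find_peak_pairs(P: np.ndarray, direction: str, T: float) -> list[PeakPair]:
    """Symmetric stripe pairs whose mean log power exceeds ``T``.

    Sorted by value descending; ties broken toward the pair nearer DC.
    """
    if not np.isfinite(T):
        raise ValueError("threshold must be finite")
    return [p for p in _all_pairs_sorted(P, direction) if p.value > T]


def _suppress(F: np.ndarray, pairs: Sequence[PeakPair], num: int, mu: float) -> np.ndarray:
    """Copy of ``F`` with the top ``num`` pairs rescaled to log power ``mu``.

    The complex coefficient keeps its phase; the target magnitude is
    ``expm1(mu)``, the inverse of the log1p power mapping.  Both mirror
    members are rescaled so Hermitian symmetry is preserved.
    """
    out = F.copy()
    target = np.expm1(mu)
    for p in pairs[:num]:
        for cell in p.cells:
            mag = np.abs(out[cell])
            out[cell] = target * (out[cell] / mag) if mag > 0 else target
    return out


def suppress_and_invert(
    spec: Spectrum,
    pairs_h: Sequence[PeakPair],
    pairs_v: Sequence[PeakPair],
    stats: StripeStats,
    num_h_stripe: int,
    num_v_stripe: int,
    merge: str = "joint",
) -> np.ndarray:
    """Suppress the top peak pairs on each stripe and invert.

    ``num_h_stripe`` pairs on the horizontal stripe remove vertical noise,
    ``num_v_stripe`` pairs on the vertical stripe remove horizontal noise.
    The stripes share no cells, so with ``merge="joint"`` (default) both
    suppressions are applied to one spectrum and inverted once — full-
    strength removal in both directions.  ``merge="average"`` instead
    inverts two one-stripe spectra and averages the maps; because the
    untouched arm still carries each peak, averaging is exactly
    half-strength suppression (the averaged spectrum holds
    ``(suppressed + original) / 2`` at every modified cell), retaining 25%
    of the noise energy.  The joint merge is therefore the default.
    """
    if num_h_stripe > len(pairs_h) or num_v_stripe > len(pairs_v):
        raise ValueError("suppression count exceeds available peak pairs")
    if merge == "average":
        Xh = idft2(_suppress(spec.F, pairs_h, num_h_stripe, stats.mu_h))
        Xv = idft2(_suppress(spec.F, pairs_v, num_v_stripe, stats.mu_v))
        return 0.5 * (Xh + Xv)
    if merge != "joint":
        raise ValueError("merge must be 'joint' or 'average'")
    F = _suppress(spec.F, pairs_h, num_h_stripe, stats.mu_h)
    F = _suppress(F, pairs_v, num_v_stripe, stats.mu_v)
    return idft2(F)


def denoise_map(values: np.ndarray, params: NoiseParams) -> np.ndarray:
    """Denoise one map with learned global (i1, num) but per-map thresholds.

    Counts are clamped per map to the number of pairs actually above its
    thresholds.
    """
    spec = dft2(values)
    P = power_spectrum(spec)
    st = stripe_stats(P)
    Th = st.mu_h + params.i1_h * 0.5 * st.sigma_h
    Tv = st.mu_v + params.i1_v * 0.5 * st.sigma_v
    pairs_h = find_peak_pairs(P, "horizontal", Th)
    pairs_v = find_peak_pairs(P, "vertical", Tv)
    return suppress_and_invert(
        spec, pairs_h, pairs_v, st,
        min(params.num_h, len(pairs_h)), min(params.num_v, len(pairs_v)),
    )


def suppressed_offsets(values: np.ndarray, params: NoiseParams) -> dict[str, list[int]]:
    """Frequency offsets (bins from DC) a fitted denoiser suppresses on one map."""
    spec = dft2(values)
    P = power_spectrum(spec)
    st = stripe_stats(P)
    out = {}
    for direction, i1, num, mu, sigma in (
        ("horizontal", params.i1_h, params.num_h, st.mu_h, st.sigma_h),
        ("vertical", params.i1_v, params.num_v, st.mu_v, st.sigma_v),
    ):
        pairs = find_peak_pairs(P, direction, mu + i1 * 0.5 * sigma)
        out[direction] = [p.offset for p in pairs[: min(num, len(pairs))]]
    return out


def denoise_dataset(data: DatasetTensor, params: NoiseParams) -> DatasetTensor:
    """Apply a fitted denoiser to every map of a dataset."""
    out = np.stack([denoise_map(m, params) for m in data.maps])
    return data.replace_maps(out)


def default_scorer(seed: int = 0, k: int = 45, max_iter: int = 200) -> Scorer:
    """Downstream scorer for the parameter search: LR on an SVD subspace.

    Mirrors the pipeline the search is meant to serve (SVD features +
    logistic regression); ``k`` is capped by the training-fold size.
    """
    from sklearn.decomposition import PCA
    from sklearn.linear_model import LogisticRegression

    def score(Xtr: np.ndarray, ytr: np.ndarray, Xv: np.ndarray, yv: np.ndarray
              ) -> tuple[float, float]:
        kk = min(k, Xtr.shape[0] - 1, Xtr.shape[1])
        pca = PCA(n_components=kk, svd_solver="randomized", random_state=seed)
        Ztr = pca.fit_transform(Xtr)
        Zv = pca.transform(Xv)
        clf = LogisticRegression(max_iter=max_iter, random_state=seed)
        clf.fit(Ztr, ytr)
        return float(clf.score(Ztr, ytr)), float(clf.score(Zv, yv))

    return score


def _direction_search(
    maps: np.ndarray,
    labels: np.ndarray,
    direction: str,
    scorer: Scorer,
    K: int,
    i1_grid: np.ndarray,
    num_cand: np.ndarray,
    seed: int,
) -> tuple[int, int, float, PerformanceTensor]:
    """Grid-search (i1, num) for one stripe by K-fold CV.

    Per map everything reusable is precomputed once: stripe statistics,
    pairs sorted by descending value, and the cumulative single-stripe
    denoised maps after suppressing the top k pairs (k = 0..max num).  A
    cell (i1, num) then only assembles precomputed maps and runs the scorer.
    """
    Z = len(maps)
    max_num = int(num_cand.max())
    mus = np.empty(Z)
    sigmas = np.empty(Z)
    pair_values = []  # per map, descending
    cum = np.empty((Z, max_num + 1, maps[0].size), dtype=np.float32)
    for j, m in enumerate(maps):
        spec = dft2(m)
        P = power_spectrum(spec)
        st = stripe_stats(P)
        mu, sigma = (st.mu_h, st.sigma_h) if direction == "horizontal" else (st.mu_v, st.sigma_v)
        mus[j], sigmas[j] = mu, sigma
        pairs = _all_pairs_sorted(P, direction)
        pair_values.append(np.array([p.value for p in pairs]))
        F = spec.F.copy()
        cum[j, 0] = m.ravel()
        for k in range(1, max_num + 1):
            if k <= len(pairs):
                F = _suppress(F, pairs[k - 1 : k], 1, mu)
                cum[j, k] = idft2(F).ravel()
            else:
                cum[j, k] = cum[j, k - 1]

    # pairs above threshold form a prefix of the descending-sorted list
    avail = np.empty((len(i1_grid), Z), dtype=int)
    for a, i1 in enumerate(i1_grid):
        for j in range(Z):
            T = mus[j] + i1 * 0.5 * sigmas[j]
            avail[a, j] = int(np.sum(pair_values[j] > T))

    val = np.full((K, len(i1_grid), len(num_cand)), np.nan)
    tra = np.full_like(val, np.nan)
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    for k_fold, (tr_idx, va_idx) in enumerate(skf.split(np.zeros(Z), labels)):
        for a in range(len(i1_grid)):
            for b, num in enumerate(num_cand):
                if avail[a, tr_idx].max(initial=0) < num:
                    continue  # infeasible: no training map offers that many pairs
                k_tr = np.minimum(num, avail[a, tr_idx])
                k_va = np.minimum(num, avail[a, va_idx])
                Xtr = cum[tr_idx, k_tr]
                Xva = cum[va_idx, k_va]
                tr_acc, va_acc = scorer(Xtr, labels[tr_idx], Xva, labels[va_idx])
                tra[k_fold, a, b] = tr_acc
                val[k_fold, a, b] = va_acc

    perf = PerformanceTensor(val, tra, np.asarray(i1_grid), np.asarray(num_cand), direction)
    mean_val = perf.mean_validation()
    if np.all(np.isnan(mean_val)):
        raise RuntimeError(
            f"no feasible (i1, num) combination on the {direction} stripe; widen the i1 grid"
        )
    flat = np.where(np.isnan(mean_val), -np.inf, mean_val)
    a_best, b_best = np.unravel_index(np.argmax(flat), flat.shape)
    i1_best = int(i1_grid[a_best])
    mean_thresh = float(np.mean(mus + i1_best * 0.5 * sigmas))
    return i1_best, int(num_cand[b_best]), mean_thresh, perf


def fit_noise_params(
    train: DatasetTensor,
    scorer: Scorer | None = None,
    K: int = 10,
    i1_grid: Sequence[int] = range(-2, 9),
    num_cand_h: Sequence[int] | None = None,
    num_cand_v: Sequence[int] | None = None,
    seed: int = 0,
) -> tuple[NoiseParams, dict[str, PerformanceTensor]]:
    """Learn (i1, num) for both stripes by CV against downstream accuracy.

    Defaults follow the supervised search as published: K=10 folds, i1 in
    -2..8, and num candidates spanning all pair counts (1..31 horizontal,
    1..19 vertical).  Smaller K / coarser candidate sets trade fidelity for
    speed and are exposed for desk-scale runs.  Deterministic given ``seed``
    (fold assignment and scorer).
    """
    if scorer is None:
        scorer = default_scorer(seed=seed)
    i1_grid = np.asarray(list(i1_grid), dtype=int)
    num_h = np.asarray(list(num_cand_h) if num_cand_h is not None else range(1, N_PAIRS_H + 1))
    num_v = np.asarray(list(num_cand_v) if num_cand_v is not None else range(1, N_PAIRS_V + 1))
    _, counts = np.unique(train.labels, return_counts=True)
    if counts.min() < K:
        raise ValueError(
            f"need at least K={K} samples per class for stratified folds "
            f"(smallest class has {counts.min()}); reduce K"
        )
    X = train.maps
    y = train.labels
    i1_h, nh, th, perf_h = _direction_search(X, y, "horizontal", scorer, K, i1_grid, num_h, seed)
    i1_v, nv, tv, perf_v = _direction_search(X, y, "vertical", scorer, K, i1_grid, num_v, seed)
    params = NoiseParams(
        i1_h=i1_h, num_h=nh, i1_v=i1_v, num_v=nv,
        threshold_h=th, threshold_v=tv,
        provenance={
            "K": int(K),
            "i1_grid": [int(v) for v in i1_grid],
            "num_cand_h": [int(v) for v in num_h],
            "num_cand_v": [int(v) for v in num_v],
            "seed": int(seed),
            "n_train": int(len(train)),
        },
    )
    return params, {"horizontal": perf_h, "vertical": perf_v}
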