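"""Spherical-searchlight stimulus-encoding analysis.

For every sphere of voxels on a scattered center lattice, a ridge
regression maps reduced stimulus feature vectors to multivoxel response
patterns; held-out patterns are scored by the correlation-error probability
(1 - p of the prediction/observation correlation across the sphere's
voxels), averaged over the cross-validation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .glm import BetaPatterns, zscore_within_fold
from .music_features import fit_reduce

__all__ = [
    "Searchlight",
    "EncodingScore",
    "SearchlightMap",
    "sphere_offsets",
    "enumerate_spheres",
    "fit_predict_ridge",
    "correlation_error_probability",
    "run_searchlight",
    "fill_scattered",
]


@dataclass
class Searchlight:
    """One sphere: its center and the flat indices of its member voxels."""

    center: tuple
    member_voxels: np.ndarray  # flat (C-order) indices into the volume
    radius: int = 3

    def __post_init__(self) -> None:
        self.member_voxels = np.asarray(self.member_voxels, dtype=int)


@dataclass
class EncodingScore:
    center: tuple
    accuracy: float
    n_tests: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class SearchlightMap:
    """Per-voxel accuracy volume; NaN where no sphere was centered."""

    volume: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    radius: int = 3
    scatter_step: int = 3
    scatter_offset: tuple = (0, 0, 0)
    n_tests: int = 0

    def computed_voxels(self) -> np.ndarray:
        return np.isfinite(self.volume) & self.mask


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer (dx, dy, dz) offsets with squared Euclidean norm <= radius^2."""
    r = int(radius)
    g = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(g, g, g, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r * r
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def enumerate_spheres(
    mask: np.ndarray,
    radius: int = 3,
    scatter_step: int = 3,
    rng_seed: int = 0,
    scatter_offset: tuple = None,
) -> list:
    """Spheres centered on a scattered lattice of in-mask voxels.

    Centers lie on a lattice of spacing ``scatter_step`` with a uniformly
    random offset in ``{0..step-1}^3`` (drawn from ``rng_seed`` unless
    ``scatter_offset`` is given explicitly); members are in-mask voxels
    within Euclidean voxel distance ``radius`` of the center.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if scatter_offset is None:
        rng = np.random.default_rng(rng_seed)
        scatter_offset = tuple(rng.integers(0, scatter_step, size=3))
    offsets = sphere_offsets(radius)
    shape = mask.shape
    flat_strides = np.array([shape[1] * shape[2], shape[2], 1])
    spheres = []
    axes = [np.arange(scatter_offset[d], shape[d], scatter_step) for d in range(3)]
    for cx in axes[0]:
        for cy in axes[1]:
            for cz in axes[2]:
                if not mask[cx, cy, cz]:
                    continue
                pts = offsets + (cx, cy, cz)
                ok = ((pts >= 0) & (pts < shape)).all(axis=1)
                pts = pts[ok]
                inmask = mask[pts[:, 0], pts[:, 1], pts[:, 2]]
                members = pts[inmask] @ flat_strides
                spheres.append(
                    Searchlight(
                        center=(int(cx), int(cy), int(cz)),
                        member_voxels=np.sort(members),
                        radius=radius,
                    )
                )
    return spheres


def fit_predict_ridge(
    train_features: np.ndarray,
    train_patterns: np.ndarray,
    test_features: np.ndarray,
    ridge_lambda: float,
) -> np.ndarray:
    """Ridge predictions with a shared penalty across voxels.

    Features and patterns are centered with training means (the intercept is
    unpenalized), the coefficient matrix solves
    ``(X'X + lambda I) W = X'Y``, and predictions add the training mean
    back. The dual form is used when training samples are fewer than feature
    dimensions.
    """
    if ridge_lambda <= 0:
        raise ValueError("ridge lambda must be positive")
    X = np.asarray(train_features, dtype=float)
    Y = np.asarray(train_patterns, dtype=float)
    Xt = np.asarray(test_features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Xt.ndim == 1:
        Xt = Xt[:, None]
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc, Yc = X - x_mean, Y - y_mean
    n, d = Xc.shape
    if n < d:
        alpha = np.linalg.solve(Xc @ Xc.T + ridge_lambda * np.eye(n), Yc)
        pred = (Xt - x_mean) @ (Xc.T @ alpha)
    else:
        W = np.linalg.solve(Xc.T @ Xc + ridge_lambda * np.eye(d), Xc.T @ Yc)
        pred = (Xt - x_mean) @ W
    return pred + y_mean


def correlation_error_probability(predicted: np.ndarray, observed: np.ndarray):
    """1 - p of the Pearson correlation between prediction and observation.

    p is the two-sided probability of |r| under the null (t distribution
    with n - 2 df). Perfect predictions score 1; a constant vector scores 0
    with ``constant=True`` in the returned flag.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if predicted.size < 3:
        raise ValueError("need at least 3 voxels to correlate")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        return 0.0, True
    r, p = stats.pearsonr(predicted, observed)
    return float(1.0 - p), False


def _rowwise_pearson(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Pearson r per row (across columns); 0 where a row is constant."""
    pc = pred - pred.mean(axis=1, keepdims=True)
    oc = obs - obs.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc**2).sum(axis=1) * (oc**2).sum(axis=1))
    valid = denom > 0
    r = np.zeros(pred.shape[0])
    r[valid] = (pc * oc).sum(axis=1)[valid] / denom[valid]
    return np.clip(r, -1.0, 1.0)


def _cep_from_r(r: np.ndarray, m: np.ndarray, constant: np.ndarray) -> np.ndarray:
    """Correlation-error probability 1 - p from r and sample sizes m."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((m - 2) / np.maximum(1.0 - r**2, 1e-300))
    score = 1.0 - 2.0 * stats.t.sf(np.abs(t), m - 2)
    score[constant] = 0.0
    return score


def run_searchlight(
    betas: BetaPatterns,
    features: dict,
    genres: dict,
    mask: np.ndarray,
    affine: np.ndarray = None,
    radius: int = 3,
    scatter_step: int = 3,
    repetitions: int = 10,
    rng_seed: int = 0,
    ridge_lambda: float = 1.0,
    min_variance: float = 0.95,
    min_sphere_voxels: int = 3,
    scatter_offset: tuple = None,
) -> SearchlightMap:
    """Scattered searchlight encoding map for one subject and feature kind.

    Per repetition, one randomly chosen stimulus per genre is held out (all
    runs); the feature reduction is refit on the remaining stimuli, betas
    are z-scored with training-cell statistics, and a ridge model predicts
    each held-out (stimulus, run) pattern. Per sphere, the accuracy is the
    mean correlation-error probability over
    ``5 held-out stimuli x runs x repetitions`` tests.
    """
    mask = np.asarray(mask, dtype=bool)
    if affine is None:
        affine = np.eye(4)
    rng = np.random.default_rng(rng_seed)
    if scatter_offset is None:
        scatter_offset = tuple(rng.integers(0, scatter_step, size=3))
    spheres = enumerate_spheres(
        mask, radius=radius, scatter_step=scatter_step, scatter_offset=scatter_offset
    )
    spheres = [s for s in spheres if s.member_voxels.size >= min_sphere_voxels]

    stim_ids = list(betas.stimulus_ids)
    stim_index = {sid: i for i, sid in enumerate(stim_ids)}
    by_genre = {}
    for sid in stim_ids:
        by_genre.setdefault(genres[sid], []).append(sid)
    n_runs = len(betas.run_ids)

    if (mask & ~betas.mask).any():
        raise ValueError("searchlight mask extends outside the beta mask")
    # map flat volume indices to positions along the masked-voxel (beta) axis
    flat_to_masked = np.full(betas.mask.size, -1, dtype=int)
    flat_to_masked[np.flatnonzero(betas.mask.reshape(-1))] = np.arange(betas.n_voxels)

    totals = np.zeros(len(spheres))
    n_tests = 0
    for _ in range(repetitions):
        held = [by_genre[g][rng.integers(len(by_genre[g]))] for g in sorted(by_genre)]
        train_ids = [sid for sid in stim_ids if sid not in held]
        reduced = fit_reduce(features, train_ids, min_variance=min_variance)

        train_cells = np.zeros((len(stim_ids), n_runs), dtype=bool)
        test_cells = np.zeros((len(stim_ids), n_runs), dtype=bool)
        for sid in train_ids:
            train_cells[stim_index[sid], :] = True
        for sid in held:
            test_cells[stim_index[sid], :] = True
        z = zscore_within_fold(betas, train_cells)

        X_tr = np.vstack(
            [np.tile(reduced.vectors[sid], (n_runs, 1)) for sid in train_ids]
        )
        X_te = np.vstack([np.tile(reduced.vectors[sid], (n_runs, 1)) for sid in held])
        Y_tr = np.vstack([z.betas[stim_index[sid]] for sid in train_ids])
        Y_te = np.vstack([z.betas[stim_index[sid]] for sid in held])

        # shared ridge operator: predictions = M @ Y_train (dual form), so the
        # expensive solve happens once per repetition, not per sphere
        x_mean = X_tr.mean(axis=0)
        Xc = X_tr - x_mean
        n = Xc.shape[0]
        K = Xc @ Xc.T + ridge_lambda * np.eye(n)
        M = (X_te - x_mean) @ Xc.T @ np.linalg.inv(K)
        y_mean = Y_tr.mean(axis=0)
        pred_full = M @ (Y_tr - y_mean) + y_mean  # (tests, all voxels)

        n_te = X_te.shape[0]
        r_all = np.empty((len(spheres), n_te))
        m_all = np.empty((len(spheres), n_te))
        const_all = np.zeros((len(spheres), n_te), dtype=bool)
        for i, s in enumerate(spheres):
            cols = flat_to_masked[s.member_voxels]
            pred = pred_full[:, cols]
            obs = Y_te[:, cols]
            r_all[i] = _rowwise_pearson(pred, obs)
            m_all[i] = cols.size
            const_all[i] = (np.ptp(pred, axis=1) == 0) | (np.ptp(obs, axis=1) == 0)
        totals += _cep_from_r(r_all, m_all, const_all).sum(axis=1)
        n_tests += n_te

    volume = np.full(mask.shape, np.nan)
    for i, s in enumerate(spheres):
        volume[s.center] = totals[i] / n_tests
    return SearchlightMap(
        volume=volume,
        mask=mask,
        affine=np.asarray(affine, dtype=float),
        radius=radius,
        scatter_step=scatter_step,
        scatter_offset=tuple(int(v) for v in scatter_offset),
        n_tests=n_tests,
    )


def fill_scattered(slmap: SearchlightMap) -> np.ndarray:
    """Fill uncomputed in-mask voxels with the nearest computed center's value.

    Returns a full volume (NaN outside the mask) suitable for group-level
    voxel-wise statistics on the complete mask lattice.
    """
    from scipy.ndimage import distance_transform_edt

    computed = slmap.computed_voxels()
    if not computed.any():
        raise ValueError("map has no computed voxels")
    _, nearest = distance_transform_edt(~computed, return_indices=True)
    filled = slmap.volume[tuple(nearest)]
    filled[~slmap.mask] = np.nan
    return filled
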