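"""Per-voxel GLM response estimation.

EPI run time series are projected to per-stimulus response patterns by
ordinary least squares on an event-related design: one boxcar regressor per
stimulus condition, convolved with a canonical double-gamma hemodynamic
response function, plus constant and linear-trend nuisance columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HRFParams",
    "double_gamma_hrf",
    "condition_regressor",
    "DesignMatrix",
    "BetaPatterns",
    "build_design",
    "fit_glm",
    "zscore_within_fold",
]


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma parameters (SPM convention).

    Response peak at ``peak_delay`` s, undershoot peaking at
    ``undershoot_delay`` s scaled by ``1 / undershoot_ratio``.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 6.0


def double_gamma_hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Evaluate the double-gamma HRF at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    p = params
    peak = gamma_dist.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    under = gamma_dist.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    h = peak - under / p.undershoot_ratio
    h = np.where(t < 0, 0.0, h)
    peak_val = h.max()
    return h / peak_val if peak_val > 0 else h


def condition_regressor(
    onsets,
    duration: float,
    n_volumes: int,
    tr: float,
    hrf_params: HRFParams = HRFParams(),
    oversample: int = 16,
) -> np.ndarray:
    """HRF-convolved boxcar regressor for one condition, sampled at the TR.

    The boxcar is built on an ``oversample``-times-finer grid (half-open
    event intervals ``[onset, onset + duration)``), convolved with the HRF on
    that grid, and decimated back to volume times. Both the forward
    simulator and the GLM use this exact function, so noise-free round trips
    are exact.
    """
    dt = tr / oversample
    n_fine = n_volumes * oversample
    box = np.zeros(n_fine)
    for onset in np.atleast_1d(onsets):
        lo = int(np.ceil(onset / dt - 1e-9))
        hi = int(np.ceil((onset + duration) / dt - 1e-9))
        if hi > n_fine:
            raise ValueError(f"event at {onset} s extends past the run")
        box[lo:hi] = 1.0
    kernel = double_gamma_hrf(np.arange(0, 32.0 + dt / 2, dt)) * dt
    conv = np.convolve(box, kernel)[:n_fine]
    return conv[::oversample]


@dataclass
class DesignMatrix:
    """T x (conditions + nuisance) design for one run."""

    values: np.ndarray
    condition_ids: list
    tr: float
    n_nuisance: int = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("design matrix contains non-finite entries")
        if self.values.shape[1] != len(self.condition_ids) + self.n_nuisance:
            raise ValueError("column count does not match conditions + nuisance")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


@dataclass
class BetaPatterns:
    """stimulus x run x voxel GLM response estimates within a mask."""

    betas: np.ndarray
    stimulus_ids: list
    run_ids: list
    mask: np.ndarray
    subject_id: str = ""
    zscored: bool = False
    flagged_voxels: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_stim, n_run, n_vox = self.betas.shape
        if n_stim != len(self.stimulus_ids) or n_run != len(self.run_ids):
            raise ValueError("beta array shape does not match stimulus/run ids")
        if n_vox != int(self.mask.sum()):
            raise ValueError("voxel axis does not match mask voxel count")

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]

    def save(self, path) -> None:
        np.savez(
            path,
            betas=self.betas,
            stimulus_ids=np.array(self.stimulus_ids, dtype=object),
            run_ids=np.array(self.run_ids),
            mask=self.mask,
            subject_id=self.subject_id,
            zscored=self.zscored,
        )

    @classmethod
    def load(cls, path) -> "BetaPatterns":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                betas=z["betas"],
                stimulus_ids=[str(s) for s in z["stimulus_ids"]],
                run_ids=[int(r) for r in z["run_ids"]],
                mask=z["mask"],
                subject_id=str(z["subject_id"]),
                zscored=bool(z["zscored"]),
            )


def build_design(
    events,
    n_volumes: int,
    tr: float,
    hrf_params: HRFParams = HRFParams(),
    stimulus_order=None,
) -> DesignMatrix:
    """Build the event-related design for one run.

    ``events`` is a table (pandas DataFrame or dict of sequences) with
    columns ``onset``, ``duration``, ``stimulus_id``. One regressor per
    stimulus condition; a constant and a linear trend are appended.
    """
    onsets = np.asarray(events["onset"], dtype=float)
    durations = np.asarray(events["duration"], dtype=float)
    stim = [str(s) for s in np.asarray(events["stimulus_id"])]
    if (onsets < 0).any():
        raise ValueError("negative event onset")
    if ((onsets + durations) > n_volumes * tr + 1e-9).any():
        raise ValueError("event extends past the end of the run")

    condition_ids = (
        list(stimulus_order)
        if stimulus_order is not None
        else sorted(set(stim))
    )
    columns = []
    for cid in condition_ids:
        cond_onsets = onsets[[s == cid for s in stim]]
        if len(cond_onsets) > 1:
            order = np.sort(cond_onsets)
            dur = durations[[s == cid for s in stim]][np.argsort(cond_onsets)]
            if (order[1:] < order[:-1] + dur[:-1]).any():
                raise ValueError(f"overlapping events for condition {cid!r}")
        dur = durations[[s == cid for s in stim]]
        if len(set(dur)) > 1:
            raise ValueError(f"inconsistent durations for condition {cid!r}")
        columns.append(
            condition_regressor(cond_onsets, float(dur[0]) if len(dur) else 0.0,
                                n_volumes, tr, hrf_params)
            if len(cond_onsets)
            else np.zeros(n_volumes)
        )
    const = np.ones(n_volumes)
    trend = np.linspace(-1.0, 1.0, n_volumes)
    values = np.column_stack(columns + [const, trend]) if columns else np.column_stack([const, trend])
    return DesignMatrix(values=values, condition_ids=condition_ids, tr=tr)


def fit_glm(epi: np.ndarray, design: DesignMatrix, mask: np.ndarray) -> np.ndarray:
    """OLS fit of one run; returns (condition x voxel) betas, nuisance dropped.

    ``epi`` is (T, X, Y, Z) or already (T, voxels). Raises on a
    rank-deficient design rather than silently regularizing.
    """
    epi = np.asarray(epi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if epi.ndim == 4:
        data = epi[:, mask]
    elif epi.ndim == 2:
        data = epi
    else:
        raise ValueError("epi must be 4-D (T,X,Y,Z) or 2-D (T,voxels)")
    X = design.values
    if data.shape[0] != X.shape[0]:
        raise ValueError("design rows must equal volume count")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design: rank {rank} < {X.shape[1]} columns"
        )
    coef, *_ = np.linalg.lstsq(X, data, rcond=None)
    n_cond = len(design.condition_ids)
    return coef[:n_cond]


def zscore_within_fold(betas: BetaPatterns, train_index: np.ndarray) -> BetaPatterns:
    """Z-score each voxel using statistics from training cells only.

    ``train_index`` is a boolean (stimulus x run) cell selector. The training
    mean and standard deviation are applied to *all* cells. Zero-variance
    voxels have their std floored at machine-epsilon scale and are flagged.
    """
    train_index = np.asarray(train_index, dtype=bool)
    if train_index.shape != betas.betas.shape[:2]:
        raise ValueError("train_index must be (stimulus x run)")
    if not train_index.any():
        raise ValueError("empty training cell selection")
    train = betas.betas[train_index]  # (cells, voxels)
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    flagged = std < np.finfo(float).eps
    std = np.where(flagged, np.finfo(float).eps, std)
    z = (betas.betas - mean) / std
    return BetaPatterns(
        betas=z,
        stimulus_ids=list(betas.stimulus_ids),
        run_ids=list(betas.run_ids),
        mask=betas.mask,
        subject_id=betas.subject_id,
        zscored=True,
        flagged_voxels=flagged,
    )
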