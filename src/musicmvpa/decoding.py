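"""Within-subject multivoxel decoding of song identity and genre.

Feature selection (one-way ANOVA over stimulus factors on dedicated
selection runs), linear SVM with norm-scaled margin parameter, leave-run-out
and leave-one-stimulus-per-genre-out cross-validation, and comparison of the
resulting confusion structure with behavioral confusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .glm import BetaPatterns, zscore_within_fold

__all__ = [
    "CrossValScheme",
    "ConfusionMatrix",
    "select_voxels_anova",
    "train_svm",
    "run_decoding",
    "group_summary",
    "confusion_spearman",
]

DEFAULT_SELECTION_RUNS = (1, 4)


@dataclass
class CrossValScheme:
    """Cross-validation folds over (stimulus, run) cells.

    ``folds`` is a list of (train_cells, test_cells) pairs, each a boolean
    (stimulus x run) selector. Runs reserved for feature selection appear in
    no fold.
    """

    kind: str  # leave_run_out | leave_stimulus_per_genre_out
    folds: list
    feature_selection_runs: tuple = DEFAULT_SELECTION_RUNS

    def validate(self) -> None:
        for train, test in self.folds:
            if (train & test).any():
                raise ValueError("train and test cells overlap")


def _cv_run_indices(run_ids, selection_runs):
    sel = set(selection_runs)
    return [i for i, r in enumerate(run_ids) if r not in sel]


def make_leave_run_out(betas: BetaPatterns,
                       selection_runs=DEFAULT_SELECTION_RUNS) -> CrossValScheme:
    """One fold per non-selection run; that run's cells are the test set."""
    n_stim, n_run = betas.betas.shape[:2]
    cv_runs = _cv_run_indices(betas.run_ids, selection_runs)
    folds = []
    for test_run in cv_runs:
        train = np.zeros((n_stim, n_run), dtype=bool)
        test = np.zeros((n_stim, n_run), dtype=bool)
        for r in cv_runs:
            (test if r == test_run else train)[:, r] = True
        folds.append((train, test))
    return CrossValScheme("leave_run_out", folds, tuple(selection_runs))


def make_leave_stimulus_per_genre_out(
    betas: BetaPatterns,
    genres: dict,
    selection_runs=DEFAULT_SELECTION_RUNS,
) -> CrossValScheme:
    """Five folds, each holding out all runs of one stimulus per genre.

    ``genres`` maps stimulus_id -> genre label. Stimuli are ordered within
    genre; fold *i* holds out the i-th stimulus of every genre, so each
    stimulus is held out exactly once.
    """
    n_stim, n_run = betas.betas.shape[:2]
    cv_runs = _cv_run_indices(betas.run_ids, selection_runs)
    by_genre = {}
    for idx, sid in enumerate(betas.stimulus_ids):
        by_genre.setdefault(genres[sid], []).append(idx)
    sizes = {len(v) for v in by_genre.values()}
    if len(sizes) != 1:
        raise ValueError("genres must contain equally many stimuli")
    n_folds = sizes.pop()
    folds = []
    for i in range(n_folds):
        held = {ids[i] for ids in by_genre.values()}
        train = np.zeros((n_stim, n_run), dtype=bool)
        test = np.zeros((n_stim, n_run), dtype=bool)
        for r in cv_runs:
            for s in range(n_stim):
                (test if s in held else train)[s, r] = True
        folds.append((train, test))
    return CrossValScheme(
        "leave_stimulus_per_genre_out", folds, tuple(selection_runs)
    )


@dataclass
class ConfusionMatrix:
    """Integer (true x predicted) confusion counts."""

    counts: np.ndarray
    labels: list
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError("confusion matrix must be L x L")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    def normalize(self) -> "ConfusionMatrix":
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        row[row == 0] = 1.0
        return ConfusionMatrix(self.counts / row, list(self.labels), True)

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")


def select_voxels_anova(
    betas: BetaPatterns,
    selection_runs,
    labels: list,
    k: int = 5000,
) -> np.ndarray:
    """Top-k voxels by one-way ANOVA F-score on the selection runs.

    ``labels`` gives one factor level per stimulus (here: the stimulus id
    itself, a 25-level factor). Ties break toward the lower voxel index; if
    ``k`` exceeds the voxel count all voxels are kept.
    """
    sel = [i for i, r in enumerate(betas.run_ids) if r in set(selection_runs)]
    if not sel:
        raise ValueError("no selection runs present")
    if len(sel) < 2:
        raise ValueError("need >= 2 observations per factor level")
    data = betas.betas[:, sel, :]  # (stim, sel_runs, vox)
    n_stim, n_obs, n_vox = data.shape
    X = data.reshape(n_stim * n_obs, n_vox)
    y = np.repeat(np.asarray(labels, dtype=object), n_obs)
    F, _ = f_classif(X, y)
    F = np.nan_to_num(F, nan=0.0)
    k = min(k, n_vox)
    order = np.argsort(-F, kind="stable")  # stable sort: ties by voxel index
    return np.sort(order[:k])


def train_svm(patterns: np.ndarray, labels, multiclass: str = "ovo") -> SVC:
    """Linear SVM with C = 1 / (mean training-sample L2 norm).

    One-vs-one by default (``multiclass='ovr'`` wraps a one-vs-rest
    scheme). Deterministic given its inputs.
    """
    patterns = np.asarray(patterns, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train")
    mean_norm = float(np.linalg.norm(patterns, axis=1).mean())
    C = 1.0 / mean_norm if mean_norm > 0 else 1.0
    clf = SVC(kernel="linear", C=C)
    if multiclass == "ovr":
        clf = OneVsRestClassifier(SVC(kernel="linear", C=C))
    clf.fit(patterns, labels)
    clf.effective_C_ = C
    return clf


def run_decoding(
    betas: BetaPatterns,
    scheme: CrossValScheme,
    target: str,
    genres: dict = None,
    k: int = 5000,
    multiclass: str = "ovo",
) -> tuple:
    """Cross-validated decoding; returns (accuracy, ConfusionMatrix).

    Per fold: z-score with training-cell statistics, train on training
    cells, predict held-out cells. Voxel selection (ANOVA on the scheme's
    selection runs) happens once, outside the folds. ``target`` is ``song``
    (label = stimulus id) or ``genre`` (label = genre; requires ``genres``).
    """
    if target not in ("song", "genre"):
        raise ValueError("target must be 'song' or 'genre'")
    if target == "genre" and genres is None:
        raise ValueError("genre decoding requires a stimulus -> genre map")
    scheme.validate()
    sel_runs = set(scheme.feature_selection_runs)
    cv_run_cols = {i for i, r in enumerate(betas.run_ids) if r in sel_runs}
    for train, test in scheme.folds:
        used = set(np.nonzero(train.any(axis=0) | test.any(axis=0))[0])
        if used & cv_run_cols:
            raise ValueError("feature-selection runs leak into CV folds")

    voxels = select_voxels_anova(
        betas, scheme.feature_selection_runs, betas.stimulus_ids, k=k
    )
    if target == "song":
        cell_label = lambda s, r: betas.stimulus_ids[s]
        label_set = list(betas.stimulus_ids)
    else:
        cell_label = lambda s, r: genres[betas.stimulus_ids[s]]
        label_set = sorted(set(genres[s] for s in betas.stimulus_ids))
    lab_index = {l: i for i, l in enumerate(label_set)}

    counts = np.zeros((len(label_set), len(label_set)), dtype=int)
    n_correct = 0
    n_total = 0
    for train, test in scheme.folds:
        if not test.any():
            raise ValueError("empty test fold")
        z = zscore_within_fold(betas, train)
        data = z.betas[:, :, voxels]
        tr_cells = np.argwhere(train)
        te_cells = np.argwhere(test)
        X_tr = data[train]
        y_tr = [cell_label(s, r) for s, r in tr_cells]
        clf = train_svm(X_tr, y_tr, multiclass=multiclass)
        pred = clf.predict(data[test])
        for (s, r), p in zip(te_cells, pred):
            truth = cell_label(s, r)
            counts[lab_index[truth], lab_index[p]] += 1
            n_correct += truth == p
            n_total += 1
    return n_correct / n_total, ConfusionMatrix(counts, label_set)


def group_summary(accuracies) -> tuple:
    """Mean and standard error (sd / sqrt(n)) across subjects."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need >= 2 subjects")
    return float(acc.mean()), float(acc.std(ddof=1) / np.sqrt(acc.size))


def confusion_spearman(neural: ConfusionMatrix, behavioral: ConfusionMatrix) -> tuple:
    """Spearman rank correlation over strictly-upper-triangle entries.

    Restricting to above-diagonal cells removes the positive bias the shared
    diagonal structure would induce. Returns (rho, two-sided p); rho is NaN
    if either vector is constant.
    """
    a = np.asarray(neural.counts, dtype=float)
    b = np.asarray(behavioral.counts, dtype=float)
    if a.shape != b.shape:
        raise ValueError("confusion matrices must have the same shape")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 labels")
    iu = np.triu_indices(n, k=1)
    va, vb = a[iu], b[iu]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(va, vb)
    return float(rho), float(p)
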