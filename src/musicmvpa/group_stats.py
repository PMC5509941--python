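"""Group-level inference on searchlight maps.

Null searchlight maps are built per subject by shuffling the stimulus ->
feature assignment; group null distributions are obtained by bootstrap
resampling of those null maps pair-wise by subject; voxels are thresholded
against the per-voxel bootstrap quantile and surviving clusters are tested
against the null distribution of maximum cluster size (family-wise error
control).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import BetaPatterns
from .searchlight import SearchlightMap, fill_scattered, run_searchlight

__all__ = [
    "NullMapSet",
    "ClusterRecord",
    "make_null_maps",
    "bootstrap_group_null",
    "BootstrapNull",
    "threshold_and_cluster",
    "cluster_fwe",
    "clusters_to_csv",
    "clusters_from_csv",
]

_CONNECTIVITY_STRUCTS = {
    "faces": ndimage.generate_binary_structure(3, 1),
    "edges": ndimage.generate_binary_structure(3, 2),
    "corners": ndimage.generate_binary_structure(3, 3),
}


@dataclass
class NullMapSet:
    """Per-subject randomized-target null maps on a shared mask lattice.

    ``values`` is (subjects, n_null, voxels) over the computed (filled) mask
    voxels; ``mask`` is the shared boolean volume.
    """

    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be (subjects, n_null, voxels)")
        if self.values.shape[2] != int(self.mask.sum()):
            raise ValueError("voxel axis must match the mask voxel count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_null_per_subject(self) -> int:
        return self.values.shape[1]


def make_null_maps(
    betas: BetaPatterns,
    features: dict,
    genres: dict,
    mask: np.ndarray,
    n_null: int = 100,
    rng_seed: int = 0,
    repetitions: int = 2,
    scatter_offset: tuple = None,
    **searchlight_kwargs,
) -> np.ndarray:
    """Randomized-target null searchlight maps for one subject.

    Each null model applies a random permutation to the stimulus -> feature
    assignment and reruns the searchlight (at ``repetitions``
    cross-validation repetitions, typically fewer than the true analysis).
    Scatter offsets are shared with the true map when ``scatter_offset`` is
    given. Returns (n_null, mask voxels) filled accuracy values.
    """
    rng = np.random.default_rng(rng_seed)
    sids = sorted(features)
    out = None
    for j in range(n_null):
        perm = rng.permutation(len(sids))
        shuffled = {sids[i]: features[sids[perm[i]]] for i in range(len(sids))}
        slmap = run_searchlight(
            betas,
            shuffled,
            genres,
            mask,
            repetitions=repetitions,
            rng_seed=int(rng.integers(2**31)),
            scatter_offset=scatter_offset,
            **searchlight_kwargs,
        )
        filled = fill_scattered(slmap)[mask]
        if out is None:
            out = np.empty((n_null, filled.size))
        out[j] = filled
    return out


@dataclass
class BootstrapNull:
    """Bootstrap group-mean null maps: (n_bootstrap, voxels)."""

    samples: np.ndarray
    mask: np.ndarray

    @property
    def n_bootstrap(self) -> int:
        return self.samples.shape[0]

    def voxel_threshold(self, voxel_p: float = 0.001) -> np.ndarray:
        """Per-voxel (1 - voxel_p) quantile of the bootstrap null."""
        return np.quantile(self.samples, 1.0 - voxel_p, axis=0)

    def voxel_p(self, group_map: np.ndarray) -> np.ndarray:
        """Empirical per-voxel p of a group map, (r + 1) / (B + 1)."""
        r = (self.samples >= group_map[None, :]).sum(axis=0)
        return (r + 1.0) / (self.n_bootstrap + 1.0)


def bootstrap_group_null(
    nulls: NullMapSet,
    n_bootstrap: int = 10000,
    rng_seed: int = 0,
    chunk: int = 2000,
) -> BootstrapNull:
    """Bootstrap the group null: each sample draws one null map per subject
    (independently, with replacement) and averages across subjects."""
    if nulls.n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    if n_bootstrap < 1000:
        import warnings

        warnings.warn("n_bootstrap < 1000: tail quantiles will be unstable")
    rng = np.random.default_rng(rng_seed)
    n_subj, n_null, n_vox = nulls.values.shape
    samples = np.empty((n_bootstrap, n_vox), dtype=np.float32)
    for start in range(0, n_bootstrap, chunk):
        stop = min(start + chunk, n_bootstrap)
        draw = rng.integers(0, n_null, size=(stop - start, n_subj))
        acc = np.zeros((stop - start, n_vox))
        for s in range(n_subj):
            acc += nulls.values[s, draw[:, s], :]
        samples[start:stop] = (acc / n_subj).astype(np.float32)
    return BootstrapNull(samples=samples, mask=nulls.mask)


def threshold_and_cluster(
    group_map: np.ndarray,
    bootstrap: BootstrapNull,
    mask: np.ndarray,
    voxel_p: float = 0.001,
    connectivity: str = "faces",
) -> tuple:
    """Voxel-wise threshold then connected components.

    ``group_map`` is the true group-mean map over mask voxels. Voxels whose
    value strictly exceeds the (1 - voxel_p) bootstrap quantile survive;
    components are formed under the requested connectivity (default: shared
    faces). Returns (binary volume, labeled volume, cluster sizes).
    """
    mask = np.asarray(mask, dtype=bool)
    thresh = bootstrap.voxel_threshold(voxel_p)
    surviving = np.zeros(mask.shape, dtype=bool)
    surviving[mask] = group_map > thresh
    struct = _CONNECTIVITY_STRUCTS[connectivity]
    labeled, n_clusters = ndimage.label(surviving, structure=struct)
    sizes = np.array(
        [int((labeled == i).sum()) for i in range(1, n_clusters + 1)], dtype=int
    )
    return surviving, labeled, sizes


@dataclass
class ClusterRecord:
    """One significant cluster, mirroring the reported table columns."""

    index: int
    size: int
    max: float
    mean: float
    std: float
    center_of_mass: tuple  # mm coordinates via the affine
    p_cluster: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if not 0.0 < self.p_cluster <= 1.0:
            raise ValueError("p_cluster must lie in (0, 1]")


def _max_cluster_size(binary: np.ndarray, struct: np.ndarray) -> int:
    labeled, n = ndimage.label(binary, structure=struct)
    if n == 0:
        return 0
    return int(np.bincount(labeled.reshape(-1))[1:].max())


def cluster_fwe(
    group_map: np.ndarray,
    bootstrap: BootstrapNull,
    mask: np.ndarray,
    affine: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    connectivity: str = "faces",
    label_volume: np.ndarray = None,
    label_names: dict = None,
) -> list:
    """FWE-corrected cluster inference.

    The null distribution of maximum suprathreshold cluster size is built by
    thresholding every bootstrap null map exactly as the true map;
    ``p_cluster`` for an observed cluster of size *s* is
    ``(#null maxima >= s + 1) / (B + 1)``. Clusters with
    ``p_cluster < cluster_p`` are reported with accuracy statistics and the
    (unweighted) center of mass mapped through the affine. An optional
    integer ``label_volume`` with ``label_names`` populates the label field
    from the voxel majority.
    """
    mask = np.asarray(mask, dtype=bool)
    struct = _CONNECTIVITY_STRUCTS[connectivity]
    thresh = bootstrap.voxel_threshold(voxel_p)

    null_maxima = np.empty(bootstrap.n_bootstrap, dtype=int)
    binary = np.zeros(mask.shape, dtype=bool)
    for b in range(bootstrap.n_bootstrap):
        binary[:] = False
        binary[mask] = bootstrap.samples[b] > thresh
        null_maxima[b] = _max_cluster_size(binary, struct)

    _, labeled, sizes = threshold_and_cluster(
        group_map, bootstrap, mask, voxel_p, connectivity
    )
    volume = np.full(mask.shape, np.nan)
    volume[mask] = group_map

    records = []
    order = np.argsort(-sizes, kind="stable")
    out_index = 0
    for ci in order:
        size = int(sizes[ci])
        p = ((null_maxima >= size).sum() + 1.0) / (bootstrap.n_bootstrap + 1.0)
        if p >= cluster_p:
            continue
        where = np.argwhere(labeled == ci + 1)
        vals = volume[labeled == ci + 1]
        com_vox = where.mean(axis=0)
        com_mm = (np.asarray(affine) @ np.append(com_vox, 1.0))[:3]
        label = ""
        if label_volume is not None:
            ids, counts = np.unique(
                np.asarray(label_volume)[labeled == ci + 1], return_counts=True
            )
            majority = int(ids[np.argmax(counts)])
            label = (label_names or {}).get(majority, str(majority) if majority else "")
        out_index += 1
        records.append(
            ClusterRecord(
                index=out_index,
                size=size,
                max=float(np.nanmax(vals)),
                mean=float(np.nanmean(vals)),
                std=float(np.nanstd(vals)),
                center_of_mass=tuple(float(v) for v in com_mm),
                p_cluster=float(p),
                label=label,
            )
        )
    return records


_CSV_COLUMNS = ["#", "Voxels", "Max", "Mean", "Std", "X", "Y", "Z", "p_clus", "Structure"]


def clusters_to_csv(records: list) -> str:
    rows = [
        {
            "#": r.index,
            "Voxels": r.size,
            "Max": r.max,
            "Mean": r.mean,
            "Std": r.std,
            "X": r.center_of_mass[0],
            "Y": r.center_of_mass[1],
            "Z": r.center_of_mass[2],
            "p_clus": r.p_cluster,
            "Structure": r.label,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(index=False)


def clusters_from_csv(text: str) -> list:
    df = pd.read_csv(io.StringIO(text), keep_default_na=False)
    return [
        ClusterRecord(
            index=int(row["#"]),
            size=int(row["Voxels"]),
            max=float(row["Max"]),
            mean=float(row["Mean"]),
            std=float(row["Std"]),
            center_of_mass=(float(row["X"]), float(row["Y"]), float(row["Z"])),
            p_cluster=float(row["p_clus"]),
            label=str(row["Structure"]),
        )
        for _, row in df.iterrows()
    ]
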