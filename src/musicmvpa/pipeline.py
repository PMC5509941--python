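"""End-to-end orchestration on synthetic data.

``run_pipeline`` executes simulate -> features -> GLM -> decoding and/or
searchlight -> group statistics, writing every intermediate product and a
summary report with full provenance (config + seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .decoding import (
    ConfusionMatrix,
    confusion_spearman,
    group_summary,
    make_leave_run_out,
    make_leave_stimulus_per_genre_out,
    run_decoding,
)
from .glm import BetaPatterns, build_design, fit_glm
from .group_stats import (
    NullMapSet,
    bootstrap_group_null,
    cluster_fwe,
    clusters_to_csv,
    make_null_maps,
)
from .io_utils import write_confusions, write_events, write_volume
from .music_features import fit_reduce, resample_to_frames, transcription_to_grid, transpose_to_c
from .searchlight import fill_scattered, run_searchlight
from .synthetic_data import (
    GENRES,
    default_brain,
    default_stimuli,
    generate_behavioral_confusions,
    generate_melody,
    generate_session,
    synthesize_chromagram,
    stimuli_to_json,
)

__all__ = ["build_feature_matrices", "session_to_betas", "run_pipeline"]


def build_feature_matrices(stimuli, rng_seed: int) -> dict:
    """All three per-stimulus feature kinds from generated melodies.

    Returns {kind -> {stimulus_id -> FeatureMatrix}}.
    """
    rng = np.random.default_rng(rng_seed)
    out = {"melody_abs": {}, "melody_rel": {}, "chroma": {}}
    for spec in stimuli:
        mseed, cseed = rng.integers(2**31, size=2)
        melody = generate_melody(spec, int(mseed))
        grid = transcription_to_grid(melody)
        out["melody_abs"][spec.stimulus_id] = resample_to_frames(
            grid, spec.tempo, spec.duration, kind="melody_abs",
            stimulus_id=spec.stimulus_id,
        )
        out["melody_rel"][spec.stimulus_id] = resample_to_frames(
            transpose_to_c(grid, spec.key), spec.tempo, spec.duration,
            kind="melody_rel", stimulus_id=spec.stimulus_id,
        )
        out["chroma"][spec.stimulus_id] = synthesize_chromagram(
            melody, spec, int(cseed)
        )
    return out


def session_to_betas(session, mask: np.ndarray, subject_id: str = "") -> BetaPatterns:
    """GLM-fit every run of a synthetic session to stimulus x run x voxel betas."""
    stim_ids = sorted(session.events[0]["stimulus_id"])
    per_run = []
    for r in range(session.n_runs):
        design = build_design(
            session.events[r],
            session.volumes_per_run,
            session.tr,
            stimulus_order=stim_ids,
        )
        epi = session.epi[r]  # (T, X, Y, Z)
        per_run.append(fit_glm(epi, design, mask))
    betas = np.stack(per_run, axis=1)  # (stimulus, run, voxel)
    return BetaPatterns(
        betas=betas,
        stimulus_ids=stim_ids,
        run_ids=list(range(1, session.n_runs + 1)),
        mask=mask,
        subject_id=subject_id,
    )


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the configured synthetic pipeline; returns the summary dict."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    def stage(name):
        print(f"[musicmvpa] stage: {name}", flush=True)

    # --- simulate ---------------------------------------------------------
    stage("simulate")
    stimuli = default_stimuli()
    (out / "stimuli.json").write_text(stimuli_to_json(stimuli))
    features = build_feature_matrices(stimuli, int(rng.integers(2**31)))
    genres = {s.stimulus_id: s.genre for s in stimuli}

    # ground-truth reduction (fitted on all stimuli) sizes the planted weights
    all_ids = [s.stimulus_id for s in stimuli]
    reduced_truth = {
        kind: fit_reduce(features[kind], all_ids, config.min_variance)
        for kind in config.feature_kinds
    }
    feature_dims = {k: r.basis.shape[1] * 60 for k, r in reduced_truth.items()}
    brain = default_brain(
        feature_dims,
        shape=config.grid_shape,
        snr=config.snr,
        slab_thickness=config.slab_thickness,
        rng_seed=int(rng.integers(2**31)),
        kinds=config.feature_kinds,
    )
    write_volume(out / "region_labels.nii", brain.region_labels, brain.affine)
    np.savez(
        out / "ground_truth_weights.npz",
        **{
            f"region_{r}_{enc.feature_kind}": enc.weights
            for r, enc in brain.region_encoding.items()
            if enc.weights is not None
        },
    )
    truth_vectors = {k: r.vectors for k, r in reduced_truth.items()}

    mask = np.ones(config.grid_shape, dtype=bool)
    behavioral = generate_behavioral_confusions(int(rng.integers(2**31)))
    write_confusions(out / "behavioral_confusions.csv", behavioral)

    subjects = []
    for s in range(config.n_subjects):
        session = generate_session(
            brain,
            stimuli,
            truth_vectors,
            rng_seed=int(rng.integers(2**31)),
            n_runs=config.n_runs,
            volumes_per_run=config.volumes_per_run,
            tr=config.tr,
            subject_id=f"sub-{s + 1:02d}",
        )
        subjects.append(session)
        sdir = out / session.subject_id
        sdir.mkdir(exist_ok=True)
        for r in range(session.n_runs):
            write_events(sdir / f"run-{r + 1}_events.tsv", session.events[r])

    # --- features --------------------------------------------------------
    stage("features")
    fdir = out / "features"
    fdir.mkdir(exist_ok=True)
    for kind in config.feature_kinds:
        kdir = fdir / kind
        kdir.mkdir(exist_ok=True)
        for sid, fm in features[kind].items():
            fm.to_csv(kdir / f"{sid}.csv")

    # --- glm -------------------------------------------------------------
    stage("glm")
    all_betas = []
    for session in subjects:
        betas = session_to_betas(session, mask, session.subject_id)
        betas.save(out / session.subject_id / "betas.npz")
        all_betas.append(betas)

    summary = {
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "seed": config.seed,
    }

    # --- decoding --------------------------------------------------------
    if config.do_decoding:
        stage("decode")
        k = min(config.n_select_voxels, int(mask.sum()))
        song_acc, genre_acc = [], []
        genre_confusions = None
        for betas in all_betas:
            acc_s, _ = run_decoding(
                betas, make_leave_run_out(betas), "song", k=k
            )
            acc_g, conf_g = run_decoding(
                betas,
                make_leave_stimulus_per_genre_out(betas, genres),
                "genre",
                genres=genres,
                k=k,
            )
            song_acc.append(acc_s)
            genre_acc.append(acc_g)
            gc = conf_g.normalize().counts
            genre_confusions = gc if genre_confusions is None else genre_confusions + gc
        genre_confusions /= len(all_betas)
        neural = ConfusionMatrix(genre_confusions, list(GENRES), normalized=True)
        behav = ConfusionMatrix(behavioral.to_numpy(), list(GENRES), normalized=True)
        rho, pval = confusion_spearman(neural, behav)
        song_mean, song_se = group_summary(song_acc)
        genre_mean, genre_se = group_summary(genre_acc)
        summary["decoding"] = {
            "song": {"per_subject": song_acc, "mean": song_mean, "se": song_se,
                     "chance": 1 / 25},
            "genre": {"per_subject": genre_acc, "mean": genre_mean, "se": genre_se,
                      "chance": 1 / 5},
            "confusion_spearman": {"rho": rho, "p": pval},
        }
        np.savetxt(out / "group_genre_confusions.csv", genre_confusions,
                   delimiter=",", header=",".join(GENRES), comments="")

    # --- searchlight + group stats --------------------------------------
    if config.do_searchlight:
        stage("searchlight")
        sl = config.searchlight
        gs = config.group
        scatter_offset = tuple(
            int(v) for v in rng.integers(0, sl.scatter_step, size=3)
        )
        summary["searchlight"] = {"scatter_offset": scatter_offset, "clusters": {}}
        for kind in config.feature_kinds:
            maps, nulls = [], []
            for betas in all_betas:
                slmap = run_searchlight(
                    betas,
                    features[kind],
                    genres,
                    mask,
                    affine=brain.affine,
                    radius=sl.radius,
                    scatter_step=sl.scatter_step,
                    repetitions=sl.repetitions,
                    rng_seed=int(rng.integers(2**31)),
                    ridge_lambda=sl.ridge_lambda,
                    min_sphere_voxels=sl.min_sphere_voxels,
                    scatter_offset=scatter_offset,
                )
                write_volume(
                    out / betas.subject_id / f"searchlight_{kind}.nii",
                    slmap.volume,
                    brain.affine,
                )
                maps.append(fill_scattered(slmap)[mask])
                nulls.append(
                    make_null_maps(
                        betas,
                        features[kind],
                        genres,
                        mask,
                        n_null=gs.n_null,
                        rng_seed=int(rng.integers(2**31)),
                        repetitions=gs.null_repetitions,
                        scatter_offset=scatter_offset,
                        affine=brain.affine,
                        radius=sl.radius,
                        scatter_step=sl.scatter_step,
                        ridge_lambda=sl.ridge_lambda,
                        min_sphere_voxels=sl.min_sphere_voxels,
                    )
                )
            stage(f"group-stats ({kind})")
            group_map = np.mean(maps, axis=0)
            null_set = NullMapSet(np.stack(nulls), mask, brain.affine)
            boot = bootstrap_group_null(
                null_set, n_bootstrap=gs.n_bootstrap,
                rng_seed=int(rng.integers(2**31)),
            )
            records = cluster_fwe(
                group_map, boot, mask, brain.affine,
                voxel_p=gs.voxel_p, cluster_p=gs.cluster_p,
                connectivity=gs.connectivity,
                label_volume=brain.region_labels,
                label_names={r: enc.feature_kind
                             for r, enc in brain.region_encoding.items()},
            )
            (out / f"clusters_{kind}.csv").write_text(clusters_to_csv(records))
            gvol = np.full(mask.shape, np.nan)
            gvol[mask] = group_map
            write_volume(out / f"group_map_{kind}.nii", gvol, brain.affine)
            summary["searchlight"]["clusters"][kind] = [
                {
                    "size": r.size,
                    "max": r.max,
                    "mean": r.mean,
                    "std": r.std,
                    "center_of_mass": r.center_of_mass,
                    "p_cluster": r.p_cluster,
                    "label": r.label,
                }
                for r in records
            ]

    summary["elapsed_seconds"] = time.time() - t0
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
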