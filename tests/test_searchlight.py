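import numpy as np
import pytest

import musicmvpa.searchlight as sl_module
from musicmvpa.music_features import fit_reduce
from musicmvpa.pipeline import session_to_betas
from musicmvpa.searchlight import (
    SearchlightMap,
    correlation_error_probability,
    enumerate_spheres,
    fill_scattered,
    fit_predict_ridge,
    run_searchlight,
    sphere_offsets,
)
from musicmvpa.synthetic_data import default_brain, generate_session


def brute_force_ball_count(radius):
    count = 0
    for x in range(-radius, radius + 1):
        for y in range(-radius, radius + 1):
            for z in range(-radius, radius + 1):
                if x * x + y * y + z * z <= radius * radius:
                    count += 1
    return count


class TestSphereGeometry:
    @pytest.mark.parametrize("radius,expected", [(1, 7), (2, 33), (3, 123)])
    def test_ball_sizes(self, radius, expected):
        assert brute_force_ball_count(radius) == expected  # independent oracle
        assert sphere_offsets(radius).shape[0] == expected

    def test_unbounded_mask_max_members(self):
        mask = np.ones((15, 15, 15), dtype=bool)
        spheres = enumerate_spheres(mask, radius=3, scatter_step=1,
                                    scatter_offset=(0, 0, 0))
        assert max(s.member_voxels.size for s in spheres) == 123

    def test_center_in_members(self):
        mask = np.ones((9, 9, 9), dtype=bool)
        for s in enumerate_spheres(mask, radius=2, scatter_step=3, rng_seed=0):
            flat = np.ravel_multi_index(s.center, mask.shape)
            assert flat in s.member_voxels

    def test_reflection_symmetry(self):
        offs = sphere_offsets(3)
        as_set = {tuple(o) for o in offs}
        assert as_set == {tuple(-o) for o in offs}

    def test_members_match_brute_force_on_random_mask(self):
        rng = np.random.default_rng(0)
        mask = rng.random((10, 10, 10)) < 0.6
        mask[4, 4, 4] = True
        spheres = enumerate_spheres(mask, radius=3, scatter_step=2,
                                    scatter_offset=(0, 0, 0))
        shape = mask.shape
        for s in spheres[:20]:
            cx, cy, cz = s.center
            expected = set()
            for x in range(shape[0]):
                for y in range(shape[1]):
                    for z in range(shape[2]):
                        if not mask[x, y, z]:
                            continue
                        if (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= 9:
                            expected.add(np.ravel_multi_index((x, y, z), shape))
            assert expected == set(s.member_voxels)

    def test_scatter_ratio_27(self):
        mask = np.ones((24, 24, 24), dtype=bool)
        n1 = len(enumerate_spheres(mask, scatter_step=1, scatter_offset=(0, 0, 0)))
        n3 = len(enumerate_spheres(mask, scatter_step=3, scatter_offset=(0, 0, 0)))
        assert n1 == 27 * n3

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enumerate_spheres(np.zeros((4, 4, 4), dtype=bool))


class TestFitPredictRidge:
    def test_small_lambda_matches_ols(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 3))
        Xt = rng.standard_normal((6, 5))
        pred = fit_predict_ridge(X, Y, Xt, ridge_lambda=1e-10)
        X1 = np.column_stack([np.ones(40), X])
        W, *_ = np.linalg.lstsq(X1, Y, rcond=None)
        ols = np.column_stack([np.ones(6), Xt]) @ W
        np.testing.assert_allclose(pred, ols, atol=1e-6)

    def test_large_lambda_shrinks_to_mean(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 4))
        Y = rng.standard_normal((20, 2))
        pred = fit_predict_ridge(X, Y, rng.standard_normal((5, 4)), 1e12)
        np.testing.assert_allclose(pred, np.tile(Y.mean(axis=0), (5, 1)), atol=1e-6)

    def test_closed_form_oracle_3x2(self):
        # hand-checkable 3-sample, 2-feature system
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([[1.0], [2.0], [3.0]])
        lam = 0.5
        xm, ym = X.mean(axis=0), y.mean(axis=0)
        Xc, yc = X - xm, y - ym
        W = np.linalg.inv(Xc.T @ Xc + lam * np.eye(2)) @ Xc.T @ yc
        Xt = np.array([[2.0, 1.0]])
        expected = (Xt - xm) @ W + ym
        np.testing.assert_allclose(
            fit_predict_ridge(X, y, Xt, lam), expected, atol=1e-12
        )

    def test_dual_equals_primal(self):
        rng = np.random.default_rng(2)
        Xw = rng.standard_normal((10, 30))  # wide: dual path
        Y = rng.standard_normal((10, 4))
        Xt = rng.standard_normal((3, 30))
        lam = 2.0
        xm, ym = Xw.mean(axis=0), Y.mean(axis=0)
        Xc = Xw - xm
        W = np.linalg.solve(Xc.T @ Xc + lam * np.eye(30), Xc.T @ (Y - ym))
        np.testing.assert_allclose(
            fit_predict_ridge(Xw, Y, Xt, lam), (Xt - xm) @ W + ym, atol=1e-8
        )

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            fit_predict_ridge(np.eye(3), np.eye(3), np.eye(3), 0.0)


class TestCorrelationErrorProbability:
    def test_perfect_prediction_scores_near_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 2.5])
        score, constant = correlation_error_probability(v, v)
        assert not constant
        assert score > 0.999

    def test_constant_vector_flagged_zero(self):
        score, constant = correlation_error_probability(
            np.ones(5), np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        )
        assert score == 0.0 and constant

    def test_null_scores_uniform(self):
        # independent noise: 1 - p is uniform on [0, 1], mean 0.5
        rng = np.random.default_rng(0)
        scores = [
            correlation_error_probability(
                rng.standard_normal(20), rng.standard_normal(20)
            )[0]
            for _ in range(400)
        ]
        se = 1.0 / np.sqrt(12 * len(scores))
        assert abs(np.mean(scores) - 0.5) < 3 * se

    def test_matches_permutation_p(self):
        # parametric p vs permutation p on n = 20 toys
        rng = np.random.default_rng(1)
        n_perm = 4000
        for _ in range(5):
            x = rng.standard_normal(20)
            y = 0.5 * x + rng.standard_normal(20)
            score, _ = correlation_error_probability(x, y)
            p_param = 1.0 - score
            r_obs = abs(np.corrcoef(x, y)[0, 1])
            exceed = 0
            for _ in range(n_perm):
                r = np.corrcoef(x, rng.permutation(y))[0, 1]
                exceed += abs(r) >= r_obs
            p_perm = (exceed + 1) / (n_perm + 1)
            mc_err = 3 * np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
            assert abs(p_param - p_perm) < mc_err + 0.01

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(2)
        pred = rng.standard_normal((8, 15))
        obs = rng.standard_normal((8, 15))
        r = sl_module._rowwise_pearson(pred, obs)
        m = np.full(8, 15.0)
        scores = sl_module._cep_from_r(r, m, np.zeros(8, dtype=bool))
        for i in range(8):
            expected, _ = correlation_error_probability(pred[i], obs[i])
            assert scores[i] == pytest.approx(expected, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            correlation_error_probability(np.ones(2), np.ones(2))


@pytest.fixture(scope="module")
def planted_subject(stimuli, feature_matrices, reduced_features, feature_dims):
    brain = default_brain(feature_dims, shape=(12, 12, 12), snr=20.0, rng_seed=4)
    vectors = {k: r.vectors for k, r in reduced_features.items()}
    session = generate_session(
        brain, stimuli, vectors, rng_seed=5, dtype=np.float32
    )
    betas = session_to_betas(session, np.ones((12, 12, 12), dtype=bool))
    return brain, betas


class TestRunSearchlight:
    def test_400_tests_per_sphere(self, planted_subject, feature_matrices, genres):
        _, betas = planted_subject
        slmap = run_searchlight(
            betas, feature_matrices["chroma"], genres,
            np.ones((12, 12, 12), bool), repetitions=10, rng_seed=0,
        )
        assert slmap.n_tests == 5 * 8 * 10  # = 400

    def test_planted_sphere_high_accuracy(
        self, stimuli, feature_matrices, reduced_features, genres
    ):
        # a sphere lying entirely inside a planted region scores near 1
        from musicmvpa.synthetic_data import GroundTruthBrain, RegionEncoding

        shape = (12, 12, 12)
        labels = np.zeros(shape, dtype=np.int16)
        labels[2:10, 2:10, 2:10] = 1
        d = len(next(iter(reduced_features["chroma"].vectors.values())))
        rng = np.random.default_rng(8)
        brain = GroundTruthBrain(
            shape=shape, affine=np.eye(4), region_labels=labels,
            region_encoding={
                1: RegionEncoding(
                    "chroma", rng.standard_normal(((labels == 1).sum(), d)),
                    snr=20.0,
                )
            },
        )
        session = generate_session(
            brain, stimuli, {"chroma": reduced_features["chroma"].vectors},
            rng_seed=9, dtype=np.float32,
        )
        betas = session_to_betas(session, np.ones(shape, dtype=bool))
        slmap = run_searchlight(
            betas, feature_matrices["chroma"], genres, np.ones(shape, bool),
            repetitions=10, rng_seed=1, scatter_offset=(0, 0, 0),
        )
        assert slmap.volume[6, 6, 6] > 0.95  # sphere spans 3..9: fully planted

    def test_background_at_chance(self, planted_subject, feature_matrices, genres):
        brain, betas = planted_subject
        mask = np.ones((12, 12, 12), dtype=bool)
        slmap = run_searchlight(
            betas, feature_matrices["chroma"], genres, mask,
            repetitions=10, rng_seed=1, scatter_offset=(0, 0, 0),
        )
        from scipy.ndimage import binary_dilation

        computed = np.isfinite(slmap.volume)
        halo = binary_dilation(brain.region_labels > 0, iterations=4)
        far = computed & ~halo
        assert far.any()
        assert abs(np.nanmean(slmap.volume[far]) - 0.5) < 0.12

    def test_heldout_never_trained(
        self, planted_subject, feature_matrices, genres, monkeypatch
    ):
        # structural: every refit uses 20 train stimuli, and the excluded 5
        # are one per genre
        _, betas = planted_subject
        calls = []
        original = fit_reduce

        def spy(features, train_ids, **kwargs):
            calls.append(list(train_ids))
            return original(features, train_ids, **kwargs)

        monkeypatch.setattr(sl_module, "fit_reduce", spy)
        run_searchlight(
            betas, feature_matrices["melody_abs"], genres,
            np.ones((12, 12, 12), bool), repetitions=4, rng_seed=2,
        )
        assert len(calls) == 4
        all_ids = set(feature_matrices["melody_abs"])
        for train_ids in calls:
            held = all_ids - set(train_ids)
            assert len(train_ids) == 20 and len(held) == 5
            assert len({genres[sid] for sid in held}) == 5

    def test_seeded_determinism(self, planted_subject, feature_matrices, genres):
        _, betas = planted_subject
        mask = np.ones((12, 12, 12), bool)
        m1 = run_searchlight(betas, feature_matrices["chroma"], genres, mask,
                             repetitions=2, rng_seed=7)
        m2 = run_searchlight(betas, feature_matrices["chroma"], genres, mask,
                             repetitions=2, rng_seed=7)
        np.testing.assert_array_equal(m1.volume, m2.volume)
        assert m1.scatter_offset == m2.scatter_offset

    def test_feature_specific_recovery(
        self, stimuli, feature_matrices, reduced_features, genres
    ):
        # plant ONLY melody_rel weights: melody_rel maps must beat chroma maps
        # inside the planted region, across seeds
        from musicmvpa.synthetic_data import GroundTruthBrain, RegionEncoding

        shape = (10, 10, 10)
        labels = np.zeros(shape, dtype=np.int16)
        labels[3:7, 3:7, 4:6] = 1
        d = len(next(iter(reduced_features["melody_rel"].vectors.values())))
        wins = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            brain = GroundTruthBrain(
                shape=shape,
                affine=np.eye(4),
                region_labels=labels,
                region_encoding={
                    1: RegionEncoding(
                        "melody_rel", rng.standard_normal(((labels == 1).sum(), d)),
                        snr=10.0,
                    )
                },
            )
            vectors = {"melody_rel": reduced_features["melody_rel"].vectors}
            session = generate_session(
                brain, stimuli, vectors, rng_seed=seed + 50, dtype=np.float32
            )
            betas = session_to_betas(session, np.ones(shape, dtype=bool))
            mask = np.ones(shape, dtype=bool)
            scores = {}
            for kind in ("melody_rel", "chroma"):
                m = run_searchlight(
                    betas, feature_matrices[kind], genres, mask,
                    repetitions=5, rng_seed=seed, scatter_offset=(1, 1, 1),
                )
                sel = np.isfinite(m.volume) & (labels == 1)
                scores[kind] = np.nanmean(m.volume[sel])
            wins += scores["melody_rel"] > scores["chroma"]
        assert wins == 3


class TestFillScattered:
    def test_nearest_fill(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        volume = np.full((4, 4, 4), np.nan)
        volume[0, 0, 0] = 1.0
        volume[3, 3, 3] = 2.0
        slmap = SearchlightMap(volume=volume, mask=mask, affine=np.eye(4))
        filled = fill_scattered(slmap)
        assert filled[0, 0, 1] == 1.0
        assert filled[3, 3, 2] == 2.0
        assert np.isfinite(filled).all()

    def test_outside_mask_nan(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2] = True
        volume = np.full((4, 4, 4), np.nan)
        volume[0, 0, 0] = 1.0
        slmap = SearchlightMap(volume=volume, mask=mask, affine=np.eye(4))
        filled = fill_scattered(slmap)
        assert np.isnan(filled[3, 3, 3])
        assert filled[1, 1, 1] == 1.0
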