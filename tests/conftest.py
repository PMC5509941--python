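import numpy as np
import pytest

from musicmvpa.music_features import fit_reduce
from musicmvpa.pipeline import build_feature_matrices, session_to_betas
from musicmvpa.synthetic_data import (
    GroundTruthBrain,
    default_stimuli,
    generate_session,
)

KINDS = ("melody_abs", "melody_rel", "chroma")


@pytest.fixture(scope="session")
def stimuli():
    return default_stimuli()


@pytest.fixture(scope="session")
def genres(stimuli):
    return {s.stimulus_id: s.genre for s in stimuli}


@pytest.fixture(scope="session")
def feature_matrices(stimuli):
    return build_feature_matrices(stimuli, rng_seed=0)


@pytest.fixture(scope="session")
def reduced_features(stimuli, feature_matrices):
    ids = [s.stimulus_id for s in stimuli]
    return {k: fit_reduce(feature_matrices[k], ids) for k in KINDS}


@pytest.fixture(scope="session")
def feature_dims(reduced_features):
    return {k: r.basis.shape[1] * 60 for k, r in reduced_features.items()}


def make_noise_brain(shape=(6, 6, 6)):
    """A brain with no planted regions: every voxel is pure noise."""
    return GroundTruthBrain(
        shape=tuple(shape),
        affine=np.eye(4),
        region_labels=np.zeros(shape, dtype=np.int16),
        region_encoding={},
    )


def make_noise_betas(stimuli, seed, shape=(6, 6, 6), n_runs=8):
    """Signal-free betas from the full forward + GLM pipeline."""
    brain = make_noise_brain(shape)
    session = generate_session(
        brain, stimuli, {}, rng_seed=seed, n_runs=n_runs, dtype=np.float32
    )
    return session_to_betas(session, np.ones(shape, dtype=bool))


@pytest.fixture(scope="session")
def noise_betas(stimuli):
    return make_noise_betas(stimuli, seed=123)
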