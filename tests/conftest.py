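import dataclasses

import numpy as np
import pytest

import strabscreen as ss


@pytest.fixture(scope="session")
def default_spec() -> ss.EyeSceneSpec:
    return ss.EyeSceneSpec()


@pytest.fixture(scope="session")
def rendered_pair(default_spec):
    """Noiseless, zero-deviation scene with centred reflexes."""
    return ss.render_eye_pair(default_spec)


@pytest.fixture(scope="session")
def deviated_pair(default_spec):
    spec = dataclasses.replace(
        default_spec,
        iris_center_offset_right=(12.0, 3.0),
        reflex_offset_right=(-5.0, -1.0),
    )
    return ss.render_eye_pair(spec)


@pytest.fixture(scope="session")
def embedding_provider():
    return ss.get_provider("random-projection")


@pytest.fixture(scope="session")
def cohort_scenes():
    """Noiseless 60-scene cohort with the reference missing-reflex mix
    (8 of 30 normal and 13 of 30 strabismic photographed without a pen
    torch)."""
    return ss.make_dataset(30, 30, seed=11,
                           reflex_missing_rate=(8 / 30, 13 / 30))


@pytest.fixture(scope="session")
def cohort_records(cohort_scenes, embedding_provider):
    """The cohort pushed through the full image pipeline."""
    return ss.process_synthetic_cohort(cohort_scenes, embedding_provider)


def truth_position_features(truth) -> ss.PositionFeatures:
    """Position features computed from exact ground-truth geometry."""
    return ss.position_similarity(
        truth.pupil_center_right, truth.pupil_center_left,
        truth.canthus_medial_right, truth.canthus_lateral_right,
        truth.canthus_medial_left, truth.canthus_lateral_left,
    )


def shuffle_labels(records, seed=0):
    """Reassign the cohort's labels at random, keeping class sizes."""
    rng = np.random.default_rng(seed)
    labels = [r.label for r in records]
    perm = rng.permutation(len(labels))
    return [dataclasses.replace(r, label=labels[perm[i]])
            for i, r in enumerate(records)]


def null_accuracy(records, n_shuffles=10, n_experiments_each=50, seed=0):
    """Mean accuracy under the label-randomization null.

    A single shuffle retains chance feature-label association across every
    split, so the null averages over several independent shuffles as well
    as over splits.
    """
    means = []
    for i in range(n_shuffles):
        null = shuffle_labels(records, seed=seed + i)
        rep = ss.evaluate(null, n_experiments=n_experiments_each,
                          base_seed=seed + 1000 + i)
        means.append(rep.accuracy_mean)
    return float(np.mean(means))
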