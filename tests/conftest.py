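import pytest

from mptissue.mpmri_io import normalize_channels
from mptissue.phantom import PhantomSpec, default_phantom_spec, generate_cohort, generate_phantom
from mptissue.signatures import sample_balanced, signature_sets_from_labels
from mptissue.ssae_seg import SsaeTrainConfig


SMALL_GRID = dict(grid_shape=(20, 20, 6), lesion_radius_voxels=3.0)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(default_phantom_spec("malignant", seed=7, **SMALL_GRID))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(
        default_phantom_spec("malignant", seed=7, noise_sd=0.0, **SMALL_GRID))


@pytest.fixture(scope="session")
def tiny_cohort():
    base = PhantomSpec(**SMALL_GRID)
    return generate_cohort(4, benign_fraction=0.5, base_spec=base, seed=11)


@pytest.fixture(scope="session")
def fast_cfg():
    """Reduced-epoch training config for unit tests."""
    return SsaeTrainConfig(max_epochs=120, head_epochs=300,
                           fine_tune_epochs=200, seed=0)


@pytest.fixture(scope="session")
def tiny_training_set(tiny_cohort):
    normalized = [normalize_channels(ph.study) for ph in tiny_cohort]
    sets = [
        s for i, ph in enumerate(tiny_cohort)
        for s in signature_sets_from_labels(normalized[i], ph.truth_labels,
                                            max_per_class=300, seed=i)
    ]
    return sample_balanced(sets, cap_per_class=300, seed=0)


@pytest.fixture(scope="session")
def tiny_normalized(tiny_cohort):
    return [normalize_channels(ph.study) for ph in tiny_cohort]
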