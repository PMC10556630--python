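import numpy as np
import pytest

from counterstream import cg_tasks
from counterstream.scene_synth import SceneSpec, sample_scene


@pytest.fixture(scope="session")
def tiny_chargrid_split():
    """Small 6-class chargrid split reused across model/task tests."""
    return cg_tasks.make_chargrid_dataset(
        n_images=40, n_classes=6, chars_per_image=6, examples_per_image=5,
        seed=11, n_test_nc=30, n_test_cg=30,
    )


@pytest.fixture(scope="session")
def tiny_chargrid_config(tiny_chargrid_split):
    return cg_tasks.chargrid_task_config(tiny_chargrid_split)


@pytest.fixture(scope="session")
def tiny_persons_split():
    return cg_tasks.make_persons_dataset(
        n_images=40, n_person_identities=6, excluded_pairs=4, seed=5,
        n_test_nc=30, n_test_cg=30,
    )


@pytest.fixture(scope="session")
def small_scene():
    return sample_scene(SceneSpec(n_persons=2, n_objects=1), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
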