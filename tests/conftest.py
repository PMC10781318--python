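import numpy as np
import pytest

import thermoface as tf


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_separable_session():
    """In-memory separable session, reduced size for unit tests."""
    cfg = tf.separable_config(seed=7, n_subjects=4, image_shape=(120, 160))
    return tf.generate_dataset(cfg)


@pytest.fixture(scope="session")
def noise_free_session():
    """All noise terms zero: stamped ROI values should survive the pipeline."""
    cfg = tf.table1_config(
        seed=3,
        n_subjects=2,
        image_shape=(120, 160),
        sd_total={r: 0.0 for r in tf.ROI_NAMES},
        subject_sd_fraction=0.0,
        pixel_texture_sd=0.0,
    )
    return tf.generate_dataset(cfg)


@pytest.fixture(scope="session")
def session_dir(tmp_path_factory):
    """A small separable session written to disk (frames, sidecars, landmarks)."""
    out = tmp_path_factory.mktemp("session")
    cfg = tf.separable_config(seed=11, n_subjects=3, image_shape=(120, 160))
    session = tf.generate_dataset(cfg, out_dir=out)
    return out, session
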