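import numpy as np
import pytest

from rdwkit.synthetic_data import SceneConfig, generate_dataset, longtail_counts


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """30 small scenes with a long-tailed 4-class distribution, split 70:20:10."""
    root = tmp_path_factory.mktemp("ds") / "scenes"
    cfg = SceneConfig(
        image_size=(32, 32),
        num_classes=4,
        per_class_counts=tuple(int(c) for c in longtail_counts(4)),
        seed=11,
    )
    return generate_dataset(cfg, 30, root)


def random_box(rng, span=10.0):
    from rdwkit.boxes import BoxXYWH

    return BoxXYWH(
        cx=float(rng.uniform(-span, span)),
        cy=float(rng.uniform(-span, span)),
        w=float(rng.uniform(0.1, span)),
        h=float(rng.uniform(0.1, span)),
    )
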