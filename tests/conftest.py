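import numpy as np
import pytest

from polamat import SceneSpec, render_sample, write_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def normal_bundle():
    """Noiseless float-rendered normal-class sample, 32x32."""
    return render_sample(SceneSpec(width=32, height=32, class_label="normal", seed=7))


@pytest.fixture(scope="session")
def cancer_bundle():
    return render_sample(SceneSpec(width=32, height=32, class_label="cancer", seed=8))


@pytest.fixture(scope="session")
def uint8_dataset(tmp_path_factory):
    """A small written dataset: 3 normal + 3 cancer uint8 RGB samples."""
    root = tmp_path_factory.mktemp("colopola")
    bundles = [
        render_sample(
            SceneSpec(width=24, height=24, class_label=lab, seed=50 + i,
                      quantization="uint8")
        )
        for i, lab in enumerate(["normal"] * 3 + ["cancer"] * 3)
    ]
    manifest = write_dataset(bundles, root, split_fraction=2 / 3, seed=0)
    return root, manifest, bundles
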