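import numpy as np
import pytest

from nsseg.synthetic import LesionParams, generate_dataset, generate_sample


@pytest.fixture(scope="session")
def params32() -> LesionParams:
    return LesionParams(image_size=32)


@pytest.fixture(scope="session")
def params64() -> LesionParams:
    return LesionParams(image_size=64)


@pytest.fixture(scope="session")
def sample_arrays32(params32):
    """Twelve small generated (image, mask) pairs as stacked arrays."""
    images, masks = [], []
    for i in range(12):
        img, m = generate_sample(params32, 500 + i)
        images.append(img)
        masks.append(m.values)
    return np.stack(images), np.stack(masks)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, params32):
    """A 12-sample on-disk dataset (8 train / 2 val / 2 test) at 32 px."""
    out = tmp_path_factory.mktemp("tinydata")
    manifest = generate_dataset(
        12, params32, seed=900, out_dir=out, split_fractions=(0.67, 0.17, 0.16)
    )
    return manifest


class LookupModel:
    """Oracle 'model' returning a stored probability map per image content."""

    def __init__(self, mapping):
        # keys are image byte digests, values probability maps
        self._mapping = mapping

    def __call__(self, image):
        return self._mapping[image.tobytes()]


@pytest.fixture()
def oracle_model_factory():
    def build(manifest):
        from nsseg.datamodel import load_sample

        mapping = {}
        for rec in manifest:
            img, mask = load_sample(rec, manifest.target_size)
            mapping[img.tobytes()] = mask.values.astype(np.float64)
        return LookupModel(mapping)

    return build
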