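import numpy as np
import pytest

from radiopath.image_io import ImageVolume, RoiMask, write_volume


@pytest.fixture
def write_nifti(tmp_path):
    """Write an array (+spacing) as NIfTI and return the path."""

    def _write(name, data, spacing=(1.0, 1.0, 1.0), as_mask=False):
        path = tmp_path / name
        obj = RoiMask(np.asarray(data), spacing) if as_mask else ImageVolume(
            np.asarray(data, dtype=np.float64), spacing
        )
        write_volume(obj, path)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
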