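import numpy as np
import pytest

import fibrilsaxs as fs
from fibrilsaxs.synthetic import default_analysis_config


@pytest.fixture(scope="session")
def default_spec():
    return fs.SyntheticSpec()


@pytest.fixture(scope="session")
def default_pattern(default_spec):
    pattern, truth = fs.generate(default_spec)
    return pattern, truth


@pytest.fixture(scope="session")
def default_config(default_spec):
    return default_analysis_config(default_spec)


@pytest.fixture(scope="session")
def synthetic_image(tmp_path_factory, default_pattern):
    """Default noiseless pattern saved as float32 TIFF."""
    pattern, truth = default_pattern
    path = tmp_path_factory.mktemp("synth") / "synthetic.tif"
    fs.save_pattern(pattern, path)
    return path, truth


@pytest.fixture(scope="session")
def pipeline_row(default_config, synthetic_image):
    """Structure parameters recovered end-to-end from the default pattern."""
    path, truth = synthetic_image
    row = fs.run_single(default_config, path)
    return row, truth


def make_flat_pattern(value=5.0, shape=(64, 64)):
    return fs.Pattern(np.full(shape, float(value)), np.ones(shape, bool), "flat")
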