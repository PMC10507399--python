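import numpy as np
import pytest

from cytosweep import synth


@pytest.fixture(scope="session")
def design():
    """Small multi-file, multi-batch design with the five default populations."""
    return synth.default_design(n_files=4, events_per_file=300, seed=7)


@pytest.fixture(scope="session")
def dataset(design):
    """(CellTable with ground truth, file metadata, marker metadata)."""
    return synth.generate_dataset(design)


@pytest.fixture(scope="session")
def run_inputs(tmp_path_factory):
    """A complete on-disk input set (FCS dir, metadata CSVs, config, truth)."""
    root = tmp_path_factory.mktemp("run_inputs")
    design = synth.default_design(n_files=3, events_per_file=250, seed=11)
    return synth.write_run_inputs(design, root), design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
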