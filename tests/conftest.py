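import numpy as np
import pytest

from sheetbuild.fixtures import (
    MapSpec,
    SheetSpec,
    build_ideal_strand,
    build_sheet,
    density_from_model,
    truth_table,
)


@pytest.fixture(scope="session")
def sheet_model():
    """Standard fixture: 4 antiparallel strands x 6 residues, 4.5 A apart."""
    return build_sheet(SheetSpec(n_strands=4, residues_per_strand=6))


@pytest.fixture(scope="session")
def sheet_truth(sheet_model):
    return truth_table(sheet_model)


@pytest.fixture(scope="session")
def sheet_grid(sheet_model):
    """Noise-free model density of the standard sheet at 2.5 A."""
    return density_from_model(sheet_model, MapSpec(resolution=2.5))


@pytest.fixture(scope="session")
def strand_model():
    return build_ideal_strand(10)


@pytest.fixture(scope="session")
def strand_grid(strand_model):
    return density_from_model(strand_model, MapSpec(resolution=2.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
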