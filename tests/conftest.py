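import numpy as np
import pytest

from perimem.materials import SolventContrast
from perimem.slabs import (
    BilayerParams,
    DMPC_DMPG_11,
    ProteinParams,
    SubstrateParams,
    build_stack,
)


@pytest.fixture(scope="session")
def q_grid():
    return np.logspace(np.log10(0.008), np.log10(0.3), 150)


@pytest.fixture(scope="session")
def bilayer_alone_stack():
    """Protein-free hydrogenated bilayer at the 95% D2O contrast."""
    return build_stack(
        SubstrateParams(14.0, 0.75, 3.0, 5.0),
        BilayerParams(60.0, 3.0, 4.0, 5.0, 3.0, 0.0),
        DMPC_DMPG_11,
        SolventContrast(0.95),
    )


@pytest.fixture(scope="session")
def with_protein_params():
    """Truth parameters of the with-protein hydrogenated condition."""
    return dict(
        substrate=SubstrateParams(14.0, 0.75, 3.0, 5.0),
        bilayer=BilayerParams(45.0, 10.0, 17.0, 8.0, 4.0, 11.0),
        protein=ProteinParams(84.0, 0.26, 3.0, 0.39),
    )
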