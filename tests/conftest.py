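import numpy as np
import pandas as pd
import pytest

from dommech.data_io import StructureRecord
from dommech.synthetic_data import SyntheticSpec, gen_all


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic cohort shared by read-only tests."""
    spec = SyntheticSpec(
        seed=7, n_genes=300, n_embedding_dims=32, n_informative_embeddings=3,
        n_families=8,
    )
    return gen_all(spec)


@pytest.fixture()
def toy_structure():
    """Deterministic 10-residue straight chain, fully confident, fully exposed."""
    n = 10
    coords = np.zeros((n, 3))
    coords[:, 0] = 3.8 * np.arange(n)
    return StructureRecord(
        protein="TOY",
        positions=np.arange(1, n + 1),
        aa=np.array(list("ACDEFGHIKL")),
        coords=coords,
        plddt=np.full(n, 95.0),
        asa=np.full(n, 100.0),
        scriber=np.linspace(0.1, 1.0, n),
    )


@pytest.fixture()
def trio_frame():
    rng = np.random.default_rng(0)
    n = 200
    return pd.DataFrame(
        {
            "pDN": rng.uniform(size=n),
            "pGOF": rng.uniform(size=n),
            "pLOF": rng.uniform(size=n),
        },
        index=[f"P{i:04d}" for i in range(n)],
    )
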