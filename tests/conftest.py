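import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from quartpac.fixtures import ChainSpec, FixtureSpec, make_structure


@pytest.fixture(scope="session")
def two_line_structure():
    """Two parallel 150-residue lines 5 Å apart (the canonical dimer)."""
    spec = FixtureSpec(
        chains=[
            ChainSpec(length=150, geometry="line", accession="P10001",
                      chain_id="A"),
            ChainSpec(length=150, geometry="line", accession="P10002",
                      chain_id="B", offset=(0.0, 5.0, 0.0)),
        ],
        seed=0,
        structure_id="DIMER",
    )
    structure, pdb_text = make_structure(spec)
    return spec, structure, pdb_text


@pytest.fixture(scope="session")
def helix_trimer():
    spec = FixtureSpec(
        chains=[
            ChainSpec(length=20, geometry="ideal_helix", accession="P20001",
                      chain_id="A"),
            ChainSpec(length=20, geometry="ideal_helix", accession="P20002",
                      chain_id="B", offset=(12.0, 0.0, 0.0)),
            ChainSpec(length=20, geometry="ideal_helix", accession="P20003",
                      chain_id="C", offset=(0.0, 12.0, 0.0)),
        ],
        seed=3,
        structure_id="TRIMER",
    )
    structure, pdb_text = make_structure(spec)
    return spec, structure, pdb_text


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
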