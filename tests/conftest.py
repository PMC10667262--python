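import numpy as np
import pytest

from gba1pd.fixtures import (
    fixture_72,
    fixture_exclusion,
    fixture_full,
    fixture_table1,
    load_vus_fixture,
)
from gba1pd.variants import load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def fx72():
    return fixture_72()


@pytest.fixture(scope="session")
def fxfull():
    return fixture_full()


@pytest.fixture(scope="session")
def cohort_exclusion():
    return fixture_exclusion()


@pytest.fixture(scope="session")
def cohort_table1():
    return fixture_table1()


@pytest.fixture(scope="session")
def vus_table():
    return load_vus_fixture()


def pdb_atom(serial, name, resname, resseq, x, y, z, occ=1.0, altloc=" ", chain="A"):
    return (
        f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           C"
    )


def toy_pdb(residues, chain="A"):
    """residues: iterable of (resseq, resname, (x, y, z)) -> Calpha-only PDB text."""
    lines = [
        pdb_atom(i + 1, "CA", resname, resseq, *xyz, chain=chain)
        for i, (resseq, resname, xyz) in enumerate(residues)
    ]
    return "\n".join(lines + ["END"]) + "\n"


@pytest.fixture
def toy_model_text():
    return toy_pdb(
        [
            (1, "ALA", (0.0, 0.0, 0.0)),
            (2, "GLY", (3.0, 4.0, 0.0)),
            (3, "SER", (6.0, 0.0, 0.0)),
            (4, "LEU", (20.0, 0.0, 0.0)),
        ]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230595)
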