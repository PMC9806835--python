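import numpy as np
import pytest

from confscan.backends import ToyTorsionalPES, random_pes, toy_chain_geometry
from confscan.io import (
    load_benchmark_ledger,
    load_benchmark_table,
    load_seed_geometry,
    load_seed_torsions,
)


@pytest.fixture(scope="session")
def cysteine_seed():
    return load_seed_geometry()


@pytest.fixture(scope="session")
def cysteine_torsions():
    return load_seed_torsions()


@pytest.fixture(scope="session")
def neutral_table():
    return load_benchmark_table("neutral")


@pytest.fixture(scope="session")
def site_tables():
    return {s: load_benchmark_table(s) for s in ("N", "O", "S")}


@pytest.fixture(scope="session")
def pa_gb_table():
    return load_benchmark_table("pa_gb")


@pytest.fixture(scope="session")
def neutral_ledger():
    return load_benchmark_ledger("neutral")


@pytest.fixture(scope="session")
def chain2():
    """5-atom chain with two rotatable bonds."""
    return toy_chain_geometry(2)


@pytest.fixture(scope="session")
def pes2():
    """Seeded 2-torsion multi-well potential used across search tests."""
    return random_pes(2, seed=3)


@pytest.fixture(scope="session")
def cosine_pes():
    """Analytically trivial PES: one cosine per coordinate.

    Wells at (120°, 240°) with V=0; saddles where exactly one
    coordinate sits on its barrier top.
    """
    return ToyTorsionalPES(
        amplitudes=(
            ((1, 2.0, np.radians(120.0)),),
            ((1, 3.0, np.radians(240.0)),),
        )
    )
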