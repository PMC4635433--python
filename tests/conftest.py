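import numpy as np
import pytest

from ctrace.cli_io import default_parameter_table
from ctrace.model_core import (
    N_POOLS,
    BiomeParameterSet,
    PoolLayout,
    SoilTexture,
    TransferSystem,
    build_transfer_system,
)
from ctrace.synthetic_data import generate_grid


@pytest.fixture(scope="session")
def layout():
    return PoolLayout()


@pytest.fixture(scope="session")
def table():
    return default_parameter_table()


@pytest.fixture(scope="session")
def loam():
    return SoilTexture.from_clay_silt(0.20, 0.35, porosity=0.45)


@pytest.fixture(scope="session")
def dbf_params(table):
    return table["DBF"]


@pytest.fixture(scope="session")
def gra_params(table):
    return table["GRA"]


@pytest.fixture(scope="session")
def dbf_system(dbf_params, loam):
    return build_transfer_system(dbf_params, loam)


@pytest.fixture(scope="session")
def small_grid():
    return generate_grid(shape=(6, 6), seed=42)


def random_transfer_system(seed: int, n: int = N_POOLS) -> TransferSystem:
    """Random valid n-pool system: unit diagonal A, column transfer sums <= 1,
    acyclic routing (strictly lower-triangular transfers), positive rates."""
    rng = np.random.default_rng(seed)
    A = np.eye(n)
    for j in range(n - 1):
        # always feed the next pool so every pool holds carbon at equilibrium
        receivers = [j + 1]
        if j + 2 < n:
            receivers.append(int(rng.integers(j + 2, n)))
        fracs = rng.uniform(0.05, 0.45, size=len(receivers))
        total = fracs.sum()
        if total > 0.95:
            fracs *= 0.95 / total
        for r, f in zip(receivers, fracs):
            A[r, j] -= f
    c = rng.uniform(0.02, 2.0, size=n)
    B = np.zeros(n)
    k = rng.integers(1, min(4, n) + 1)
    alloc = rng.dirichlet(np.ones(k))
    B[:k] = alloc
    return TransferSystem(A=A, C=np.diag(c), B=B)


def random_xi(seed: int, n: int = N_POOLS) -> np.ndarray:
    rng = np.random.default_rng(seed + 10_000)
    diag = rng.uniform(0.05, 1.0, size=n)
    diag[:4] = 1.0
    return np.diag(diag)
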