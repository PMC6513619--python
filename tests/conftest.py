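"""Shared small simulation fixtures (session-scoped to amortize numba JIT)."""

import numpy as np
import pytest

from heterospread import SimConfig, auto_lattice_size, run_colony, run_linear


@pytest.fixture(scope="session")
def small_colony():
    """Homogeneous radial colony, N=2000, with mutations."""
    cfg = SimConfig(L=151, rho=0.0, k=0.0, s=0.0, mu=0.01, N_target=2000, seed=42)
    return run_colony(cfg)


@pytest.fixture(scope="session")
def disordered_colony():
    """Radial colony at rho=0.3, k=0 that reaches its target size."""
    for seed in range(100, 140):
        cfg = SimConfig(L=201, rho=0.3, k=0.0, mu=0.01, N_target=3000, seed=seed)
        r = run_colony(cfg)
        if r.terminated_by == "reached_N":
            return r
    raise RuntimeError("no rho=0.3 colony reached its target size")


@pytest.fixture(scope="session")
def small_linear():
    """Homogeneous linear run to modest height."""
    cfg = SimConfig(L=64, geometry="linear", rho=0.0, h_target=100, seed=7)
    return run_linear(cfg)


@pytest.fixture(scope="session")
def neutral_ensemble():
    """20 homogeneous colonies at N=20000, mu=5e-4 (clone statistics)."""
    L = auto_lattice_size(20000, 0.0)
    return [
        run_colony(SimConfig(L=L, rho=0.0, mu=5e-4, N_target=20000, seed=5000 + i))
        for i in range(20)
    ]
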