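import numpy as np
import pytest

import dll2d


@pytest.fixture(scope="session")
def free_liquid_stores():
    """Obstacle- and dimer-free runs (pure cooperative solvent), L=32."""
    stores = []
    for k in range(2):
        st = dll2d.initialize_system(32, 0.0, 0.0, seed=4000 + k)
        stores.append(dll2d.run_trajectory(st, 2000))
    return stores


@pytest.fixture(scope="session")
def dimer_liquid_stores():
    """c=0, d=0.5 ensemble used by observable and fit tests, L=32."""
    stores = []
    for k in range(2):
        st = dll2d.initialize_system(32, 0.0, 0.5, seed=4100 + k)
        stores.append(dll2d.run_trajectory(st, 2000))
    return stores


def make_store(times, disp, sites=None, e2e=None, obj_species=None, dimers=None, L=16):
    """Assemble a synthetic TrajectoryStore from plain arrays."""
    times = np.asarray(times, dtype=np.int64)
    disp = np.asarray(disp, dtype=float)
    k, n, _ = disp.shape
    if sites is None:
        sites = np.zeros((k, n), np.int32) + np.arange(n, dtype=np.int32)
    if obj_species is None:
        obj_species = np.zeros(n, np.int8)  # all solvent
    if dimers is None:
        dimers = np.empty((0, 2), np.int32)
    if e2e is None:
        e2e = np.empty((k, len(dimers), 2))
    hist = np.zeros(L * L + 1, np.int64)
    return dll2d.TrajectoryStore(
        times=times,
        disp=disp,
        sites=np.asarray(sites, np.int32),
        e2e=np.asarray(e2e, dtype=float),
        obj_species=np.asarray(obj_species, np.int8),
        dimers=np.asarray(dimers, np.int32),
        L=L,
        decade_stats=np.zeros((1, 6), np.int64),
        found_hist=hist.copy(),
        accepted_hist=hist.copy(),
    )
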