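import numpy as np
import pytest

from dichopt.hrf import BlockHRF
from dichopt.laminar import equivolume_depth, sample_ribbon
from dichopt.synth import make_block_design, make_cortical_ribbon
from dichopt.synth.boldsim import LaminarTruth, simulate_bold_run


@pytest.fixture(scope="session")
def slab():
    """Parallel-surface ribbon with its voxel grid and depth volume."""
    mesh = make_cortical_ribbon("slab", 400, thickness=2.0, extent=12.0)
    grid = sample_ribbon(mesh, voxel_size=0.4)
    depth = equivolume_depth(mesh, grid)
    return mesh, depth.grid, depth


@pytest.fixture(scope="session")
def wedge():
    """Curved (cylindrical-sector) ribbon, pial:white area ratio 2:1."""
    mesh = make_cortical_ribbon("wedge", 2500, thickness=2.0, area_ratio=2.0)
    grid = sample_ribbon(mesh, voxel_size=0.15)
    depth = equivolume_depth(mesh, grid)
    return mesh, depth.grid, depth


@pytest.fixture(scope="session")
def events():
    return make_block_design(3, 18.0, 12.0, seed=11)


@pytest.fixture(scope="session")
def hrf():
    return BlockHRF()


@pytest.fixture(scope="session")
def noiseless_run(slab, events, hrf):
    """Noiseless simulated run with uniform 50/50 mixing weights."""
    mesh, grid, depth = slab
    truth = LaminarTruth.from_adi(
        0.3, 1.0, bsi_ae=np.linspace(0.45, 0.25, 21), bsi_fe=np.linspace(0.05, 0.10, 21)
    )
    weights = np.full((mesh.n_vertices, 2), 0.45)
    run = simulate_bold_run(
        mesh, grid, truth, events, tr=2.0, noise_sd=0.0, seed=5,
        weights=weights, hrf=hrf, depth=depth.depth,
    )
    return run
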