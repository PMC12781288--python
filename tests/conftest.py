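import numpy as np
import pytest

from anm import (
    AnmConfig,
    BrainMask,
    VolumeGrid,
    default_acceptance_spec,
    ground_truth,
    run_compare,
    run_group,
    simulate_connectome,
    simulate_foci,
)


@pytest.fixture
def grid2mm() -> VolumeGrid:
    """17^3 grid at 2 mm isotropic, centred on the world origin."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -16.0
    return VolumeGrid(shape=(17, 17, 17), affine=affine)


@pytest.fixture
def full_mask2mm(grid2mm) -> BrainMask:
    return BrainMask(grid=grid2mm, data=np.ones(grid2mm.shape, dtype=bool))


@pytest.fixture
def small_grid() -> VolumeGrid:
    """10^3 grid, identity affine, for brute-force oracle comparisons."""
    return VolumeGrid(shape=(10, 10, 10), affine=np.eye(4))


@pytest.fixture
def small_mask(small_grid) -> BrainMask:
    rng = np.random.default_rng(7)
    data = rng.random(small_grid.shape) < 0.8
    data.flat[0] = True  # never empty
    return BrainMask(grid=small_grid, data=data)


@pytest.fixture(scope="session")
def acceptance_run():
    """Full pipeline at the reference synthetic scenario (shared across tests)."""
    spec = default_acceptance_spec(rng_seed=1)
    participants, mask = simulate_connectome(spec)
    table = simulate_foci(spec)
    config = AnmConfig()
    nt = run_group(table, participants, config, mask, "NT")
    asd = run_group(table, participants, config, mask, "ASD")
    comparison = run_compare(nt, asd, config, mask)
    truth = ground_truth(spec, config.overlap_fraction)
    return {
        "spec": spec,
        "mask": mask,
        "config": config,
        "nt": nt,
        "asd": asd,
        "comparison": comparison,
        "truth": truth,
    }
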