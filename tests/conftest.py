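import numpy as np
import pytest

import hsetools as h

# Reference simulation conditions: 500 cells, 500 genes, 10% dynamic,
# amplitude 2, noise sd 0.3, 20% dropout (the generator defaults).
STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_dataset() -> h.SimulatedDataset:
    return h.generate_trajectory_dataset(h.TrajectorySimConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def study_result(study_dataset):
    """Full pericyte-branch dynamics run on the reference simulation."""
    sel = h.select_cells_near_path(study_dataset.embedding, study_dataset.path, 0.20)
    res = h.run_dynamics_pipeline(
        study_dataset.adata,
        sel,
        study_dataset.pseudotime,
        h.DynamicsConfig.pericyte_branch(),
    )
    return sel, res


@pytest.fixture(scope="session")
def small_dataset() -> h.SimulatedDataset:
    return h.generate_trajectory_dataset(
        h.TrajectorySimConfig(n_cells=150, n_genes=60, frac_dynamic=0.2, seed=11)
    )


def make_segment_path(a=(0.0, 0.0), b=(10.0, 0.0)) -> h.TrajectoryPath:
    return h.TrajectoryPath(("A", "B"), np.array([a, b], dtype=float))
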