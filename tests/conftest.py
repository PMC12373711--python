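import numpy as np
import pandas as pd
import pytest

from plp.atlas import make_fixture_atlas
from plp.cohort import CohortDesign, CohortTable, default_design, simulate_cohort


@pytest.fixture(scope="session")
def atlas():
    """14-region fixture atlas (2 regions per network) on a 24^3 grid."""
    return make_fixture_atlas(grid_shape=(24, 24, 24), regions_per_network=2, seed=7)


@pytest.fixture(scope="session")
def study_design(atlas):
    """Study-conditions design: 174/206 subjects, published baselines."""
    return default_design(atlas, seed=11)


@pytest.fixture(scope="session")
def cohort(study_design):
    return simulate_cohort(study_design)


def null_design(atlas, seed=0, rho=0.3, global_rho=0.0, n_per_group=(174, 206)):
    """Design with no group effects: shared baselines, no point or edge
    effects, no covariates."""
    base = default_design(atlas, seed=seed)
    return CohortDesign(
        regions=base.regions,
        region_network=base.region_network,
        baseline_means=base.baseline_means,
        baseline_sds=base.baseline_sds,
        n_per_group=n_per_group,
        group_labels=base.group_labels,
        network_correlation=rho,
        global_correlation=global_rho,
        seed=seed,
    )


def make_cohort_from_matrix(X1, X2, regions, labels=("CSVD", "HC")):
    """Assemble a CohortTable directly from per-group SUV matrices."""
    n1, n2 = len(X1), len(X2)
    subjects = [f"{labels[0]}_{i:03d}" for i in range(n1)] + [
        f"{labels[1]}_{i:03d}" for i in range(n2)
    ]
    groups = [labels[0]] * n1 + [labels[1]] * n2
    suv = pd.DataFrame(np.vstack([X1, X2]), index=subjects, columns=regions)
    return CohortTable(
        subjects=subjects,
        group=pd.Series(groups, index=subjects, name="group"),
        covariates=pd.DataFrame(index=subjects),
        suv=suv,
    )
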