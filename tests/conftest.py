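import numpy as np
import pandas as pd
import pytest

from cervicomp import (
    AbundanceTable,
    CohortConfig,
    SampleMetadata,
    aitchison_distance,
    clr_transform,
    default_template,
    replace_zeros,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def cohort():
    """One default-size synthetic cohort shared across tests."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_clr(cohort):
    table, _ = cohort
    return clr_transform(replace_zeros(table))


@pytest.fixture(scope="session")
def cohort_distance(cohort_clr):
    return aitchison_distance(cohort_clr)


@pytest.fixture()
def toy_counts():
    return AbundanceTable(
        pd.DataFrame(
            [[10, 0], [5, 5]],
            index=["s1", "s2"],
            columns=["Lactobacillus", "Prevotella"],
        ),
        mode="counts",
    )


def two_group_config(profile_group: str = "Normal", sizes=(20, 20),
                     concentration: float | None = None, seed: int = 0):
    """Config drawing two diagnosis-labelled groups from one shared profile."""
    template = default_template()
    profile = template[profile_group]
    groups = ["Normal", "LSIL"][: len(sizes)]
    profiles = {}
    for g in groups:
        c = concentration if concentration is not None else profile.concentration
        profiles[g] = type(profile)(g, profile.means.copy(),
                                    profile.prevalence.copy(), c)
    return CohortConfig(seed=seed,
                        group_sizes=dict(zip(groups, sizes)),
                        profiles=profiles)
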