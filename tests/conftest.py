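"""Shared fixtures: small synthetic cohorts and cached pipeline stages."""

import pytest

from msub.pipeline import preprocess_cohort, state_stage
from msub.simulate import GeneratorConfig, generate_cohort


SMALL = dict(
    n_tumor=120,
    n_normal=20,
    n_genes=100,
    planted_hypo_per_subtype=12,
    planted_hyper_per_subtype=4,
)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(**SMALL, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A small cohort with 3 planted subtypes plus its ground truth."""
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_states(small_config):
    """Preprocessed small cohort with probe clusters and called states.

    Regenerated rather than shared with ``small_cohort`` because
    preprocessing mutates the tables in place.
    """
    cohort, truth = generate_cohort(small_config)
    cohort = preprocess_cohort(cohort)
    cmap, cluster_beta, states, calls = state_stage(cohort, seed=7)
    return cohort, truth, cmap, cluster_beta, states, calls
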