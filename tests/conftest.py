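import pytest

from lesionspeech import pipeline, synth


@pytest.fixture(scope="session")
def fixture_config():
    return synth.CohortConfig(n_participants=18, seed=42)


@pytest.fixture(scope="session")
def fixture_cohort(fixture_config):
    return synth.generate_cohort(fixture_config)


@pytest.fixture(scope="session")
def fixture_coherence(fixture_cohort, fixture_config):
    return synth.generate_coherence_trials(fixture_cohort, fixture_config,
                                           paper_counts_fixture=True)


@pytest.fixture(scope="session")
def fixture_association(fixture_cohort, fixture_config, fixture_coherence):
    return synth.generate_association_trials(
        fixture_cohort, fixture_config, paper_counts_fixture=True,
        coherence_trials=fixture_coherence)


@pytest.fixture(scope="session")
def recovery_config():
    """200-participant cohort with the default (nonzero) couplings."""
    return synth.CohortConfig(n_participants=200, seed=11)


@pytest.fixture(scope="session")
def recovery_run(recovery_config):
    """Full pipeline output on the recovery cohort (computed once)."""
    return pipeline.run_all(recovery_config)
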