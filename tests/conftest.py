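import pytest

from orthonod import (
    default_scenario,
    run_differential_representation,
    simulate_counts,
    simulate_panel,
)


@pytest.fixture(scope="session")
def default_run():
    """One full run of the study-shaped scenario, shared across tests."""
    scenario = default_scenario(seed=7)
    tree, panel = simulate_panel(scenario)
    matrix, truth = simulate_counts(tree, panel, scenario)
    results = run_differential_representation(matrix, panel)
    return scenario, tree, panel, matrix, truth, results
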