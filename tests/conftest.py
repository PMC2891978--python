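"""Shared fixtures: the planted-recovery genome and its full analysis.

The recovery genome (1,000 genes, 55 RP, 15% planted OCU at bias strength
0.5) is the workhorse of the acceptance suite; its full three-window
analysis is expensive, so it is computed once per session and shared.
"""

import pytest

from ocuscan import CVConfig, SimParams, analyze_genome, simulate_genome

RECOVERY_SEED = 11


@pytest.fixture(scope="session")
def recovery_seed():
    return RECOVERY_SEED


@pytest.fixture(scope="session")
def recovery_sim():
    return simulate_genome(SimParams(seed=RECOVERY_SEED))


@pytest.fixture(scope="session")
def recovery_report(recovery_sim):
    return analyze_genome(
        recovery_sim.genome, cv=CVConfig.desk(RECOVERY_SEED)
    )
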