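"""Shared fixtures: reduced-scale experiment runs and a small surrogate model.

The heavy objects are session-scoped so the whole suite pays for each
simulation exactly once.
"""

import logging

import pytest

from singlecase.phases import StudyDesign, build_study
from singlecase.runner import RunConfig, analyze_dataset, run_experiment
from singlecase.svc import train_default_surrogate

logging.getLogger("singlecase").setLevel(logging.ERROR)

#: Scale used for the reduced-scale replication runs: 0.1 of the full
#: design, i.e. 16,000 series per experiment and at least 4,000 null
#: series in every single-factor stratum.
REPLICATION_SCALE = 0.1
REPLICATION_SEED = 7


@pytest.fixture(scope="session")
def exp1_run():
    """Trend-stability experiment, CDC decisions, at reduced scale."""
    return run_experiment(
        RunConfig(
            experiment="trend",
            scale=REPLICATION_SCALE,
            seed=REPLICATION_SEED,
            methods=("cdc",),
        )
    )


@pytest.fixture(scope="session")
def exp2_run():
    """Variability-stability experiment, CDC decisions, at reduced scale."""
    return run_experiment(
        RunConfig(
            experiment="variability",
            scale=REPLICATION_SCALE,
            seed=REPLICATION_SEED,
            methods=("cdc",),
        )
    )


@pytest.fixture(scope="session")
def small_trend_study():
    """A small trend-experiment dataset for structural invariants."""
    return build_study(StudyDesign("trend", 25, 5, seed=3))


@pytest.fixture(scope="session")
def surrogate_model():
    """Surrogate SVC trained on a small seeded corpus (protocol-scale is 40k)."""
    return train_default_surrogate(seed=11, n_graphs=4000)


@pytest.fixture(scope="session")
def exp1_svc_decisions(exp1_run, surrogate_model):
    """Surrogate-SVC decisions on the same graphs as the CDC run."""
    decisions, _ = analyze_dataset(exp1_run.dataset, ("svc",), surrogate_model)
    return decisions
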