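import numpy as np
import pytest

from transmeta.synth import (
    CovariateSpec,
    LinearModel,
    OutcomeModel,
    PopulationSpec,
)


def sem_spec(
    n=1000,
    a=5.0,
    b=0.01,
    c=0.01,
    label="S",
    freq=0.3,
    mediator_sd=5.0,
    outcome_sd=0.17,
    extra_covariates=(),
    mediator_cov=None,
    outcome_cov=None,
):
    """Linear-SEM stratum spec with known (a, b, c) ground truth."""
    covs = (CovariateSpec("age", "normal", (60.0, 10.0)),) + tuple(extra_covariates)
    med_eff = {"age": 0.1}
    out_eff = {"age": 0.002}
    if mediator_cov:
        med_eff.update(mediator_cov)
    if outcome_cov:
        out_eff.update(outcome_cov)
    return PopulationSpec(
        label=label,
        n=n,
        effect_allele_freq=freq,
        covariates=covs,
        mediator=LinearModel("m", 100.0, a, med_eff, mediator_sd),
        outcome=OutcomeModel("y", 0.8, c, b, out_eff, outcome_sd),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
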