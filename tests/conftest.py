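import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import twinefw as tw

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def published_table() -> tw.ReferenceTable:
    """The published twin EFW reference, wrapped with invariant checks."""
    return tw.ReferenceTable(tw.japanese_twin_efw_reference())


@pytest.fixture(scope="session")
def truth(published_table) -> tw.SyntheticTruth:
    return tw.derive_truth_from_reference(published_table)


@pytest.fixture(scope="session")
def small_cohort(truth):
    """60 pregnancies, enough to exercise every downstream stage quickly."""
    return tw.generate_cohort(truth, 60, seed=11)


@pytest.fixture(scope="session")
def full_run(truth):
    """The scaled-down analogue of the reference study, computed once.

    400 simulated pregnancies, eligibility filter, full Gibbs schedule
    (burn-in 1000, thinning 5, 5000 retained draws), predictive samples
    on the 16-37 week grid and the resulting reference table.
    """
    pregnancies, exams, ledger = tw.generate_cohort(truth, 400, seed=1234)
    log = tw.apply_eligibility(pregnancies)
    included = set(log.included_ids())
    analysis = [e for e in exams if e.pregnancy_id in included]
    draws = tw.fit_gibbs(
        analysis, config=tw.ModelConfig(n_keep=5000, thin=5, burn_in=1000, seed=5678)
    )
    samples = tw.predictive_table_samples(draws, weeks=range(16, 38), seed=99)
    table = tw.build_reference_table(samples)
    return {
        "truth": truth,
        "pregnancies": pregnancies,
        "exams": exams,
        "ledger": ledger,
        "log": log,
        "draws": draws,
        "samples": samples,
        "table": table,
    }
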