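from __future__ import annotations

import pytest

from mclclaims import RunConfig, default_codesets, run_pipeline
from mclclaims.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def codesets():
    return default_codesets()


@pytest.fixture(scope="session")
def synth_small():
    """A small default-condition claims bundle (churn, prior treatment on)."""
    return generate(GeneratorConfig(n_patients=60, seed=11))


@pytest.fixture(scope="session")
def pipeline_200():
    """End-to-end run on 200 patients under the default study conditions."""
    return run_pipeline(RunConfig(n_patients=200, seed=5, fit_models=False))


@pytest.fixture(scope="session")
def clean_recovery_run():
    """Run with churn, dropout and pre-index treatment disabled: ground truth
    must be exactly recoverable."""
    cfg = GeneratorConfig(n_patients=200, seed=23, enrollment_churn=0.0,
                          prior_treatment_prob=0.0)
    return run_pipeline(RunConfig(generator=cfg, fit_models=False, top_k=20))
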