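import numpy as np
import pandas as pd
import pytest

from glmaid import cohort


@pytest.fixture(scope="session")
def default_cfg():
    return cohort.default_config()


@pytest.fixture(scope="session")
def cohort167(default_cfg):
    """One seeded default cohort shared across tests."""
    return cohort.generate(default_cfg, seed_override=1)


@pytest.fixture(scope="session")
def big_cohort(default_cfg):
    """Inflated design (~10,000 samples) for Monte-Carlo recovery and
    significance-pattern checks."""
    cfg = cohort.GeneratorConfig(
        design=cohort.default_design(total=10_020),
        parameters=default_cfg.parameters, seed=7)
    return cfg, cohort.generate(cfg)


def make_cohort(n_per_cell=3, effects=None, residual_sd=1.0, seed=0,
                parameters=("Y",), grand_mean=0.0, lower_bound=-np.inf):
    """Small custom cohort builder for targeted tests.

    ``effects`` maps parameter name -> {term: offset array}.
    """
    design = cohort.FactorDesign()
    design.cell_counts = {cell: n_per_cell for cell in design.cells()}
    specs = []
    for name in parameters:
        specs.append(cohort.ParameterSpec(
            name=name, unit="", grand_mean=grand_mean,
            residual_sd=residual_sd,
            effects={t: np.asarray(a, dtype=float)
                     for t, a in (effects or {}).get(name, {}).items()},
            detection_limit=0.0, lower_bound=lower_bound))
    cfg = cohort.GeneratorConfig(design=design, parameters=specs, seed=seed)
    return cohort.generate(cfg)
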