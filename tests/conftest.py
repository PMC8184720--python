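import numpy as np
import pandas as pd
import pytest

from glycoprog.datamodel import Cohort
from glycoprog.pipeline import RunConfig, run_pipeline
from glycoprog.simulate import (
    SimConfig,
    attach_response,
    immune_gene_sets,
    simulate_multi_cohort,
)


def make_cohort(name="toy", n_genes=4, n_samples=6, seed=0, **clinical_extra) -> Cohort:
    """Small deterministic cohort for unit tests."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    samples = [f"S{i + 1}" for i in range(n_samples)]
    expression = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(n_genes, n_samples)), index=genes, columns=samples
    )
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "os_time": rng.uniform(30, 2000, n_samples).round(0),
            "os_event": rng.integers(0, 2, n_samples),
            **clinical_extra,
        }
    )
    clinical.loc[0, "os_event"] = 1  # at least one event
    return Cohort(name=name, expression=expression, clinical=clinical)


@pytest.fixture(scope="session")
def sim_study():
    """One synthetic 6-training + 1-validation study with response labels."""
    config = SimConfig(n_cohorts=7, seed=11)
    cohorts, truth = simulate_multi_cohort(config)
    cohorts = [attach_response(c, truth) for c in cohorts]
    return config, cohorts, truth


@pytest.fixture(scope="session")
def pipeline_report(sim_study):
    """Full pipeline run on the session study (training = first 6 cohorts)."""
    config, cohorts, truth = sim_study
    run_config = RunConfig(
        training=cohorts[:6],
        validation=cohorts[6:],
        gene_universe=tuple(f"GLY_{i + 1:03d}" for i in range(config.n_genes)),
        immune_sets=immune_gene_sets(truth),
        seed=config.seed,
    )
    return run_pipeline(run_config), truth
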